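"""Interface residues and solvent accessibility.

Protein–protein interfaces are geometric: two residues are in contact when
their Cα atoms lie within 5.0 Å of each other (inclusive).  Protein–nucleic
interfaces are defined by burial: residues whose relative accessible
surface area (RASA) strictly decreases when the nucleic chains are added to
the context.  Solvent-accessible surface area is computed with a
Shrake–Rupley sphere-sampling scheme (probe radius 1.4 Å by default);
surface residues of a complex are those with RASA above a cutoff
(default 5 %) in the full-complex context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import DEFAULT_RADIUS, MAX_ASA, VDW_RADII
from .structures import AtomRecord, ComplexRecord

CONTACT_CUTOFF = 5.0   # Å, Cα–Cα, inclusive
PROBE_RADIUS = 1.4     # Å
SASA_POINTS = 300      # sphere sample points per atom
RASA_EPS = 1e-6        # Å², guards quadrature noise in strict comparisons

ResidueKey = tuple[str, int]  # (chain_id, 1-based sequence position)


@dataclass
class InterfaceAnnotation:
    """Interface residues of one query chain, per partner chain."""

    structure_id: str
    by_partner: dict[str, set[int]] = field(default_factory=dict)
    partner_type: dict[str, str] = field(default_factory=dict)

    def union(self, interface_type: str | None = None) -> set[int]:
        out: set[int] = set()
        for partner, residues in self.by_partner.items():
            if interface_type is None or self.partner_type[partner] == interface_type:
                out |= residues
        return out


@dataclass
class SasaProfile:
    """Per-residue solvent-accessible surface area, keyed by (chain, pos)."""

    area: dict[ResidueKey, float]   # Å²
    rasa: dict[ResidueKey, float]   # % of the per-residue maximum

    def chain_area(self, chain_id: str) -> dict[int, float]:
        return {pos: a for (cid, pos), a in self.area.items() if cid == chain_id}

    def chain_rasa(self, chain_id: str) -> dict[int, float]:
        return {pos: r for (cid, pos), r in self.rasa.items() if cid == chain_id}


def protein_interface(
    complex_record: ComplexRecord,
    chain_id: str,
    cutoff: float = CONTACT_CUTOFF,
) -> InterfaceAnnotation:
    """Cα-contact interface of ``chain_id`` with every other protein chain.

    Residue *i* of the query chain is interface with partner chain *P* iff
    some Cα of *P* lies within ``cutoff`` (inclusive) of residue *i*'s Cα.
    """
    query = complex_record.chain(chain_id)
    qpos, qxyz = query.rep_coords()
    annot = InterfaceAnnotation(structure_id=query.structure_id)
    if len(qpos) == 0:
        return annot
    qtree = cKDTree(qxyz)
    for partner in complex_record.chains:
        if partner.chain_name == chain_id or partner.molecule_type != "protein":
            continue
        ppos, pxyz = partner.rep_coords()
        if len(ppos) == 0:
            continue
        hits = qtree.query_ball_point(pxyz, r=cutoff)
        touched = {int(qpos[i]) for per_atom in hits for i in per_atom}
        if touched:
            annot.by_partner[partner.chain_name] = touched
            annot.partner_type[partner.chain_name] = "protein"
    return annot


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}, using fallback radius "
                      f"{DEFAULT_RADIUS} Å")
        r = DEFAULT_RADIUS
    return r


def sasa(
    atoms: list[AtomRecord],
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> SasaProfile:
    """Shrake–Rupley solvent-accessible surface area, summed per residue.

    Each atom is inflated by the probe radius and sampled with ``n_points``
    quasi-uniform sphere points; a point is exposed iff it lies outside
    every neighbouring inflated sphere.  RASA is the residue area divided
    by the tabulated per-residue maximum (×100); residue types without a
    tabulated maximum use the area of their own atoms computed in
    isolation (so RASA stays within [0, 100] up to quadrature noise).
    """
    if not atoms:
        return SasaProfile(area={}, rasa={})
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([_radius(a.element) + probe for a in atoms])
    unit = _sphere_points(n_points)

    tree = cKDTree(xyz)
    max_r = radii.max()
    exposed = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + radii[i] * unit
        free = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(xyz[i], r=radii[i] + max_r):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            free &= d2 > radii[j] ** 2
        exposed[i] = free.mean() * 4.0 * np.pi * radii[i] ** 2

    area: dict[ResidueKey, float] = {}
    res_name: dict[ResidueKey, str] = {}
    atom_idx: dict[ResidueKey, list[int]] = {}
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.residue_seq_pos)
        area[key] = area.get(key, 0.0) + exposed[i]
        res_name[key] = a.res_name
        atom_idx.setdefault(key, []).append(i)

    rasa: dict[ResidueKey, float] = {}
    for key, total in area.items():
        ref = MAX_ASA.get(res_name[key])
        if ref is None:
            ref = float(np.sum(4.0 * np.pi * radii[atom_idx[key]] ** 2))
        rasa[key] = 100.0 * total / ref
    return SasaProfile(area=area, rasa=rasa)


def nucleic_interface(
    complex_record: ComplexRecord,
    chain_id: str,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> InterfaceAnnotation:
    """Residues of ``chain_id`` buried by nucleic chains (RASA decrease).

    For each nucleic chain, a residue of the query chain is interface with
    it iff its SASA computed on the isolated protein chain strictly exceeds
    (beyond a small numerical epsilon) the SASA computed with that nucleic
    chain present.
    """
    query = complex_record.chain(chain_id)
    annot = InterfaceAnnotation(structure_id=query.structure_id)
    nucleic = [c for c in complex_record.chains if c.molecule_type == "nucleic"]
    if not nucleic:
        return annot
    alone = sasa(query.atoms, probe=probe, n_points=n_points).chain_area(chain_id)
    for nc in nucleic:
        bound = sasa(query.atoms + nc.atoms, probe=probe,
                     n_points=n_points).chain_area(chain_id)
        buried = {pos for pos, a in alone.items()
                  if a - bound.get(pos, 0.0) > RASA_EPS}
        if buried:
            annot.by_partner[nc.chain_name] = buried
            annot.partner_type[nc.chain_name] = "nucleic"
    return annot


def surface_residues(
    complex_record: ComplexRecord,
    chain_id: str,
    rasa_cutoff: float = 5.0,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> set[int]:
    """Query-chain residues with RASA > ``rasa_cutoff`` (%) in the
    full-complex context."""
    atoms = [a for c in complex_record.chains for a in c.atoms]
    profile = sasa(atoms, probe=probe, n_points=n_points)
    return {pos for pos, r in profile.chain_rasa(chain_id).items()
            if r > rasa_cutoff}
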