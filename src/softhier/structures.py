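"""Reading and writing PDB-format coordinate files.

Each crystallised chain is reduced to the information the downstream
analysis needs: the full SEQRES sequence, which sequence positions are
actually observed (have a representative atom in the ATOM records), the
B-factor of the representative atom at each observed position, and the
molecule type.  Sequence positions are 1-based over the SEQRES sequence;
every downstream residue set (soft disorder, interfaces, surface) lives in
this coordinate system.

A residue counts as *observed* iff its representative atom is present:
the Cα for amino acids, the C1′ for nucleotides.  Residues present only
through side-chain atoms are treated as unobserved, because the per-residue
B-factor is read from the Cα.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: representative atom per molecule type
REP_ATOM = {"protein": "CA", "nucleic": "C1'"}

_NUCLEIC_NAMES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class AtomRecord:
    """One atom of a chain, in SEQRES coordinates."""

    chain_id: str
    residue_seq_pos: int        # 1-based position in the full chain sequence
    res_name: str               # 3-letter (protein) / 1-2 letter (nucleic) code
    atom_name: str
    element: str
    coords: np.ndarray          # (3,) in Å
    b_factor: float             # Å²

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.b_factor < 0:
            raise ValueError("B-factor must be non-negative")


@dataclass
class ChainRecord:
    """One crystallised chain: sequence, observation mask, Cα B-factors."""

    structure_id: str           # "<entry>_<chain>", e.g. "4m0l_A"
    chain_name: str
    sequence: str               # one-letter codes over the full SEQRES
    res_names: list[str]        # 3-letter codes, parallel to sequence
    observed_mask: np.ndarray   # bool per 1-based sequence position
    ca_b: dict[int, float]      # position -> B-factor (observed positions only)
    molecule_type: str          # "protein" | "nucleic"
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if len(self.observed_mask) != len(self.sequence):
            raise ValueError("observed_mask length != sequence length")
        observed = self.observed_positions()
        if set(self.ca_b) != observed:
            raise ValueError("ca_b must be defined exactly on observed positions")

    def __len__(self) -> int:
        return len(self.sequence)

    def observed_positions(self) -> set[int]:
        return {int(i) + 1 for i in np.flatnonzero(self.observed_mask)}

    def missing_positions(self) -> set[int]:
        """SEQRES positions with no representative atom in the ATOM records."""
        return {int(i) + 1 for i in np.flatnonzero(~self.observed_mask)}

    def rep_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Representative-atom coordinates: (positions, (n, 3) array)."""
        rep = REP_ATOM[self.molecule_type]
        pairs = [(a.residue_seq_pos, a.coords) for a in self.atoms if a.atom_name == rep]
        pairs.sort(key=lambda p: p[0])
        if not pairs:
            return np.empty(0, dtype=int), np.empty((0, 3))
        pos, xyz = zip(*pairs)
        return np.asarray(pos, dtype=int), np.vstack(xyz)


@dataclass
class ComplexRecord:
    """All chains of one coordinate file."""

    entry_id: str
    chains: list[ChainRecord]
    resolution: float | None = None
    r_value: float | None = None

    def __post_init__(self) -> None:
        names = [c.chain_name for c in self.chains]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate chain ids in entry {self.entry_id}")

    def chain(self, chain_name: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_name == chain_name:
                return c
        raise KeyError(f"no chain {chain_name!r} in entry {self.entry_id}")


def _one_letter(res_name: str) -> str:
    info = gemmi.find_tabulated_residue(res_name)
    if info is not None:
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _molecule_type(res_names: list[str]) -> str:
    n_nuc = sum(1 for r in res_names if r.strip() in _NUCLEIC_NAMES)
    return "nucleic" if n_nuc > len(res_names) / 2 else "protein"


def _select_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name (tie -> first)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(path: str | Path, entry_id: str | None = None) -> ComplexRecord:
    """Parse a PDB-format file into a :class:`ComplexRecord`.

    Residues listed in SEQRES but absent from the ATOM records are marked
    unobserved.  Without SEQRES the sequence is the observed residues only
    (a warning is logged).  Chains with zero observed residues are skipped
    with a warning.
    """
    path = Path(path)
    if entry_id is None:
        entry_id = path.stem
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models in {path}")
    st.setup_entities()
    st.assign_label_seq_id()
    model = st[0]

    chains: list[ChainRecord] = []
    for chain in model:
        ent = st.get_entity_of(chain.get_polymer())
        seqres = list(ent.full_sequence) if ent is not None else []
        seqres = [gemmi.Entity.first_mon(m) for m in seqres]
        has_seqres = bool(seqres)
        if not has_seqres:
            logger.warning(
                "%s chain %s: no SEQRES, sequence taken from observed residues",
                entry_id, chain.name,
            )
            seqres = [r.name for r in chain]

        mol_type = _molecule_type(seqres)
        rep_atom = REP_ATOM[mol_type]
        n = len(seqres)
        observed = np.zeros(n, dtype=bool)
        ca_b: dict[int, float] = {}
        atoms: list[AtomRecord] = []

        for idx, residue in enumerate(chain):
            if has_seqres and residue.label_seq is not None:
                pos = int(residue.label_seq)
            else:
                pos = idx + 1
            if not (1 <= pos <= n):
                continue
            for atom in _select_altloc(residue):
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_seq_pos=pos,
                    res_name=residue.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    b_factor=float(atom.b_iso),
                ))
                if atom.name == rep_atom:
                    observed[pos - 1] = True
                    ca_b[pos] = float(atom.b_iso)

        if not observed.any():
            logger.warning("%s chain %s: zero observed residues, skipped",
                           entry_id, chain.name)
            continue
        chains.append(ChainRecord(
            structure_id=f"{entry_id}_{chain.name}",
            chain_name=chain.name,
            sequence="".join(_one_letter(r) for r in seqres),
            res_names=list(seqres),
            observed_mask=observed,
            ca_b=ca_b,
            molecule_type=mol_type,
            atoms=atoms,
        ))
    resolution = float(st.resolution) if st.resolution > 0 else None
    return ComplexRecord(entry_id=entry_id, chains=chains, resolution=resolution)


def write_structure(complex_record: ComplexRecord, path: str | Path) -> None:
    """Write a ComplexRecord as a PDB-format file (SEQRES + ATOM records)."""
    if not complex_record.chains:
        raise ValueError("cannot write a complex with no chains")
    st = gemmi.Structure()
    st.name = complex_record.entry_id
    model = gemmi.Model("1")
    for cr in complex_record.chains:
        chain = gemmi.Chain(cr.chain_name)
        by_pos: dict[int, list[AtomRecord]] = {}
        for a in cr.atoms:
            by_pos.setdefault(a.residue_seq_pos, []).append(a)
        for pos in sorted(by_pos):
            res = gemmi.Residue()
            res.name = by_pos[pos][0].res_name
            res.seqid = gemmi.SeqId(pos, " ")
            res.label_seq = pos
            for a in by_pos[pos]:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coords)
                atom.b_iso = a.b_factor
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    # attach the full SEQRES sequence per chain entity
    for cr in complex_record.chains:
        polymer = st[0][cr.chain_name].get_polymer()
        ent = st.get_entity_of(polymer)
        if ent is not None:
            ent.full_sequence = list(cr.res_names)
    st.assign_label_seq_id()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_manifest(path: str | Path) -> list[dict]:
    """Read a manifest TSV (entry_id, path, resolution, r_value).

    Paths are resolved relative to the manifest's directory.  resolution /
    r_value may be empty.
    """
    import csv

    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            p = Path(row["path"])
            if not p.is_absolute():
                p = path.parent / p
            rows.append({
                "entry_id": row["entry_id"],
                "path": p,
                "resolution": float(row["resolution"]) if row.get("resolution") else None,
                "r_value": float(row["r_value"]) if row.get("r_value") else None,
            })
    if not rows:
        raise ValueError(f"empty manifest: {path}")
    return rows


def load_manifest_structures(path: str | Path) -> list[ComplexRecord]:
    """Load every structure listed in a manifest TSV, attaching metadata."""
    records = []
    for row in read_manifest(path):
        rec = read_structure(row["path"], entry_id=row["entry_id"])
        if row["resolution"] is not None:
            rec.resolution = row["resolution"]
        if row["r_value"] is not None:
            rec.r_value = row["r_value"]
        records.append(rec)
    return records
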