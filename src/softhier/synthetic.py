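"""Seeded synthetic clusters with planted disorder, interfaces and DAGs.

The generator emulates what the analysis assumes about real crystal
clusters: several near-identical copies of one chain crystallised in
complexes of increasing partner count, with (a) high-B segments planted so
that per-chain normalisation recovers them as b > 1 calls, (b) segments
omitted from the ATOM records but present in SEQRES (missing residues,
partly member-specific to exercise intermittent disorder), and (c) partner
chains positioned so that designated residues fall within the Cα contact
cutoff — planting interfaces geometrically.  A single parameter,
``overlap_f``, is the probability that each newly added interface residue
is drawn from the parent node's planted soft-disorder region, so the
pipeline's measured sensitivity has a known target.

Geometry is deliberately crude (Cα traces on a straight line, partners on
angularly separated offsets): the analysis only consumes distances,
accessibilities, B-factor columns and SEQRES/ATOM gaps, not realistic
folds.  Consecutive Cα atoms sit 3.8 Å apart, partner atoms 4.0 Å from
their target residue — inside the 5 Å cutoff while the nearest sequence
neighbours stay outside it (√(3.8² + 4²) ≈ 5.5 Å), so planted contacts
are single-residue exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .hierarchy import HierNode
from .structures import AtomRecord, ChainRecord, ComplexRecord, write_structure

AA3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]
AA1 = "ARNDCQEGHILKMFPSTWYV"
CA_SPACING = 3.8      # Å between consecutive Cα
CONTACT_OFFSET = 4.0  # Å partner-to-target distance (protein)
NUC_OFFSET = 3.5      # Å partner-to-target distance (nucleic)
BASELINE_B = 30.0     # Å² baseline B-factor


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cluster."""

    chain_length: int = 60
    n_nodes: int = 3
    members_per_node: int = 2
    sdr_fraction: float = 0.12     # planted high-B segment, fraction of chain
    missing_fraction: float = 0.06  # planted missing segment, fraction of chain
    ir_per_edge: int = 6           # new interface residues per DAG edge
    overlap_f: float = 0.5         # P(new-IR residue drawn from parent SDR)
    b_noise: float = 3.0           # Å², sd of baseline B-factor noise
    b_shift_sd: float = 6.0        # high-B elevation, in units of b_noise
    extra_missing: int = 2         # member-specific missing residues
    include_nucleic: bool = False  # last added partner is a nucleic chain
    uniform_ir: bool = False       # place new IR uniformly (overlap_f = r_D)
    topology: str = "path"         # "path" (K=0..n-1) or "fork" (root + leaves)
    cluster_name: str = "syn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chain_length < 20:
            raise ValueError("chain_length must be >= 20")
        for f in (self.sdr_fraction, self.missing_fraction, self.overlap_f):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_nodes < 1:
            raise ValueError("need at least one node")
        if self.topology not in ("path", "fork"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class NodeTruth:
    index: int
    K: int
    parent: int | None
    partners: list[int]            # partner indices held by this node
    entry_ids: list[str]
    ir_cum: list[int]              # cumulative planted interface
    new_ir: list[int]              # added relative to parent
    high_b: list[int]
    missing: list[int]             # shared (node-wide) missing segment
    extras: dict[str, list[int]]   # entry_id -> member-specific missing
    sdr: list[int]                 # high_b ∪ missing ∪ extras


@dataclass
class PlantedTruth:
    config: dict
    sequence: str
    levels: list[NodeTruth]
    edges: list[dict]              # {parent, child, k, new_ir}
    partner_is_nucleic: dict[str, bool] = field(default_factory=dict)

    def node_sdr(self, index: int) -> set[int]:
        return set(self.levels[index].sdr)

    def union_sdr(self) -> set[int]:
        out: set[int] = set()
        for lvl in self.levels:
            out |= set(lvl.sdr)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "sequence": self.sequence,
            "levels": [asdict(lvl) for lvl in self.levels],
            "edges": self.edges,
            "partner_is_nucleic": self.partner_is_nucleic,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=payload["config"],
            sequence=payload["sequence"],
            levels=[NodeTruth(**lvl) for lvl in payload["levels"]],
            edges=payload["edges"],
            partner_is_nucleic=payload["partner_is_nucleic"],
        )


def _pick_segment(rng: np.random.Generator, length: int, seg_len: int,
                  forbidden: set[int]) -> set[int]:
    """A contiguous run of ``seg_len`` positions avoiding ``forbidden``."""
    if seg_len == 0:
        return set()
    starts = [s for s in range(1, length - seg_len + 2)
              if not any(p in forbidden for p in range(s, s + seg_len))]
    if not starts:
        # planted interfaces can fragment the chain so much that no
        # contiguous run remains; fall back to scattered positions
        pool = set(range(1, length + 1)) - forbidden
        if len(pool) < seg_len:
            raise ValueError(
                "infeasible geometry: no room for a planted segment "
                "(too many partners / segments for the chain length)")
        return _pick_scattered(rng, pool, seg_len)
    s = int(rng.choice(starts))
    return set(range(s, s + seg_len))


def _pick_scattered(rng: np.random.Generator, pool: set[int], n: int) -> set[int]:
    if len(pool) < n:
        raise ValueError("infeasible geometry: planted sets exhaust the chain")
    return set(int(p) for p in rng.choice(sorted(pool), size=n, replace=False))


def _node_plan(cfg: SyntheticConfig, rng: np.random.Generator) -> list[NodeTruth]:
    L = cfg.chain_length
    n_high = round(cfg.sdr_fraction * L)
    n_miss = round(cfg.missing_fraction * L)

    def plant_high_extras(forbidden: set[int]) -> tuple[set[int], list[set[int]]]:
        high = _pick_segment(rng, L, n_high, forbidden)
        extras = []
        for _ in range(cfg.members_per_node - 1):
            pool = set(range(1, L + 1)) - forbidden - high
            extras.append(_pick_scattered(rng, pool, cfg.extra_missing))
        return high, extras

    def draw_new_ir(parent_sdr: set[int], ir_cum: set[int],
                    excluded: set[int]) -> set[int]:
        # the draw pool excludes the child's planned node-wide missing
        # segment, so it coincides with the edge-test universe and the
        # planted overlap maps directly onto the measured sensitivity
        sdr_pool = set(parent_sdr) - ir_cum - excluded
        other_pool = set(range(1, L + 1)) - parent_sdr - ir_cum - excluded
        chosen: set[int] = set()
        for _ in range(cfg.ir_per_edge):
            if cfg.uniform_ir:
                pool = sdr_pool | other_pool
            else:
                use_sdr = rng.random() < cfg.overlap_f
                pool = sdr_pool if use_sdr else other_pool
                if not pool:
                    pool = other_pool if use_sdr else sdr_pool
            if not pool:
                raise ValueError("infeasible geometry: nowhere to plant IR")
            pos = int(rng.choice(sorted(pool)))
            chosen.add(pos)
            sdr_pool.discard(pos)
            other_pool.discard(pos)
        return chosen

    levels: list[NodeTruth] = []
    # root
    miss = _pick_segment(rng, L, n_miss, set())
    high, extras = plant_high_extras(miss)
    levels.append(NodeTruth(
        index=0, K=0, parent=None, partners=[], entry_ids=[],
        ir_cum=[], new_ir=[], high_b=sorted(high), missing=sorted(miss),
        extras={str(m + 1): sorted(extras[m]) for m in range(len(extras))},
        sdr=sorted(high | miss | set().union(*extras, set())),
    ))

    n_children = cfg.n_nodes - 1
    for e in range(1, n_children + 1):
        parent = levels[0] if cfg.topology == "fork" else levels[e - 1]
        miss = _pick_segment(rng, L, n_miss, set(parent.ir_cum))
        new_ir = draw_new_ir(set(parent.sdr), set(parent.ir_cum), miss)
        ir_cum = set(parent.ir_cum) | new_ir
        high, extras = plant_high_extras(ir_cum | miss)
        node = NodeTruth(
            index=e, K=parent.K + 1, parent=parent.index,
            partners=parent.partners + [e], entry_ids=[],
            ir_cum=sorted(ir_cum), new_ir=sorted(new_ir),
            high_b=sorted(high), missing=sorted(miss),
            extras={str(m + 1): sorted(extras[m]) for m in range(len(extras))},
            sdr=sorted(high | miss | set().union(*extras, set())),
        )
        levels.append(node)
    return levels


def _partner_chain(partner_idx: int, ir_positions: list[int], seq: str,
                   nucleic: bool, n_partners_total: int) -> ChainRecord:
    angle = 2.0 * math.pi * partner_idx / max(n_partners_total + 1, 3)
    r = NUC_OFFSET if nucleic else CONTACT_OFFSET
    dy, dz = r * math.cos(angle), r * math.sin(angle)
    name = "N" if nucleic else chr(ord("A") + partner_idx)
    res_name = "DA" if nucleic else None
    atom_name = "C1'" if nucleic else "CA"
    coords = [np.array([CA_SPACING * (p - 1), dy, dz]) for p in ir_positions]
    # two tail residues far from everything (and from other partners' tails),
    # so the chain has length > IR
    tail_x = -10.0 - 6.0 * partner_idx
    tail_y = 25.0 + 10.0 * partner_idx
    coords += [np.array([tail_x, tail_y, 25.0]),
               np.array([tail_x + CA_SPACING, tail_y, 25.0])]
    atoms = []
    res_names = []
    for i, xyz in enumerate(coords):
        rn = res_name or AA3[AA1.index(seq[i])]
        res_names.append(rn)
        atoms.append(AtomRecord(chain_id=name, residue_seq_pos=i + 1,
                                res_name=rn, atom_name=atom_name, element="C",
                                coords=xyz, b_factor=BASELINE_B))
    sequence = ("A" * len(coords)) if nucleic else seq[:len(coords)]
    return ChainRecord(
        structure_id=f"?_{name}", chain_name=name, sequence=sequence,
        res_names=res_names,
        observed_mask=np.ones(len(coords), dtype=bool),
        ca_b={i + 1: BASELINE_B for i in range(len(coords))},
        molecule_type="nucleic" if nucleic else "protein",
        atoms=atoms,
    )


def generate_cluster(
    config: SyntheticConfig,
    outdir: str | Path,
) -> tuple[list[Path], PlantedTruth]:
    """Write one synthetic cluster (PDB files, manifest TSV, truth JSON).

    Deterministic given ``config.seed``: the same configuration produces a
    byte-identical fixture set.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    L = config.chain_length
    seq_idx = rng.integers(0, 20, size=L)
    sequence = "".join(AA1[i] for i in seq_idx)
    res_names = [AA3[i] for i in seq_idx]

    levels = _node_plan(config, rng)
    n_partners = config.n_nodes - 1
    partner_seqs = {
        j: "".join(AA1[i] for i in rng.integers(0, 20, size=config.ir_per_edge + 2))
        for j in range(1, n_partners + 1)
    }
    nucleic_partner = n_partners if (config.include_nucleic and n_partners) else None
    # IR positions contributed by each partner = the new_ir of the node that
    # introduced it
    partner_ir = {lvl.partners[-1]: lvl.new_ir for lvl in levels if lvl.partners}

    paths: list[Path] = []
    manifest_rows: list[str] = []
    shift = config.b_shift_sd * config.b_noise
    counter = 0
    for lvl in levels:
        for m in range(config.members_per_node):
            entry = f"{config.cluster_name}n{lvl.index}m{m}"
            lvl.entry_ids.append(entry)
            unobserved = set(lvl.missing)
            if m > 0:
                unobserved |= set(lvl.extras.get(str(m), []))
            baseline = BASELINE_B + rng.normal(0.0, config.b_noise, size=L)
            baseline = np.clip(baseline, 0.01, None)
            atoms = []
            ca_b = {}
            mask = np.zeros(L, dtype=bool)
            for pos in range(1, L + 1):
                if pos in unobserved:
                    continue
                b = float(baseline[pos - 1])
                if pos in lvl.high_b:
                    b += shift
                b = round(b, 2)  # PDB fixed-width B column
                atoms.append(AtomRecord(
                    chain_id="A", residue_seq_pos=pos,
                    res_name=res_names[pos - 1], atom_name="CA", element="C",
                    coords=np.array([CA_SPACING * (pos - 1), 0.0, 0.0]),
                    b_factor=b))
                ca_b[pos] = b
                mask[pos - 1] = True
            chain_a = ChainRecord(
                structure_id=f"{entry}_A", chain_name="A", sequence=sequence,
                res_names=res_names, observed_mask=mask, ca_b=ca_b,
                molecule_type="protein", atoms=atoms)
            chains = [chain_a]
            for j in lvl.partners:
                partner = _partner_chain(
                    j, partner_ir[j], partner_seqs[j],
                    nucleic=(j == nucleic_partner),
                    n_partners_total=n_partners)
                partner.structure_id = f"{entry}_{partner.chain_name}"
                chains.append(partner)
            path = outdir / f"{entry}.pdb"
            write_structure(ComplexRecord(entry_id=entry, chains=chains), path)
            paths.append(path)
            resolution = 1.5 + 0.1 * counter
            manifest_rows.append(f"{entry}\t{path.name}\t{resolution:.2f}\t")
            counter += 1

    (outdir / "manifest.tsv").write_text(
        "entry_id\tpath\tresolution\tr_value\n" + "\n".join(manifest_rows) + "\n")

    edges = []
    for lvl in levels:
        if lvl.parent is not None:
            edges.append({"parent": lvl.parent, "child": lvl.index,
                          "k": lvl.K - levels[lvl.parent].K,
                          "new_ir": list(lvl.new_ir)})
    truth = PlantedTruth(
        config=asdict(config), sequence=sequence, levels=levels, edges=edges,
        partner_is_nucleic={str(j): j == nucleic_partner
                            for j in range(1, n_partners + 1)},
    )
    truth.to_json(outdir / "truth.json")
    return paths, truth


def generate_plddt(
    truth: PlantedTruth,
    n_models: int = 5,
    noise: float = 5.0,
    depression: float = 25.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-residue pLDDT profiles with depressed confidence on the planted
    union-SDR (plus Gaussian noise), one array per model."""
    rng = np.random.default_rng(seed)
    L = len(truth.sequence)
    union = truth.union_sdr()
    base = np.full(L, 90.0)
    for p in union:
        base[p - 1] -= depression
    models = []
    for _ in range(n_models):
        prof = base + rng.normal(0.0, noise, size=L)
        models.append(np.clip(prof, 0.0, 100.0))
    return models


def random_abstract_nodes(
    rng: np.random.Generator,
    max_nodes: int = 8,
    chain_length: int = 40,
    partner_alphabet: int = 4,
) -> list[HierNode]:
    """Random member-less nodes for stress-testing DAG edge construction.

    Signatures are random multisets over a small partner alphabet and IRs
    random residue sets, so all three edge conditions (K increase,
    signature inclusion, 75 % IR retention) are exercised, including
    violations.
    """
    n = int(rng.integers(2, max_nodes + 1))
    nodes = []
    for i in range(n):
        k = int(rng.integers(0, 4))
        sig = tuple(sorted(
            f"p{int(rng.integers(0, partner_alphabet))}" for _ in range(k)))
        ir_size = int(rng.integers(0, 13))
        ir = set(int(p) for p in
                 rng.choice(chain_length, size=ir_size, replace=False) + 1)
        ir_nuc = set()
        if rng.random() < 0.3:
            ir_nuc = set(int(p) for p in
                         rng.choice(chain_length, size=int(rng.integers(0, 5)),
                                    replace=False) + 1)
        nodes.append(HierNode(
            node_id=f"n{len(sig)}_{i}", members=[], signature=sig,
            ir_protein=ir, ir_nucleic=ir_nuc, sdr=set(), always_missing=set()))
    return nodes
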