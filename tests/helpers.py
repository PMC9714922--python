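"""Shared test utilities: tiny hand-built structures and brute-force oracles."""

from __future__ import annotations

import numpy as np

from softhier.hierarchy import AssemblyDAG, HierNode
from softhier.structures import AtomRecord, ChainRecord, ComplexRecord

CA_SPACING = 3.8


def line_chain(
    n: int,
    chain: str = "A",
    entry: str = "t",
    b=20.0,
    observed=None,
    origin=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
    molecule_type: str = "protein",
    seq: str | None = None,
) -> ChainRecord:
    """A straight Cα (or C1′) trace with controllable B-factors and gaps."""
    seq = seq or ("G" * n if molecule_type == "protein" else "A" * n)
    res_names = (["GLY"] * n if molecule_type == "protein" else ["DA"] * n)
    if seq and molecule_type == "protein":
        from softhier.synthetic import AA1, AA3
        res_names = [AA3[AA1.index(c)] for c in seq]
    b_arr = np.full(n, b, dtype=float) if np.isscalar(b) else np.asarray(b, float)
    observed = set(range(1, n + 1)) if observed is None else set(observed)
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    atom_name = "CA" if molecule_type == "protein" else "C1'"
    atoms = [
        AtomRecord(chain, p, res_names[p - 1], atom_name, "C",
                   origin + CA_SPACING * (p - 1) * direction, float(b_arr[p - 1]))
        for p in sorted(observed)
    ]
    mask = np.array([p in observed for p in range(1, n + 1)])
    return ChainRecord(
        structure_id=f"{entry}_{chain}", chain_name=chain, sequence=seq,
        res_names=res_names, observed_mask=mask,
        ca_b={p: float(b_arr[p - 1]) for p in sorted(observed)},
        molecule_type=molecule_type, atoms=atoms)


def make_complex(entry: str, *chains: ChainRecord, resolution=None) -> ComplexRecord:
    fixed = []
    for c in chains:
        c.structure_id = f"{entry}_{c.chain_name}"
        fixed.append(c)
    return ComplexRecord(entry_id=entry, chains=fixed, resolution=resolution)


def abstract_node(node_id: str, signature, ir_protein=(), ir_nucleic=(),
                  sdr=()) -> HierNode:
    return HierNode(node_id=node_id, members=[], signature=tuple(sorted(signature)),
                    ir_protein=set(ir_protein), ir_nucleic=set(ir_nucleic),
                    sdr=set(sdr), always_missing=set())


def brute_force_edges(nodes: list[HierNode],
                      overlap_min: float = 0.75) -> set[tuple[str, str, int]]:
    """Independent oracle for DAG wiring: enumerate all ordered node pairs,
    apply the three edge conditions, then delete candidates with a two-step
    candidate path between their endpoints."""
    cand = set()
    for a in nodes:
        for b in nodes:
            if a is b:
                continue
            ok = (b.K > a.K
                  and _multiset_contains(b.signature, a.signature)
                  and _retained(a.ir_protein, b.ir_protein, overlap_min)
                  and _retained(a.ir_nucleic, b.ir_nucleic, overlap_min))
            if ok:
                cand.add((a.node_id, b.node_id))
    by_id = {n.node_id: n for n in nodes}
    final = set()
    for (a, c) in cand:
        if not any((a, b) in cand and (b, c) in cand for b in by_id):
            final.add((a, c, by_id[c].K - by_id[a].K))
    return final


def _multiset_contains(child, parent) -> bool:
    child = list(child)
    for token in parent:
        if token not in child:
            return False
        child.remove(token)
    return True


def _retained(p_ir: set, c_ir: set, overlap_min: float) -> bool:
    if not p_ir:
        return True
    return len(p_ir & c_ir) > overlap_min * len(p_ir)


def dag_edge_set(dag: AssemblyDAG) -> set[tuple[str, str, int]]:
    return set(dag.edges())
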