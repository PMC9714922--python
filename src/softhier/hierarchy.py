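"""Interaction-complexity nodes and the assembly DAG.

Within one sequence cluster, every crystallised copy of the chain is
annotated with its *partner signature*: one token per partner chain that
shares at least one interface residue with it (protein partners are
labelled by their own cluster representative, all nucleic partners
collapse onto a single ``NUC`` token, but each nucleic chain still counts
as one partner).  Structures with identical signatures whose interfaces
mutually overlap by more than 75 % are grouped into one node; a node with
K partners is linked to a descendant with K' > K partners when the
descendant's signature contains the parent's, more than 75 % of the
parent's interface is retained, and no third node fits between them.
Edges therefore strictly increase K, which makes the graph acyclic; the
edge label k = K' - K is the number of partners gained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .interfaces import InterfaceAnnotation
from .structures import ComplexRecord

NUC_TOKEN = "NUC"
OVERLAP_MIN = 0.75  # strict: boundary exactly 0.75 fails

Signature = tuple[str, ...]  # sorted partner tokens (multiset)


@dataclass
class StructureAnnotation:
    """One cluster member's annotations, in representative coordinates."""

    structure_id: str           # "<entry>_<chain>"
    entry_id: str
    signature: Signature
    ir_protein: set[int]
    ir_nucleic: set[int]
    high_b: set[int]
    missing: set[int]           # SEQRES positions unobserved (mapped to rep)
    observed: set[int]          # mapped observed positions

    @property
    def K(self) -> int:
        return len(self.signature)


@dataclass
class HierNode:
    """A set of structures with identical interaction complexity."""

    node_id: str
    members: list[StructureAnnotation]
    signature: Signature
    ir_protein: set[int] = field(default_factory=set)
    ir_nucleic: set[int] = field(default_factory=set)
    sdr: set[int] = field(default_factory=set)
    always_missing: set[int] = field(default_factory=set)

    @property
    def K(self) -> int:
        return len(self.signature)

    @property
    def member_ids(self) -> list[str]:
        return [m.structure_id for m in self.members]

    def ir(self, interface_type: str | None = None) -> set[int]:
        if interface_type == "protein":
            return set(self.ir_protein)
        if interface_type == "nucleic":
            return set(self.ir_nucleic)
        return self.ir_protein | self.ir_nucleic

    def missing_in_all(self) -> set[int]:
        """Positions unobserved in every structure of the node."""
        return set.intersection(*(m.missing for m in self.members))


@dataclass
class AssemblyDAG:
    """Nodes plus directed edges labelled k = K_child - K_parent."""

    nodes: dict[str, HierNode]
    graph: nx.DiGraph

    @property
    def roots(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.in_degree(n) == 0)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.out_degree(n) == 0)

    def edges(self) -> list[tuple[str, str, int]]:
        return sorted((u, v, d["k"]) for u, v, d in self.graph.edges(data=True))

    def descendants(self, node_id: str) -> set[str]:
        if node_id not in self.graph:
            raise KeyError(f"node {node_id!r} not in DAG")
        return nx.descendants(self.graph, node_id)

    def always_missing_dagwide(self) -> set[int]:
        """Positions unobserved in every structure of the whole DAG."""
        sets = [m.missing for node in self.nodes.values() for m in node.members]
        return set.intersection(*sets) if sets else set()


def partner_signature(
    complex_record: ComplexRecord,
    chain_id: str,
    cluster_of: dict[str, str],
    protein_ir: InterfaceAnnotation,
    nucleic_ir: InterfaceAnnotation,
) -> Signature:
    """Partner tokens of one chain in one structure.

    One token per partner chain sharing >= 1 interface residue with the
    query chain; protein tokens are the partner's cluster representative
    id, every nucleic partner contributes one ``NUC`` token.
    """
    tokens: list[str] = []
    for partner, residues in protein_ir.by_partner.items():
        if not residues:
            continue
        member_id = f"{complex_record.entry_id}_{partner}"
        tokens.append(cluster_of.get(member_id, member_id))
    for partner, residues in nucleic_ir.by_partner.items():
        if residues:
            tokens.append(NUC_TOKEN)
    return tuple(sorted(tokens))


def _overlap_ok(irs: list[set[int]], overlap_min: float = OVERLAP_MIN) -> bool:
    """Rule (ii): joint intersection > 75 % of each non-empty IR."""
    non_empty = [s for s in irs if s]
    if len(non_empty) <= 1:
        return True
    joint = set.intersection(*non_empty)
    return all(len(joint) > overlap_min * len(s) for s in non_empty)


def _group_overlap_ok(members: list[StructureAnnotation],
                      overlap_min: float = OVERLAP_MIN) -> bool:
    return (_overlap_ok([m.ir_protein for m in members], overlap_min)
            and _overlap_ok([m.ir_nucleic for m in members], overlap_min))


def group_nodes(annotations: list[StructureAnnotation],
                overlap_min: float = OVERLAP_MIN) -> list[HierNode]:
    """Partition cluster members into interaction-complexity nodes.

    Members are grouped greedily in canonical (structure_id) order within
    each signature class; a member joins the first group whose joint
    interface intersection stays above 75 % of every member's interface,
    per interface type.  The whole group is re-verified after grouping.
    """
    by_sig: dict[Signature, list[StructureAnnotation]] = {}
    for ann in sorted(annotations, key=lambda a: a.structure_id):
        by_sig.setdefault(ann.signature, []).append(ann)

    nodes: list[HierNode] = []
    for sig in sorted(by_sig):
        groups: list[list[StructureAnnotation]] = []
        for ann in by_sig[sig]:
            placed = False
            for grp in groups:
                if _group_overlap_ok(grp + [ann], overlap_min):
                    grp.append(ann)
                    placed = True
                    break
            if not placed:
                groups.append([ann])
        for grp in groups:
            assert _group_overlap_ok(grp, overlap_min), \
                "node grouping failed verification"
            nodes.append(_make_node(grp, sig))

    nodes.sort(key=lambda n: (n.K, n.signature, n.member_ids[0]))
    for i, node in enumerate(nodes):
        node.node_id = f"n{node.K}_{i}"
    return nodes


def _make_node(members: list[StructureAnnotation], sig: Signature) -> HierNode:
    ir_p = set().union(*(m.ir_protein for m in members))
    ir_n = set().union(*(m.ir_nucleic for m in members))
    high_b = set().union(*(m.high_b for m in members))
    missing_union = set().union(*(m.missing for m in members))
    always = set.intersection(*(m.missing for m in members))
    return HierNode(
        node_id="",
        members=members,
        signature=sig,
        ir_protein=ir_p,
        ir_nucleic=ir_n,
        sdr=high_b | missing_union,
        always_missing=always,
    )


def _signature_contains(child: Signature, parent: Signature) -> bool:
    return not (Counter(parent) - Counter(child))


def _ir_retained(parent: HierNode, child: HierNode,
                 overlap_min: float = OVERLAP_MIN) -> bool:
    for p_ir, c_ir in ((parent.ir_protein, child.ir_protein),
                       (parent.ir_nucleic, child.ir_nucleic)):
        if p_ir and not len(p_ir & c_ir) > overlap_min * len(p_ir):
            return False
    return True


def candidate_edge(parent: HierNode, child: HierNode,
                   overlap_min: float = OVERLAP_MIN) -> bool:
    """The three edge conditions, before intermediate removal."""
    return (child.K > parent.K
            and _signature_contains(child.signature, parent.signature)
            and _ir_retained(parent, child, overlap_min))


def build_edges(nodes: list[HierNode],
                overlap_min: float = OVERLAP_MIN) -> AssemblyDAG:
    """Wire nodes into the assembly DAG.

    Candidate edges satisfy the K-increase, signature-inclusion and 75 %
    IR-retention conditions; a candidate (A, C) is discarded whenever some
    node B has candidate edges (A, B) and (B, C) — no third node may fit
    between two connected nodes.
    """
    g = nx.DiGraph()
    for node in nodes:
        g.add_node(node.node_id, K=node.K)
    cand: set[tuple[str, str]] = set()
    for a in nodes:
        for b in nodes:
            if a is not b and candidate_edge(a, b, overlap_min):
                cand.add((a.node_id, b.node_id))
    by_id = {n.node_id: n for n in nodes}
    for a, c in sorted(cand):
        has_mid = any((a, b) in cand and (b, c) in cand
                      for b in by_id if b not in (a, c))
        if not has_mid:
            g.add_edge(a, c, k=by_id[c].K - by_id[a].K)
    return AssemblyDAG(nodes=by_id, graph=g)


def shell_union(
    dag: AssemblyDAG,
    origin: str,
    depth: int | None = None,
    interface_type: str | None = None,
) -> set[int]:
    """Union of descendant IRs within ``depth`` added partners.

    ``depth=None`` means the all-shell (every descendant).  The *new* IR
    relative to the origin is this union minus the origin's own IR.
    """
    origin_node = dag.nodes[origin] if origin in dag.nodes else None
    if origin_node is None:
        raise KeyError(f"node {origin!r} not in DAG")
    out: set[int] = set()
    for desc in dag.descendants(origin):
        node = dag.nodes[desc]
        if depth is None or node.K <= origin_node.K + depth:
            out |= node.ir(interface_type)
    return out


def shell_nodes(dag: AssemblyDAG, origin: str, depth: int | None = None) -> list[HierNode]:
    """Descendant nodes within ``depth`` added partners (None = all)."""
    origin_node = dag.nodes[origin]
    return [dag.nodes[d] for d in sorted(dag.descendants(origin))
            if depth is None or dag.nodes[d].K <= origin_node.K + depth]


def edge_pairs(dag: AssemblyDAG):
    """Yield (parent, child, new_ir, k) for every DAG edge.

    ``new_ir`` is the child's union IR minus the parent's (both types).
    """
    for u, v, k in dag.edges():
        parent, child = dag.nodes[u], dag.nodes[v]
        yield parent, child, child.ir() - parent.ir(), k


def write_dag_tsv(dag: AssemblyDAG, nodes_path: str | Path,
                  edges_path: str | Path) -> None:
    with open(nodes_path, "w", newline="") as fh:
        fh.write("node_id\tK\tsignature\tmembers\n")
        for nid in sorted(dag.nodes):
            n = dag.nodes[nid]
            fh.write(f"{nid}\t{n.K}\t{','.join(n.signature)}\t"
                     f"{','.join(n.member_ids)}\n")
    with open(edges_path, "w", newline="") as fh:
        fh.write("parent\tchild\tk\n")
        for u, v, k in dag.edges():
            fh.write(f"{u}\t{v}\t{k}\n")


def dag_to_dot(dag: AssemblyDAG) -> str:
    """Minimal DOT export for visual inspection."""
    lines = ["digraph assembly {"]
    for nid in sorted(dag.nodes):
        n = dag.nodes[nid]
        lines.append(f'  "{nid}" [label="{nid}\\nK={n.K}"];')
    for u, v, k in dag.edges():
        lines.append(f'  "{u}" -> "{v}" [label="+{k}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
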