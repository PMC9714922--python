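"""Node grouping, DAG edge rules, shell queries — with a brute-force oracle."""

import numpy as np
import pytest

from softhier.hierarchy import (StructureAnnotation, build_edges, edge_pairs,
                                group_nodes, partner_signature, shell_union)
from softhier.interfaces import nucleic_interface, protein_interface
from softhier.synthetic import random_abstract_nodes

from helpers import (abstract_node, brute_force_edges, dag_edge_set,
                     line_chain, make_complex)


def _ann(sid, signature, ir_protein=(), ir_nucleic=(), high_b=(), missing=(),
         observed=None):
    return StructureAnnotation(
        structure_id=sid, entry_id=sid.rsplit("_", 1)[0],
        signature=tuple(sorted(signature)),
        ir_protein=set(ir_protein), ir_nucleic=set(ir_nucleic),
        high_b=set(high_b), missing=set(missing),
        observed=set(observed) if observed is not None else set(range(1, 41)))


# ---------------------------------------------------------------- signatures

def test_signature_protein_plus_dna_gives_k2():
    """A protein partner and one DNA chain: tokens {cluster, NUC}, K = 2."""
    a = line_chain(8, chain="A")
    b = line_chain(8, chain="B", origin=(0, 4, 0))
    n = line_chain(4, chain="N", origin=(0, -3.5, 0), molecule_type="nucleic")
    cx = make_complex("x", a, b, n)
    sig = partner_signature(
        cx, "A", {"x_B": "c1"},
        protein_interface(cx, "A"), nucleic_interface(cx, "A", n_points=400))
    assert sig == ("NUC", "c1")
    assert len(sig) == 2


def test_signature_unbound_is_empty():
    a = line_chain(8, chain="A")
    b = line_chain(8, chain="B", origin=(0, 100, 0))
    cx = make_complex("x", a, b)
    sig = partner_signature(cx, "A", {"x_B": "c1"},
                            protein_interface(cx, "A"),
                            nucleic_interface(cx, "A"))
    assert sig == ()


def test_signature_homodimer_counts_own_cluster_once():
    a = line_chain(8, chain="A")
    b = line_chain(8, chain="B", origin=(0, 4, 0))
    cx = make_complex("x", a, b)
    sig = partner_signature(cx, "A", {"x_A": "self", "x_B": "self"},
                            protein_interface(cx, "A"),
                            nucleic_interface(cx, "A"))
    assert sig == ("self",)


def test_signature_two_copies_of_same_partner_give_k2():
    """Multiset semantics: the same partner bound at two sites counts twice."""
    a = line_chain(12, chain="A")
    b = line_chain(3, chain="B", origin=(0, 4, 0))
    c = line_chain(3, chain="C", origin=(3.8 * 9, 4, 0))
    cx = make_complex("x", a, b, c)
    sig = partner_signature(cx, "A", {"x_B": "c1", "x_C": "c1"},
                            protein_interface(cx, "A"),
                            nucleic_interface(cx, "A"))
    assert sig == ("c1", "c1")


# ------------------------------------------------------------- node grouping

def test_same_signature_same_ir_one_node():
    nodes = group_nodes([_ann("a_A", ("c1",), ir_protein={1, 2, 3, 4}),
                         _ann("b_A", ("c1",), ir_protein={1, 2, 3, 4})])
    assert len(nodes) == 1
    assert nodes[0].member_ids == ["a_A", "b_A"]


def test_half_overlapping_irs_split_nodes():
    nodes = group_nodes([_ann("a_A", ("c1",), ir_protein={1, 2, 3, 4}),
                         _ann("b_A", ("c1",), ir_protein={3, 4, 5, 6})])
    assert len(nodes) == 2


def test_exactly_75_percent_overlap_fails_strict_rule():
    nodes = group_nodes([_ann("a_A", ("c1",), ir_protein={1, 2, 3, 4}),
                         _ann("b_A", ("c1",), ir_protein={1, 2, 3, 5})])
    assert len(nodes) == 2  # 3/4 retained is not > 0.75


def test_different_signatures_split_nodes():
    nodes = group_nodes([_ann("a_A", ("c1",), ir_protein={1, 2, 3, 4}),
                         _ann("b_A", ("c2",), ir_protein={1, 2, 3, 4})])
    assert len(nodes) == 2


def test_protein_and_nucleic_irs_checked_separately():
    """Identical protein IRs but disjoint nucleic IRs: rule (ii) fails on
    the nucleic track."""
    nodes = group_nodes([
        _ann("a_A", ("NUC", "c1"), ir_protein={1, 2, 3, 4}, ir_nucleic={10, 11}),
        _ann("b_A", ("NUC", "c1"), ir_protein={1, 2, 3, 4}, ir_nucleic={20, 21}),
    ])
    assert len(nodes) == 2


def test_node_unions_and_always_missing():
    nodes = group_nodes([
        _ann("a_A", ("c1",), ir_protein={1, 2, 3, 4}, high_b={8}, missing={20, 21}),
        _ann("b_A", ("c1",), ir_protein={1, 2, 3, 4}, high_b={9}, missing={21, 22}),
    ])
    node = nodes[0]
    assert node.sdr == {8, 9, 20, 21, 22}
    assert node.always_missing == {21}
    assert node.missing_in_all() == {21}


# ------------------------------------------------------------------- edges

def test_three_level_path_has_no_shortcut():
    """K = 0 → 1 → 2 with all pairwise conditions true wires 0→1→2 only."""
    n0 = abstract_node("n0", (), ir_protein=set())
    n1 = abstract_node("n1", ("p1",), ir_protein={1, 2, 3, 4})
    n2 = abstract_node("n2", ("p1", "p2"), ir_protein={1, 2, 3, 4, 8, 9})
    dag = build_edges([n0, n1, n2])
    assert dag_edge_set(dag) == {("n0", "n1", 1), ("n1", "n2", 1)}
    assert dag.roots == ["n0"] and dag.leaves == ["n2"]


def test_missing_partner_token_blocks_edge():
    n1 = abstract_node("n1", ("p1",), ir_protein={1, 2})
    n2 = abstract_node("n2", ("p2", "p3"), ir_protein={1, 2, 5})
    assert dag_edge_set(build_edges([n1, n2])) == set()


def test_insufficient_ir_retention_blocks_edge():
    n1 = abstract_node("n1", ("p1",), ir_protein={1, 2, 3, 4, 5})
    n2 = abstract_node("n2", ("p1", "p2"), ir_protein={1, 2, 3, 10, 11})
    assert dag_edge_set(build_edges([n1, n2])) == set()  # 60 % retained


def test_empty_parent_ir_vacuously_retained():
    n0 = abstract_node("n0", ())
    n1 = abstract_node("n1", ("p1",), ir_protein={4, 5})
    assert dag_edge_set(build_edges([n0, n1])) == {("n0", "n1", 1)}


def test_edges_match_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(1234)
    for _ in range(30):
        nodes = random_abstract_nodes(rng)
        got = dag_edge_set(build_edges(nodes))
        want = brute_force_edges(nodes)
        assert got == want


def test_dag_is_acyclic_with_strict_k_increase():
    import networkx as nx
    rng = np.random.default_rng(77)
    for _ in range(20):
        dag = build_edges(random_abstract_nodes(rng))
        assert nx.is_directed_acyclic_graph(dag.graph)
        for u, v, k in dag.edges():
            assert k == dag.nodes[v].K - dag.nodes[u].K >= 1


# ------------------------------------------------------------------- shells

def _diamond():
    n0 = abstract_node("n0", (), sdr={30})
    n1a = abstract_node("n1a", ("p1",), ir_protein={10, 11})
    n1b = abstract_node("n1b", ("p2",), ir_protein={20, 21})
    n2 = abstract_node("n2", ("p1", "p2"), ir_protein={10, 11, 20, 21, 25})
    return [n0, n1a, n1b, n2], build_edges([n0, n1a, n1b, n2])


def test_leaf_shell_is_empty():
    _, dag = _diamond()
    assert shell_union(dag, "n2", None) == set()


def test_one_shell_unions_both_children():
    _, dag = _diamond()
    new_ir = shell_union(dag, "n0", 1) - dag.nodes["n0"].ir()
    assert new_ir == {10, 11, 20, 21}


def test_shells_are_nested_in_depth():
    _, dag = _diamond()
    shells = [shell_union(dag, "n0", k) for k in (1, 2)]
    all_shell = shell_union(dag, "n0", None)
    assert shells[0] <= shells[1] <= all_shell
    assert all_shell == {10, 11, 20, 21, 25}


def test_edge_pairs_new_ir_and_count():
    nodes, dag = _diamond()
    pairs = list(edge_pairs(dag))
    assert len(pairs) == len(dag.edges())
    for parent, child, new_ir, k in pairs:
        assert new_ir == child.ir() - parent.ir()
    by_child = {c.node_id: new for _, c, new, _ in pairs}
    assert by_child["n1a"] == {10, 11}
    # child that only repeats the parent IR plus one residue
    n1 = abstract_node("m1", ("p1",), ir_protein={1, 2})
    n2 = abstract_node("m2", ("p1", "p2"), ir_protein={1, 2, 42})
    d2 = build_edges([n1, n2])
    (_, _, new_ir, _), = list(edge_pairs(d2))
    assert new_ir == {42}


def test_shell_query_on_unknown_node_raises():
    _, dag = _diamond()
    with pytest.raises(KeyError):
        shell_union(dag, "nope", 1)
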