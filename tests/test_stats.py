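"""Confusion metrics, random baselines, universes, bootstrap, LCR."""

import itertools
import math

import numpy as np
import pytest

from softhier.stats import (ConfusionCounts, aggregate, bootstrap_ci,
                            confusion, fraction_above_diagonal,
                            low_confidence_region, metrics)
from softhier.stats import test_universe as universe_for

from helpers import abstract_node


def naive_confusion(sdr, new_ir, universe):
    """Independent oracle: literal per-residue counting."""
    tp = fp = fn = tn = 0
    for pos in universe:
        in_sdr, in_ir = pos in sdr, pos in new_ir
        if in_sdr and in_ir:
            tp += 1
        elif in_sdr:
            fp += 1
        elif in_ir:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


# ------------------------------------------------------------- confusion

@pytest.mark.parametrize("sdr,new_ir,expect", [
    ({1, 2, 3, 4}, {3, 4, 5}, (2, 2, 1, 5)),
    ({2, 3}, {2, 3}, (2, 0, 0, 8)),
    ({1, 2}, {8, 9}, (0, 2, 2, 6)),
])
def test_confusion_counts(sdr, new_ir, expect):
    universe = set(range(1, 11))
    c = confusion(sdr, new_ir, universe)
    assert (c.TP, c.FP, c.FN, c.TN) == expect
    assert c.L == len(universe)


def test_confusion_restricts_sets_to_universe():
    c = confusion({1, 2, 99}, {2, 98}, set(range(1, 11)))
    assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 0, 8)


def test_confusion_equals_naive_counting_exhaustively_small():
    """All (sdr, new_ir) subset pairs on a universe of size 5."""
    universe = set(range(1, 6))
    subsets = [set(c) for r in range(6)
               for c in itertools.combinations(universe, r)]
    for sdr in subsets:
        for new_ir in subsets:
            c = confusion(sdr, new_ir, universe)
            assert (c.TP, c.FP, c.FN, c.TN) == naive_confusion(sdr, new_ir, universe)


# --------------------------------------------------------------- metrics

def test_metric_formulas_direct():
    m = metrics(ConfusionCounts(3, 1, 2, 4), N_D=4, N_I=5, L=10)
    assert m.Sen == pytest.approx(0.6)
    assert m.Spe == pytest.approx(0.8)
    assert m.Acc == pytest.approx(0.7)
    assert m.PPV == pytest.approx(0.75)
    assert m.NPV == pytest.approx(2 / 3)


def test_random_expectation_closed_forms():
    m = metrics(ConfusionCounts(0, 0, 0, 10), N_D=2, N_I=1, L=10)
    assert (m.Sen_r, m.Spe_r, m.PPV_r, m.NPV_r) == (0.2, 0.8, 0.1, 0.9)
    assert m.Acc_r == pytest.approx(0.2 * (2 * 0.1 - 1) + (1 - 0.1))  # 0.74


def test_random_accuracy_collapses_at_half_interface():
    """r_I = 1/2 makes Acc_r = 1/2 for every disorder rate."""
    for n_d in range(0, 11):
        m = metrics(ConfusionCounts(0, 0, 0, 10), N_D=n_d, N_I=5, L=10)
        assert m.Acc_r == pytest.approx(0.5)


def test_zero_denominators_flagged_nan():
    m = metrics(ConfusionCounts(0, 0, 0, 10), N_D=0, N_I=0, L=10)
    assert math.isnan(m.Sen) and math.isnan(m.PPV)
    assert m.Spe == 1.0 and m.NPV == 1.0


def test_random_expectation_identities_exact():
    rng = np.random.default_rng(0)
    for _ in range(50):
        L = int(rng.integers(5, 50))
        n_d, n_i = int(rng.integers(0, L)), int(rng.integers(0, L))
        m = metrics(ConfusionCounts(0, 0, 0, L), N_D=n_d, N_I=n_i, L=L)
        assert m.Sen_r + m.Spe_r == 1.0
        assert m.PPV_r + m.NPV_r == 1.0


# ------------------------------------------------------------- universes

def _parent(sdr=(), ir=(), K=1):
    node = abstract_node("par", tuple(f"p{i}" for i in range(K)),
                         ir_protein=set(ir), sdr=set(sdr))
    return node


def test_universe_c_all_is_full_range_minus_unknowable():
    parent = _parent(ir={1, 2})
    full = set(range(1, 21))
    assert universe_for(parent, set(), "C_all", full) == full
    assert universe_for(parent, {7}, "C_all", full) == full - {7}


@pytest.mark.parametrize("restriction", ["C_all", "C_minus_IR", "S_all",
                                         "S_minus_IR"])
def test_offspring_missing_excluded_everywhere(restriction):
    parent = _parent(ir={1, 2})
    full = set(range(1, 21))
    got = universe_for(parent, {7}, restriction, full, surface=full)
    assert 7 not in got


def test_universe_set_algebra():
    parent = _parent(ir={1, 2, 3})
    full = set(range(1, 21))
    surface = set(range(1, 11))
    assert (universe_for(parent, set(), "S_minus_IR", full, surface)
            == surface - {1, 2, 3})
    assert (universe_for(parent, set(), "C_minus_IR", full)
            == full - {1, 2, 3})


def test_universe_nesting():
    parent = _parent(ir={1, 2, 3})
    full = set(range(1, 31))
    surface = set(range(1, 16))
    u = {r: universe_for(parent, {9}, r, full, surface)
         for r in ("C_all", "C_minus_IR", "S_all", "S_minus_IR")}
    assert u["S_minus_IR"] <= u["S_all"] <= u["C_all"]
    assert u["C_minus_IR"] <= u["C_all"]


def test_dag_always_missing_never_enters_universe():
    parent = _parent()
    full = set(range(1, 21))
    got = universe_for(parent, set(), "C_all", full,
                        dag_always_missing={19, 20})
    assert got == full - {19, 20}


def test_surface_required_for_s_restrictions():
    with pytest.raises(ValueError):
        universe_for(_parent(), set(), "S_all", set(range(1, 10)))


# ------------------------------------------------- diagonal & aggregation

def test_fraction_above_diagonal_strict():
    perfect = metrics(ConfusionCounts(5, 0, 0, 5), 5, 5, 10)
    diag = metrics(ConfusionCounts(1, 4, 4, 16), 5, 5, 25)  # Sen=0.2=1-Spe
    from softhier.stats import PredictionRecord

    def rec(m):
        return PredictionRecord("c", "n", "edge", "C_all", 0, 1,
                                ConfusionCounts(0, 0, 0, 1), m)
    assert fraction_above_diagonal([rec(perfect)] * 3) == 1.0
    assert fraction_above_diagonal([rec(diag)]) == 0.0
    assert fraction_above_diagonal([rec(perfect), rec(diag)]) == 0.5


def test_aggregate_single_and_mean():
    from softhier.stats import PredictionRecord

    def rec(tp, fp, fn, tn, K=1):
        c = ConfusionCounts(tp, fp, fn, tn)
        return PredictionRecord("c", "n", "edge", "C_all", K, 1, c,
                                metrics(c, tp + fp, tp + fn, c.L))
    one = aggregate([rec(3, 1, 2, 4)], group_by="all", seed=0)
    assert one["Sen"].iloc[0] == pytest.approx(0.6)
    assert int(one["n"].iloc[0]) == 1
    two = aggregate([rec(2, 0, 3, 5), rec(3, 0, 2, 5)], group_by="all", seed=0)
    assert two["Sen"].iloc[0] == pytest.approx(0.5)
    # Spe == 1 makes the Sen/(1-Spe) ratio undefined: dropped from the
    # ratio mean while still counted elsewhere
    assert math.isnan(two["Sen_over_1mSpe"].iloc[0])
    assert int(two["n"].iloc[0]) == 2


def test_aggregate_group_by_k():
    from softhier.stats import PredictionRecord

    def rec(sen_tp, K):
        c = ConfusionCounts(sen_tp, 0, 10 - sen_tp, 10)
        return PredictionRecord("c", "n", "edge", "C_all", K, 1, c,
                                metrics(c, sen_tp, 10, c.L))
    df = aggregate([rec(2, 0), rec(4, 0), rec(10, 1)], group_by="K", seed=0)
    assert df.set_index("K").loc[0, "Sen"] == pytest.approx(0.3)
    assert df.set_index("K").loc[1, "Sen"] == pytest.approx(1.0)


# -------------------------------------------------------------- bootstrap

def test_bootstrap_constant_values_zero_width():
    lo, hi = bootstrap_ci([2.5] * 20, rng=0)
    assert lo == hi == 2.5


def test_bootstrap_seeded_determinism():
    vals = np.random.default_rng(4).normal(size=50)
    assert bootstrap_ci(vals, rng=123) == bootstrap_ci(vals, rng=123)
    assert bootstrap_ci(vals, rng=123) != bootstrap_ci(vals, rng=124)


def test_bootstrap_needs_two_values():
    with pytest.raises(ValueError):
        bootstrap_ci([1.0])


# ------------------------------------------------------------------- LCR

def test_lcr_below_model_mean():
    assert low_confidence_region([[90, 90, 50]]) == {3}


def test_lcr_constant_profile_empty():
    assert low_confidence_region([[70, 70, 70, 70]]) == set()


def test_lcr_union_across_models():
    m_a = [50, 90, 90, 90, 90, 90, 90]   # flags residue 1
    m_b = [90, 90, 90, 90, 90, 90, 50]   # flags residue 7
    assert low_confidence_region([m_a, m_b]) == {1, 7}


def test_lcr_length_mismatch_raises():
    with pytest.raises(ValueError):
        low_confidence_region([[90, 80], [90, 80, 70]])


# ------------------------------------------------- shell monotonicity law

def test_tp_fp_ppv_monotone_under_growing_new_ir():
    """With a fixed SDR and universe, nested new-IR sets (growing shells)
    give non-decreasing TP, non-increasing FP, non-decreasing PPV."""
    rng = np.random.default_rng(21)
    universe = set(range(1, 101))
    for _ in range(20):
        sdr = set(rng.choice(100, size=25, replace=False) + 1)
        shells = []
        acc = set()
        for _ in range(4):
            acc = acc | set(rng.choice(100, size=10, replace=False) + 1)
            shells.append(set(acc))
        prev_tp, prev_fp = -1, 10 ** 9
        prev_ppv = -1.0
        for new_ir in shells:
            c = confusion(sdr, new_ir, universe)
            assert c.TP >= prev_tp
            assert c.FP <= prev_fp
            ppv = c.TP / (c.TP + c.FP)
            assert ppv >= prev_ppv - 1e-12
            prev_tp, prev_fp, prev_ppv = c.TP, c.FP, ppv
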