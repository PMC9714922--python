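"""Scoring soft disorder as a predictor of new interfaces.

A parent node's soft-disorder region (SDR) is scored against the *new*
interface residues (new IR) of its progeny — per direct descendant (edge
test), per union of descendants up to k added partners (k-shell test), or
over all descendants (all-shell test).  Per residue of a test universe:

    TP = SDR ∩ new IR     FP = SDR \\ new IR
    FN = new IR \\ SDR     TN = universe \\ (SDR ∪ new IR)

with Sen = TP/(TP+FN), Spe = TN/(FP+TN), Acc = (TP+TN)/L,
PPV = TP/(TP+FP), NPV = TN/(TN+FN).  A uniformly random placement of
N_D = |SDR ∩ U| positions in a universe of L = |U| residues containing
N_I = |new IR ∩ U| interface residues has expectations

    Sen_r = r_D,  Spe_r = 1-r_D,  PPV_r = r_I,  NPV_r = 1-r_I,
    Acc_r = r_D(2 r_I - 1) + (1 - r_I),     r_D = N_D/L,  r_I = N_I/L.

Universes: the whole representative chain (C all), the chain minus the
parent's interface (C-IR), the parent-complex surface (S all), or the
surface minus the parent interface (S-IR).  Positions unobserved in every
structure of the evaluation target are excluded (their interface status
is unknowable), as are positions unobserved in every structure of the
whole DAG (intrinsic disorder that never orders).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import AssemblyDAG, HierNode, shell_nodes

logger = logging.getLogger(__name__)

RESTRICTIONS = ("C_all", "C_minus_IR", "S_all", "S_minus_IR")
TESTS = ("edge", "k_shell", "all_shell")
METRIC_NAMES = ("Sen", "Spe", "Acc", "PPV", "NPV")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def L(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricSet:
    """Observed metrics plus their random-guess expectations.

    Undefined entries (zero denominators) are NaN and are dropped from
    aggregation rather than imputed.
    """

    Sen: float
    Spe: float
    Acc: float
    PPV: float
    NPV: float
    r_D: float
    r_I: float

    @property
    def Sen_r(self) -> float:
        return self.r_D

    @property
    def Spe_r(self) -> float:
        return 1.0 - self.r_D

    @property
    def PPV_r(self) -> float:
        return self.r_I

    @property
    def NPV_r(self) -> float:
        return 1.0 - self.r_I

    @property
    def Acc_r(self) -> float:
        return self.r_D * (2.0 * self.r_I - 1.0) + (1.0 - self.r_I)


@dataclass
class PredictionRecord:
    """One scored prediction instance."""

    cluster: str
    parent_node: str
    test: str              # edge | k_shell | all_shell
    restriction: str       # C_all | C_minus_IR | S_all | S_minus_IR
    K: int
    plus_k: int
    counts: ConfusionCounts
    metrics: MetricSet
    child_node: str | None = None


def test_universe(
    parent: HierNode,
    target_missing: set[int],
    restriction: str,
    all_positions: set[int],
    surface: set[int] | None = None,
    dag_always_missing: set[int] = frozenset(),
) -> set[int]:
    """Residue universe for one prediction test.

    Starts from every representative position, removes positions whose
    interface status in the evaluation target is unknowable
    (``target_missing``) and DAG-wide always-missing positions, then
    applies the restriction: minus the parent IR (``*_minus_IR``) and/or
    intersected with the parent-complex surface (``S_*``).
    """
    if restriction not in RESTRICTIONS:
        raise ValueError(f"unknown restriction {restriction!r}")
    universe = set(all_positions) - set(target_missing) - set(dag_always_missing)
    if restriction.startswith("S"):
        if surface is None:
            raise ValueError("surface set required for S_* restrictions")
        universe &= surface
    if restriction.endswith("minus_IR"):
        universe -= parent.ir()
    return universe


def confusion(sdr: set[int], new_ir: set[int], universe: set[int]) -> ConfusionCounts:
    """Per-residue confusion counts, after restricting both sets to the
    universe."""
    s = sdr & universe
    n = new_ir & universe
    tp = len(s & n)
    return ConfusionCounts(
        TP=tp,
        FP=len(s) - tp,
        FN=len(n) - tp,
        TN=len(universe) - len(s | n),
    )


def metrics(counts: ConfusionCounts, N_D: int, N_I: int, L: int) -> MetricSet:
    """Observed metrics and random expectations; NaN where undefined."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return MetricSet(
        Sen=ratio(counts.TP, counts.TP + counts.FN),
        Spe=ratio(counts.TN, counts.FP + counts.TN),
        Acc=ratio(counts.TP + counts.TN, L),
        PPV=ratio(counts.TP, counts.TP + counts.FP),
        NPV=ratio(counts.TN, counts.TN + counts.FN),
        r_D=N_D / L if L else math.nan,
        r_I=N_I / L if L else math.nan,
    )


def metrics_arrays(tp, fp, fn, tn) -> dict[str, np.ndarray]:
    """Vectorised metric formulas over arrays of confusion counts."""
    tp, fp, fn, tn = (np.asarray(x, dtype=float) for x in (tp, fp, fn, tn))
    L = tp + fp + fn + tn
    with np.errstate(divide="ignore", invalid="ignore"):
        return {
            "Sen": tp / (tp + fn),
            "Spe": tn / (fp + tn),
            "Acc": (tp + tn) / L,
            "PPV": tp / (tp + fp),
            "NPV": tn / (tn + fn),
        }


def score_prediction(
    *,
    cluster: str,
    parent: HierNode,
    test: str,
    restriction: str,
    plus_k: int,
    new_ir: set[int],
    target_missing: set[int],
    all_positions: set[int],
    surface: set[int] | None,
    dag_always_missing: set[int],
    child_node: str | None = None,
) -> PredictionRecord | None:
    universe = test_universe(parent, target_missing, restriction,
                             all_positions, surface, dag_always_missing)
    if not universe:
        logger.warning("%s %s/%s %s: empty universe, record skipped",
                       cluster, parent.node_id, child_node, restriction)
        return None
    counts = confusion(parent.sdr, new_ir, universe)
    L = len(universe)
    m = metrics(counts, N_D=len(parent.sdr & universe),
                N_I=len(new_ir & universe), L=L)
    return PredictionRecord(
        cluster=cluster, parent_node=parent.node_id, test=test,
        restriction=restriction, K=parent.K, plus_k=plus_k,
        counts=counts, metrics=m, child_node=child_node,
    )


def evaluate_cluster(
    dag: AssemblyDAG,
    rep_length: int,
    cluster_id: str = "",
    tests: tuple[str, ...] = TESTS,
    restrictions: tuple[str, ...] = ("C_all",),
    surface_by_node: dict[str, set[int]] | None = None,
) -> list[PredictionRecord]:
    """Score every requested test × restriction for every parent node.

    edge: one record per outgoing edge (target = that child's new IR);
    k_shell: one record per shell depth k with a non-empty shell;
    all_shell: one record per non-leaf parent.
    """
    for t in tests:
        if t not in TESTS:
            raise ValueError(f"unknown test {t!r}")
    all_positions = set(range(1, rep_length + 1))
    dag_missing = dag.always_missing_dagwide()
    surface_by_node = surface_by_node or {}
    records: list[PredictionRecord] = []

    for nid in sorted(dag.nodes):
        parent = dag.nodes[nid]
        surface = surface_by_node.get(nid)
        children = sorted(dag.graph.successors(nid))
        descendants = shell_nodes(dag, nid, None)
        if not descendants:
            continue
        max_depth = max(n.K for n in descendants) - parent.K

        targets: list[tuple[str, int, set[int], set[int], str | None]] = []
        if "edge" in tests:
            for cid in children:
                child = dag.nodes[cid]
                targets.append((
                    "edge", dag.graph.edges[nid, cid]["k"],
                    child.ir() - parent.ir(),
                    child.missing_in_all(),
                    cid,
                ))
        if "k_shell" in tests:
            for k in range(1, max_depth + 1):
                shell = shell_nodes(dag, nid, k)
                if not shell:
                    continue
                targets.append(("k_shell", k, *_shell_target(parent, shell), None))
        if "all_shell" in tests:
            targets.append(("all_shell", max_depth,
                            *_shell_target(parent, descendants), None))

        for test, plus_k, new_ir, target_missing, child_node in targets:
            for restriction in restrictions:
                rec = score_prediction(
                    cluster=cluster_id, parent=parent, test=test,
                    restriction=restriction, plus_k=plus_k, new_ir=new_ir,
                    target_missing=target_missing,
                    all_positions=all_positions, surface=surface,
                    dag_always_missing=dag_missing, child_node=child_node,
                )
                if rec is not None:
                    records.append(rec)
    return records


def _shell_target(parent: HierNode, shell: list[HierNode]) -> tuple[set[int], set[int]]:
    """(new IR, unknowable positions) for a shell of descendant nodes.

    A position is unknowable when it is unobserved in every structure of
    the shell and never interface within it.
    """
    shell_ir = set().union(*(n.ir() for n in shell))
    missing_all = set.intersection(*(m.missing for n in shell for m in n.members))
    return shell_ir - parent.ir(), missing_all - shell_ir


def fraction_above_diagonal(records: list[PredictionRecord]) -> float:
    """Fraction of predictions with Sen strictly above 1 - Spe.

    Exact ties sit on the diagonal and are not counted; a 1e-9 guard keeps
    floating-point dust in ``1 - Spe`` from promoting them.
    """
    defined = [(r.metrics.Sen, r.metrics.Spe) for r in records
               if not (math.isnan(r.metrics.Sen) or math.isnan(r.metrics.Spe))]
    if not defined:
        return math.nan
    return sum(sen - (1.0 - spe) > 1e-9 for sen, spe in defined) / len(defined)


def records_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "cluster": r.cluster, "parent_node": r.parent_node,
            "child_node": r.child_node or "", "test": r.test,
            "restriction": r.restriction, "K": r.K, "plus_k": r.plus_k,
            "TP": r.counts.TP, "FP": r.counts.FP,
            "FN": r.counts.FN, "TN": r.counts.TN,
        }
        m = r.metrics
        row.update(Sen=m.Sen, Spe=m.Spe, Acc=m.Acc, PPV=m.PPV, NPV=m.NPV,
                   Sen_r=m.Sen_r, Spe_r=m.Spe_r, Acc_r=m.Acc_r,
                   PPV_r=m.PPV_r, NPV_r=m.NPV_r)
        rows.append(row)
    columns = ["cluster", "parent_node", "child_node", "test", "restriction",
               "K", "plus_k", "TP", "FP", "FN", "TN",
               "Sen", "Spe", "Acc", "PPV", "NPV",
               "Sen_r", "Spe_r", "Acc_r", "PPV_r", "NPV_r"]
    return pd.DataFrame(rows, columns=columns)


def aggregate(
    records: list[PredictionRecord],
    group_by: str = "all",
    n_resamples: int = 500,
    level: float = 90.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group means of metrics, ratios and random counterparts.

    ``group_by`` is one of ``K``, ``plus_k``, ``K_plus_k``, ``all``.
    Undefined metrics are dropped per-column; the Sen/(1-Spe) and
    PPV/(1-NPV) ratios drop records where the denominator vanishes.
    Bootstrap confidence bounds of the mean Sen are attached as
    ``Sen_ci_low``/``Sen_ci_high``.
    """
    df = records_frame(records)
    if df.empty:
        return df
    with np.errstate(divide="ignore", invalid="ignore"):
        df["Sen_over_1mSpe"] = np.where(df["Spe"] < 1.0,
                                        df["Sen"] / (1.0 - df["Spe"]), np.nan)
        df["PPV_over_1mNPV"] = np.where(df["NPV"] < 1.0,
                                        df["PPV"] / (1.0 - df["NPV"]), np.nan)
    keys = {"K": ["K"], "plus_k": ["plus_k"], "K_plus_k": ["K", "plus_k"],
            "all": []}[group_by]
    value_cols = ["Sen", "Spe", "Acc", "PPV", "NPV",
                  "Sen_r", "Spe_r", "Acc_r", "PPV_r", "NPV_r",
                  "Sen_over_1mSpe", "PPV_over_1mNPV"]
    rng = np.random.default_rng(seed)
    groups = df.groupby(keys) if keys else [((), df)]
    rows = []
    for name, grp in groups:
        row: dict = {}
        if keys:
            name = name if isinstance(name, tuple) else (name,)
            row.update(dict(zip(keys, name)))
        row["n"] = len(grp)
        for col in value_cols:
            row[col] = grp[col].mean()
        sen = grp["Sen"].dropna().to_numpy()
        if len(sen) >= 2:
            lo, hi = bootstrap_ci(sen, n_resamples=n_resamples, level=level,
                                  rng=rng)
            row["Sen_ci_low"], row["Sen_ci_high"] = lo, hi
        else:
            row["Sen_ci_low"] = row["Sen_ci_high"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_ci(
    values,
    n_resamples: int = 500,
    level: float = 90.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (default 90 %, 500 resamples)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap_ci needs >= 2 values")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def low_confidence_region(plddt_models: list) -> set[int]:
    """Residues with pLDDT strictly below their model's chain mean, unioned
    across models (the AF2 low-confidence region, LCR)."""
    if not plddt_models:
        raise ValueError("need at least one pLDDT profile")
    arrays = [np.asarray(m, dtype=float) for m in plddt_models]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("pLDDT profiles must have equal length")
    lcr: set[int] = set()
    for a in arrays:
        lcr |= {int(i) + 1 for i in np.flatnonzero(a < a.mean())}
    return lcr
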