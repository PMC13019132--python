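"""Cohort-level plan comparison: DVH-parameter tables, paired Wilcoxon
signed-rank tests with Bonferroni correction, and MAE summaries.

The Wilcoxon test here is the exact paired test: zero differences are
dropped (Wilcoxon's original convention), absolute differences are
mid-ranked on ties, and for n ≤ 25 pairs the two-sided p-value comes from
the full sign-flip null distribution (dynamic programming over doubled
ranks, so half-integer mid-ranks stay exact).  Above n = 25 a normal
approximation with continuity correction and the tie-adjusted variance is
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .grids import DoseGrid, Prescription, StructureSet
from .metrics import MetricSpec, dvh_metric

__all__ = [
    "WilcoxonResult",
    "TestResult",
    "CohortTable",
    "wilcoxon_signed_rank",
    "exact_signflip_distribution",
    "bonferroni_level",
    "build_cohort_table",
    "compare_plans",
    "mae_summary",
]

EXACT_N_MAX = 25


class WilcoxonResult(NamedTuple):
    statistic: float  # min(W+, W-)
    pvalue: float
    n_used: int  # pairs after dropping zeros
    exact: bool
    degenerate: bool  # all differences were zero


@dataclass(frozen=True)
class TestResult:
    metric: str
    plan_pair: Tuple[str, str]
    statistic: float
    pvalue: float
    corrected_alpha: float
    significant: bool


def exact_signflip_distribution(ranks: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the positive-rank sum W+ under sign flips.

    Returns (support, counts) where support holds the achievable values of
    2·W+ (doubled so mid-ranks are integers) and counts the number of the
    2^n sign assignments achieving each value.
    """
    doubled = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(int)
    if np.any(np.abs(2.0 * np.asarray(ranks) - doubled) > 1e-9):
        raise ValueError("ranks must be integers or half-integers")
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return np.arange(total + 1), counts


def wilcoxon_signed_rank(diffs: Sequence[float]) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    All-zero differences give the degenerate p = 1.0.  The reported
    statistic is min(W+, W-).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one pair")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, True, True)

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_minus = total - w_plus
    stat = min(w_plus, w_minus)

    if n <= EXACT_N_MAX:
        support, counts = exact_signflip_distribution(ranks)
        n_assign = counts.sum()
        w2 = int(round(2.0 * w_plus))
        p_le = counts[: w2 + 1].sum() / n_assign
        p_ge = counts[w2:].sum() / n_assign
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(stat, float(p), n, True, False)

    mean = total / 2.0
    var = float(np.sum(ranks**2)) / 4.0  # tie-adjusted by construction
    delta = w_plus - mean
    z = (delta - np.sign(delta) * 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(stat, float(p), n, False, False)


def bonferroni_level(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha/m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


# ---------------------------------------------------------------------------
# cohort tables


#: A metric entry: structure name + the DVH parameter evaluated on it.
MetricEntry = Tuple[str, MetricSpec]


@dataclass
class CohortTable:
    """Per-case DVH parameters for several plan labels.

    ``data`` is indexed by case, with MultiIndex columns
    (plan label, metric label); missing structures leave NaN cells, which
    are excluded from downstream tests and flagged.
    """

    data: pd.DataFrame
    rx: Prescription
    metrics: List[MetricEntry]
    plan_labels: List[str]
    flagged: List[str] = field(default_factory=list)

    def metric_labels(self) -> List[str]:
        return [_metric_label(s, m) for s, m in self.metrics]


def _metric_label(structure: str, spec: MetricSpec) -> str:
    unit = {"Gy": "Gy", "%": "%", "%vol": "%"}[spec.unit]
    return f"{structure} {spec.label} [{unit}]"


def build_cohort_table(
    cases: Sequence[Tuple[Dict[str, DoseGrid], StructureSet]],
    metrics: Sequence[MetricEntry],
    rx: Prescription,
) -> CohortTable:
    """Evaluate every metric for every case and plan label.

    ``cases`` is a sequence of (dose-per-plan-label, structures); all cases
    must carry the same plan labels.  Cells for structures missing or empty
    in a case are NaN and flagged.
    """
    if not cases:
        raise ValueError("empty cohort")
    labels = sorted(cases[0][0].keys())
    if len(labels) < 2:
        raise ValueError("need at least two plan labels")
    for doses, _ in cases:
        if sorted(doses.keys()) != labels:
            raise ValueError("all cases must carry the same plan labels")

    columns = pd.MultiIndex.from_tuples(
        [(lab, _metric_label(s, m)) for lab in labels for s, m in metrics],
        names=["plan", "metric"],
    )
    rows = []
    flagged: List[str] = []
    for ci, (doses, structures) in enumerate(cases):
        row = []
        for lab in labels:
            for s, m in metrics:
                if s not in structures or not structures[s].occupancy.any():
                    flagged.append(f"case {ci}: structure {s!r} missing/empty")
                    row.append(np.nan)
                    continue
                row.append(dvh_metric(doses[lab], structures[s], m, rx))
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns, index=pd.RangeIndex(len(cases), name="case"))
    return CohortTable(df, rx, list(metrics), labels, flagged)


def compare_plans(
    table: CohortTable, reference: str, alpha: float = 0.05
) -> List[TestResult]:
    """Wilcoxon signed-rank tests of every plan against the reference.

    The Bonferroni correction divides alpha by the number of metrics
    (e.g. 0.05/12 ≈ 0.0042 for the standard 12-parameter panel).
    """
    if reference not in table.plan_labels:
        raise ValueError(f"reference label {reference!r} not in table")
    m = len(table.metrics)
    level = bonferroni_level(alpha, m)
    results: List[TestResult] = []
    for lab in table.plan_labels:
        if lab == reference:
            continue
        for metric in table.metric_labels():
            paired = pd.concat(
                [table.data[(lab, metric)], table.data[(reference, metric)]], axis=1
            ).dropna()
            diffs = (paired.iloc[:, 0] - paired.iloc[:, 1]).to_numpy()
            res = wilcoxon_signed_rank(diffs)
            results.append(
                TestResult(
                    metric=metric,
                    plan_pair=(lab, reference),
                    statistic=res.statistic,
                    pvalue=res.pvalue,
                    corrected_alpha=level,
                    significant=bool(res.pvalue < level),
                )
            )
    return results


def mae_summary(table: CohortTable, reference: str) -> pd.DataFrame:
    """Mean ± SD of |plan − reference| per metric, in the metric's unit."""
    if reference not in table.plan_labels:
        raise ValueError(f"reference label {reference!r} not in table")
    if len(table.data) < 1:
        raise ValueError("need at least one case")
    out = {}
    for lab in table.plan_labels:
        if lab == reference:
            continue
        for metric in table.metric_labels():
            err = (table.data[(lab, metric)] - table.data[(reference, metric)]).abs()
            out[(lab, metric)] = {"mae": err.mean(), "sd": err.std(ddof=1) if len(err) > 1 else 0.0}
    df = pd.DataFrame(out).T
    df.index.names = ["plan", "metric"]
    return df
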