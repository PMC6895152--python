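"""Across-sample statistics: normality screen, rank-sum test, SEM summaries.

Each imaged sample contributes one row of scalar metrics (whole-image F/B
median, inter-fibrillar F/B median, inter-fibrillar area fraction, circular
std of ϕ).  Groups (foetal vs adult) are compared metric by metric with the
Wilcoxon-Mann-Whitney rank-sum test — exact by enumeration for small
tie-free samples, normal approximation with tie correction otherwise.
Shapiro-Wilk normality p-values are reported alongside but gate nothing:
the comparison is always nonparametric.  No multiple-testing correction is
applied across metrics; reports carry a footer saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "METRICS",
    "normality_test",
    "rank_sum_test",
    "summarize_groups",
    "compare_all_metrics",
]

#: Per-sample metrics carried through cohort comparisons.
METRICS = ("fb_median_whole", "fb_median_interfib", "interfib_fraction",
           "circ_std_deg")

#: Largest combined sample size for which the exact rank-sum null is used.
EXACT_LIMIT = 12


@dataclass
class GroupComparison:
    """Two-group comparison of one metric."""

    metric: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sem1: float
    sem2: float
    W_p1: float
    W_p2: float
    U: float
    p: float
    significant: bool
    method: str = "exact"
    notes: list[str] = field(default_factory=list)


def _sem(values: np.ndarray) -> float:
    """Standard error of the mean with the n−1 (sample) std."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; NaN for degenerate samples.

    Requires 3 ≤ n ≤ 5000 (the published coefficient range); an all-equal
    sample has no testable distribution and reports (NaN, NaN).
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        return float("nan"), float("nan")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def rank_sum_test(group_a, group_b) -> tuple[float, float, str]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Returns (U, p, method) with U the rank-sum statistic of ``group_a``.
    The exact permutation null is used when n1+n2 ≤ 12 and there are no
    ties; otherwise the normal approximation with midrank tie correction
    (the exact null is not defined under ties).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_LIMIT and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue), "asymptotic"


def summarize_groups(rows: pd.DataFrame, metric: str, alpha: float = 0.05,
                     group_col: str = "group",
                     groups: tuple[str, str] = ("foetal", "adult")
                     ) -> GroupComparison:
    """Compare one metric between the two groups of a cohort table.

    ``rows`` has one row per imaged sample with a ``group`` column and the
    metric columns.  Means and SEMs describe each group; significance is
    the rank-sum p-value against ``alpha``.
    """
    if metric not in rows.columns:
        raise KeyError(f"metric {metric!r} missing from cohort table")
    g1 = rows.loc[rows[group_col] == groups[0], metric].to_numpy(dtype=float)
    g2 = rows.loc[rows[group_col] == groups[1], metric].to_numpy(dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if not (np.isfinite(g1).all() and np.isfinite(g2).all()):
        raise ValueError(f"non-finite values in metric {metric!r}")
    u, p, method = rank_sum_test(g1, g2)
    notes = []
    if method == "asymptotic" and g1.size + g2.size <= EXACT_LIMIT:
        notes.append("ties present: exact null unavailable, "
                     "normal approximation used")
    return GroupComparison(
        metric=metric, n1=g1.size, n2=g2.size,
        mean1=float(g1.mean()), mean2=float(g2.mean()),
        sem1=_sem(g1), sem2=_sem(g2),
        W_p1=normality_test(g1)[1] if g1.size >= 3 else float("nan"),
        W_p2=normality_test(g2)[1] if g2.size >= 3 else float("nan"),
        U=u, p=p, significant=bool(p < alpha), method=method, notes=notes)


def compare_all_metrics(rows: pd.DataFrame, alpha: float = 0.05,
                        metrics=METRICS, **kw) -> pd.DataFrame:
    """One GroupComparison per metric, as a tidy DataFrame."""
    comps = [summarize_groups(rows, m, alpha=alpha, **kw) for m in metrics]
    return pd.DataFrame([{
        "metric": c.metric, "n1": c.n1, "n2": c.n2,
        "mean1": c.mean1, "sem1": c.sem1, "mean2": c.mean2, "sem2": c.sem2,
        "shapiro_p1": c.W_p1, "shapiro_p2": c.W_p2,
        "U": c.U, "p": c.p, "significant": c.significant,
        "method": c.method} for c in comps])
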