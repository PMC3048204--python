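"""Group-comparison statistics for cohort composition and marker levels:
median/IQR summaries, Wilcoxon rank-sum (Mann-Whitney), Kruskal-Wallis,
Pearson chi-square and Student's t-test.

All tests are two-sided and return a :class:`TestResult`. Hypothesis testing
is delegated to scipy; this module fixes the conventions (exact vs
asymptotic switch for the rank-sum test, no continuity correction for
chi-square by default, pooled-variance t by default with a Welch flag) and
handles degenerate inputs explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "SummaryRow",
    "TestResult",
    "median_iqr",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "chi_square_2xk",
    "students_t",
    "students_t_from_stats",
    "pairwise_wilcoxon",
]

#: Combined sample size at or below which the rank-sum test is exact
#: (full enumeration, no ties). Exactness is cheap here; the standard
#: tie- and continuity-corrected normal approximation is used otherwise.
EXACT_RANKSUM_MAX_N = 10


@dataclass(frozen=True)
class SummaryRow:
    """Median and quartiles of one group, in the units of the input."""

    group: str
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must satisfy q1 <= median <= q3")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    test_name: str
    n_used: tuple[int, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def median_iqr(values, group: str = "") -> SummaryRow:
    """Median and quartiles by linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return SummaryRow(group=group, n=int(values.size), median=float(med), q1=float(q1), q3=float(q3))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most
    :data:`EXACT_RANKSUM_MAX_N` and there are no ties; otherwise normal
    approximation with tie correction and continuity correction. The
    statistic reported is the Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    if x.size + y.size <= EXACT_RANKSUM_MAX_N and no_ties:
        method, note = "exact", "exact enumeration"
    else:
        method, note = "asymptotic", "normal approximation, tie and continuity corrected"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        test_name="wilcoxon rank-sum",
        n_used=(int(x.size), int(y.size)),
        note=note,
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie corrected) across two or more groups;
    p from the chi-square distribution with k-1 degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    combined = np.concatenate(groups)
    if np.unique(combined).size == 1:
        # all observations identical: H is 0/0 under the tie correction;
        # defined as 0 with p = 1
        return TestResult(
            statistic=0.0,
            p=1.0,
            test_name="kruskal-wallis",
            n_used=tuple(int(g.size) for g in groups),
            note="all observations identical",
        )
    h, p = stats.kruskal(*groups)
    return TestResult(
        statistic=float(h),
        p=float(p),
        test_name="kruskal-wallis",
        n_used=tuple(int(g.size) for g in groups),
    )


def chi_square_2xk(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table.

    No continuity correction by default; pass ``continuity_correction=True``
    for the Yates-corrected 2x2 variant.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column must have a positive marginal total")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return TestResult(
        statistic=float(chi2),
        p=float(p),
        test_name="pearson chi-square" + (" (continuity corrected)" if continuity_correction else ""),
        n_used=tuple(int(t) for t in table.sum(axis=1)),
        note=f"df={dof}",
    )


def students_t(x, y, welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test, pooled variance by default (Welch by flag).

    Degenerate inputs (zero pooled variance) are resolved explicitly:
    equal means give t = 0, p = 1; unequal means give p = 0 with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    n_used = (int(x.size), int(y.size))
    name = "welch t" if welch else "student t (pooled variance)"
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, name, n_used, note="zero variance, equal means")
        return TestResult(math.inf, 0.0, name, n_used, note="zero variance, unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return TestResult(float(t), float(p), name, n_used)


def students_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, welch: bool = False
) -> TestResult:
    """Two-sample t-test from summary statistics (mean, sd, n per group)."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch)
    name = "welch t" if welch else "student t (pooled variance)"
    return TestResult(float(t), float(p), name, (int(n1), int(n2)), note="from summary statistics")


def pairwise_wilcoxon(
    groups: dict[str, "np.ndarray"], adjust: str | None = None
) -> dict[tuple[str, str], TestResult]:
    """Post-hoc pairwise rank-sum comparisons after a Kruskal-Wallis test.

    Unadjusted by default; ``adjust`` may be ``"bonferroni"`` or ``"holm"``.
    """
    pairs = list(combinations(groups, 2))
    results = {(a, b): wilcoxon_rank_sum(groups[a], groups[b]) for a, b in pairs}
    if adjust is None:
        return results
    names = list(results)
    pvals = np.array([results[k].p for k in names])
    m = len(pvals)
    if adjust == "bonferroni":
        adj = np.minimum(pvals * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return {
        k: TestResult(r.statistic, float(adj[i]), r.test_name, r.n_used, note=f"{adjust}-adjusted")
        for i, (k, r) in enumerate(results.items())
    }
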