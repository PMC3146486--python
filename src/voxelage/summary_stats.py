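"""Cohort-characteristics statistics.

Two-sample pooled-variance t-tests (from raw values or printed group
summaries), Pearson chi-square tests of independence without continuity
correction, and one-way ANOVA with Bonferroni-corrected pairwise
post-hocs. Pooled (Student) variance and uncorrected chi-square are used
because published cohort tables report ``df = n1 + n2 - 2`` and
correction-free chi-square values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateTable, ZeroVariance

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ChiSquareResult",
    "AnovaResult",
    "summarize",
    "t_from_summary",
    "t_from_raw",
    "chi_square_independence",
    "oneway_anova_bonferroni",
]


@dataclass(frozen=True)
class GroupSummary:
    """Count, mean and sample (n-1) standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_two_tailed: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class PairwiseT:
    i: int
    j: int
    t: float
    df: int
    p_bonferroni: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: tuple[PairwiseT, ...]


def summarize(values) -> GroupSummary:
    values = np.asarray(values, dtype=np.float64)
    return GroupSummary(n=len(values), mean=float(values.mean()), sd=float(values.std(ddof=1)))


def t_from_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Pooled-variance independent-samples t from group summaries.

    df = n_a + n_b - 2. When both SDs are zero: t = 0 by convention if the
    means agree (documented), :class:`ZeroVariance` otherwise.
    """
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled_var == 0.0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=df, p_two_tailed=1.0)
        raise ZeroVariance("both SDs are zero with unequal means")
    se = np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p_two_tailed=float(p))


def t_from_raw(x, y) -> TTestResult:
    """Pooled two-sample t from raw values (via the summary route)."""
    return t_from_summary(summarize(x), summarize(y))


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square for an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTable("zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p))


def _coerce_summaries(groups) -> list[GroupSummary]:
    out = []
    for g in groups:
        out.append(g if isinstance(g, GroupSummary) else summarize(g))
    return out


def oneway_anova_bonferroni(groups) -> AnovaResult:
    """One-way F from group summaries (or raw vectors), Bonferroni post-hocs.

    Classical between/within decomposition from counts, means and SDs;
    every pair gets a pooled two-sample t with its p multiplied by the
    number of comparisons (capped at 1).
    """
    summaries = _coerce_summaries(groups)
    k = len(summaries)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([s.n for s in summaries], dtype=np.float64)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_total = ns.sum()
    grand_mean = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand_mean) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = int(n_total) - k
    if df_within <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            raise ZeroVariance("zero within-group variance with unequal means")
    else:
        F = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(F, df_between, df_within))

    n_pairs = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            res = t_from_summary(summaries[i], summaries[j])
            pairwise.append(
                PairwiseT(
                    i=i,
                    j=j,
                    t=res.t,
                    df=res.df,
                    p_bonferroni=min(1.0, res.p_two_tailed * n_pairs),
                )
            )
    return AnovaResult(
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p=float(p),
        pairwise=tuple(pairwise),
    )
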