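"""Small-sample inferential tests for dominant-vs-submissive comparisons.

The workhorse is the Wilcoxon signed-rank test: with n <= 15 informative
pairs the exact null distribution is computed by full sign-flip
enumeration (correct under ties in the magnitudes, where the tabulated
distribution is not), and a normal approximation with tie and continuity
corrections is used beyond that. A z statistic is always reported so
results read like conventional "z = -3.92" summaries.

Families of comparisons are corrected with Bonferroni; the family has to
be declared explicitly — nothing here guesses which tests belong together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "apply_bonferroni",
    "kolmogorov_smirnov_normality",
    "kruskal_wallis",
    "one_way_anova_tukey",
    "paired_t",
    "pearson",
    "wilcoxon_signed_rank",
]

#: Largest n for which the exact Wilcoxon null is enumerated (2^15 terms).
EXACT_LIMIT = 15


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    z: float | None
    p: float
    n: int
    correction: str = "none"  # none | bonferroni
    p_adj: float | None = None
    degenerate: bool = False
    method: str | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


def _signed_rank_parts(differences: Sequence[float]):
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be one-dimensional")
    d = d[d != 0]  # conventional zero handling: drop before ranking
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d)) if n else np.array([])
    w_plus = float(ranks[d > 0].sum()) if n else 0.0
    return d, ranks, w_plus, n


def _wilcoxon_z(w_plus: float, ranks: np.ndarray, n: int) -> float:
    """Normal approximation z with tie and continuity corrections."""
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 0.0
    correction = 0.5 * np.sign(w_plus - mu)
    return float((w_plus - mu - correction) / math.sqrt(var))


def wilcoxon_signed_rank(differences: Sequence[float]) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking. For n <= 15 the two-sided
    p is exact — all 2^n sign assignments of the (mid)ranks are enumerated
    and p = min(1, 2·min(P(W+ <= w), P(W+ >= w))). Larger samples use the
    tie- and continuity-corrected normal approximation.

    All differences zero (or empty input) is degenerate: p = 1.
    """
    d, ranks, w_plus, n = _signed_rank_parts(differences)
    if n == 0:
        return TestResult(
            name="wilcoxon_signed_rank",
            statistic=0.0,
            z=0.0,
            p=1.0,
            n=0,
            degenerate=True,
            method="degenerate",
        )
    z = _wilcoxon_z(w_plus, ranks, n)
    if n <= EXACT_LIMIT:
        # distribution of W+ over all sign flips, by cumulative doubling
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        total = sums.size
        lower = int(np.count_nonzero(sums <= w_plus + 1e-9))
        upper = int(np.count_nonzero(sums >= w_plus - 1e-9))
        p = min(1.0, 2.0 * min(lower, upper) / total)
        method = "exact"
    else:
        p = float(2.0 * scipy.stats.norm.sf(abs(z)))
        method = "approx"
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=w_plus,
        z=z,
        p=p,
        n=n,
        method=method,
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired-samples t test (e.g. dominant vs submissive body weight)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = d.size
    if n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    if np.ptp(d) == 0 and d[0] == 0:
        return TestResult(
            name="paired_t", statistic=math.nan, z=None, p=math.nan, n=n,
            degenerate=True,
        )
    res = scipy.stats.ttest_rel(x, y)
    return TestResult(
        name="paired_t",
        statistic=float(res.statistic),
        z=float(res.statistic),
        p=float(res.pvalue),
        n=n,
        degenerate=bool(np.isnan(res.statistic)),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    res = scipy.stats.kruskal(*arrays)
    return TestResult(
        name="kruskal_wallis",
        statistic=float(res.statistic),
        z=None,
        p=float(res.pvalue),
        n=int(sum(a.size for a in arrays)),
    )


def one_way_anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA with Tukey HSD post-hoc comparisons.

    Returns the omnibus F-test and a table with one row per group pair
    (meandiff, p_adj, CI bounds, reject).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    res = scipy.stats.f_oneway(*arrays)
    omnibus = TestResult(
        name="one_way_anova",
        statistic=float(res.statistic),
        z=None,
        p=float(res.pvalue),
        n=int(sum(a.size for a in arrays)),
    )
    values = np.concatenate(arrays)
    group_ids = np.concatenate(
        [np.repeat(lbl, a.size) for lbl, a in zip(labels, arrays)]
    )
    tukey = pairwise_tukeyhsd(values, group_ids)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return omnibus, table


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson needs n >= 3")
    res = scipy.stats.pearsonr(x, y)
    return TestResult(
        name="pearson",
        statistic=float(res.statistic),
        z=None,
        p=float(res.pvalue),
        n=int(x.size),
    )


def kolmogorov_smirnov_normality(x: Sequence[float]) -> TestResult:
    """KS test against a normal with the sample's mean and SD.

    Gate for choosing parametric vs nonparametric comparisons: small p
    means the data look non-normal, so prefer rank-based tests.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult(
            name="ks_normality", statistic=math.nan, z=None, p=math.nan,
            n=int(x.size), degenerate=True,
        )
    res = scipy.stats.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(
        name="ks_normality",
        statistic=float(res.statistic),
        z=None,
        p=float(res.pvalue),
        n=int(x.size),
    )


def apply_bonferroni(
    results: Sequence[TestResult], m: int | None = None
) -> list[TestResult]:
    """Bonferroni-adjust a declared family: p_adj = min(1, m * p).

    ``m`` defaults to the family size. The family must be passed
    explicitly; tests are never grouped implicitly.
    """
    if m is None:
        m = len(results)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return [
        replace(
            r,
            correction="bonferroni",
            p_adj=r.p if math.isnan(r.p) else min(1.0, m * r.p),
        )
        for r in results
    ]


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """One row per comparison: test, statistic, z/t, p, p_adj, n."""
    return pd.DataFrame(
        [
            {
                "test": r.name,
                "statistic": r.statistic,
                "z_or_t": r.z,
                "p": r.p,
                "p_adj": r.p_adj,
                "n": r.n,
                "correction": r.correction,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
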