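"""Rank statistics for group comparisons of per-sample mutation counts.

Implements the two nonparametric tests used to compare mutation burdens
between edited strains and uninjected controls:

* a tie-corrected Kruskal-Wallis rank-sum test (k groups, asymptotic
  chi-squared p-value with k-1 degrees of freedom), and
* a two-sided Wilcoxon rank-sum (Mann-Whitney) test whose p-value is
  computed by exact enumeration of rank assignments for small tie-free
  samples and by a tie-corrected normal approximation otherwise.

The Wilcoxon statistic ``W`` is the Mann-Whitney U of the *first* argument:
the number of (x, y) pairs with x > y (ties counted 1/2).  Argument order is
therefore part of any report schema built on these results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, norm

from .errors import DegenerateDataError, InvalidArgumentError

__all__ = ["TestResult", "midranks", "kruskal_wallis", "wilcoxon_rank_sum", "median_count"]

#: largest pooled sample size for which the exact Wilcoxon null is enumerated
EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test.

    ``df`` is present only for the Kruskal-Wallis statistic; ``method``
    records whether the p-value is asymptotic or exactly enumerated.
    """

    statistic_name: str  # "H_chi_squared" or "W"
    statistic: float
    p_value: float
    df: Optional[int] = None
    method: str = "asymptotic_chi2"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidArgumentError(f"p-value outside [0,1]: {self.p_value}")
        if self.statistic < 0:
            raise InvalidArgumentError(f"negative rank statistic: {self.statistic}")


def midranks(values: Sequence[float]) -> list[float]:
    """Rank values 1..n, assigning tied values the mean of the ranks they span.

    The ranks always sum to n(n+1)/2.
    """
    if len(values) == 0:
        raise InvalidArgumentError("midranks of an empty list")
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j + 2) / 2.0  # ranks are 1-based: positions i..j -> ranks i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def _tie_term(pooled: Sequence[float]) -> float:
    """Sum of t^3 - t over groups of tied values."""
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    return float(sum(t**3 - t for t in counts.values() if t > 1))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with an asymptotic chi-squared p-value.

    H = [12/(N(N+1)) * sum_i R_i^2/n_i - 3(N+1)] / C where R_i is the rank
    sum of group i over the pooled midranked sample and the tie correction is
    C = 1 - sum(t^3 - t) / (N^3 - N) over tie groups of size t.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidArgumentError("need >= 2 non-empty groups")
    pooled = [float(v) for g in groups for v in g]
    n_total = len(pooled)
    if n_total < 3:
        raise InvalidArgumentError("need a total of >= 3 observations")
    ranks = midranks(pooled)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction == 0.0:
        raise DegenerateDataError("all observations identical: H is undefined")
    h_raw = 0.0
    offset = 0
    for g in groups:
        r_i = sum(ranks[offset : offset + len(g)])
        h_raw += r_i**2 / len(g)
        offset += len(g)
    h_raw = 12.0 / (n_total * (n_total + 1)) * h_raw - 3.0 * (n_total + 1)
    h = h_raw / correction
    df = len(groups) - 1
    return TestResult(
        statistic_name="H_chi_squared",
        statistic=h,
        df=df,
        p_value=float(chi2.sf(h, df)),
        method="asymptotic_chi2",
    )


def _ranksum_distribution(n_x: int, n_total: int) -> np.ndarray:
    """Counts of subsets of ranks {1..n_total} of size n_x by rank sum.

    counts[s] = number of size-n_x subsets summing to s.  Standard dynamic
    programme over ranks; exact for the tie-free Wilcoxon null.
    """
    max_sum = n_x * n_total
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_x), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n_x]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of x against y.

    W = (rank sum of x in the pooled midranked sample) - n_x(n_x+1)/2, the
    Mann-Whitney U of x over y.  For tie-free pooled samples with
    n_x + n_y <= 20 the p-value enumerates all C(n_x+n_y, n_x) assignments
    of ranks to the first group and doubles the smaller tail, capped at 1;
    otherwise a tie-corrected normal approximation is used (no continuity
    correction).
    """
    if len(x) == 0 or len(y) == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    n_total = n_x + n_y
    pooled = [float(v) for v in x] + [float(v) for v in y]
    ranks = midranks(pooled)
    rank_sum_x = sum(ranks[:n_x])
    w = rank_sum_x - n_x * (n_x + 1) / 2.0

    tie_free = len(set(pooled)) == n_total
    if tie_free and n_total <= EXACT_WILCOXON_MAX_N:
        counts = _ranksum_distribution(n_x, n_total)
        total = counts.sum()
        s = int(round(rank_sum_x))
        p_le = counts[: s + 1].sum() / total
        p_ge = counts[s:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact_enumeration"
    else:
        mean = n_x * n_y / 2.0
        var = n_x * n_y / 12.0 * ((n_total + 1) - _tie_term(pooled) / (n_total * (n_total - 1)))
        if var == 0:
            raise DegenerateDataError("all observations identical: W variance is zero")
        z = (w - mean) / math.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
        method = "normal_approximation"
    return TestResult(statistic_name="W", statistic=float(w), df=None, p_value=float(p), method=method)


def median_count(values: Sequence[float]) -> float:
    """Median: the middle order statistic (odd n) or mean of the two middle ones."""
    if len(values) == 0:
        raise InvalidArgumentError("median of an empty list")
    return float(np.median(np.asarray(values, dtype=float)))
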