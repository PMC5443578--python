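"""Rank statistics: two-sided Wilcoxon rank-sum and Spearman correlation.

Both tests switch to exact enumeration at small sample sizes and to the
standard large-sample approximations otherwise.  The exact paths are the
ones the rest of the package depends on for small cohorts (e.g. expression
comparisons between a handful of mutated and non-mutated tumors), where
normal approximations are unreliable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RankSumResult", "SpearmanResult", "wilcoxon_rank_sum", "spearman"]

_EPS = 1e-12


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first group (midranks)
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    method: str  # "exact", "t-approx", or "undefined"


def wilcoxon_rank_sum(x, y, exact_max: int = 10) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of all group assignments (midranks, so ties are handled
    correctly) when both groups have at most ``exact_max`` observations;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if x.size <= exact_max and y.size <= exact_max:
        n = pooled.size
        expected = x.size * (n + 1) / 2.0
        dev = abs(w - expected)
        total = math.comb(n, x.size)
        extreme = 0
        for combo in itertools.combinations(range(n), x.size):
            ws = ranks[list(combo)].sum()
            if abs(ws - expected) >= dev - _EPS:
                extreme += 1
        return RankSumResult(w, extreme / total, "exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(w, float(res.pvalue), "asymptotic")


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0.0:
        return math.nan
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max: int = 8) -> SpearmanResult:
    """Spearman rank correlation with midrank ties.

    The p-value comes from exhaustive permutation of one vector when
    ``n <= exact_max`` and from the t-approximation with n-2 degrees of
    freedom otherwise.  A constant input vector yields an undefined (NaN)
    coefficient rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_pearson(rx, ry)
    if math.isnan(rho):
        return SpearmanResult(math.nan, math.nan, "undefined")
    if n <= exact_max:
        obs = abs(rho)
        extreme = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _rank_pearson(rx, np.asarray(perm))
            total += 1
            if abs(r) >= obs - _EPS:
                extreme += 1
        return SpearmanResult(rho, extreme / total, "exact")
    # t-approximation, n-2 degrees of freedom
    t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, _EPS))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return SpearmanResult(rho, min(p, 1.0), "t-approx")
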