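"""Nonparametric tests with exact small-sample enumeration.

Mann–Whitney, Kruskal–Wallis and the two-sample Kolmogorov–Smirnov test,
each switching automatically between an exact permutation-enumeration
null (feasible at small n) and the standard large-sample approximation:

* Mann–Whitney: exact when both groups have <= 10 observations, otherwise
  a tie- and continuity-corrected normal approximation; two-sided.
* Kruskal–Wallis: tie-corrected H; exact enumeration of all group
  assignments when the pooled sample has <= 8 observations, otherwise
  chi-square with k − 1 degrees of freedom.
* Kolmogorov–Smirnov: D = sup|F̂x − F̂y|; exact enumeration when both
  n <= 10, otherwise the asymptotic Kolmogorov distribution.

Exact p-values are tail probabilities over every split of the pooled
(possibly tied) observations, so they remain valid under ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DegenerateSampleError",
    "mann_whitney",
    "kruskal_wallis",
    "ks_two_sample",
    "skewness",
]

_EPS = 1e-12


class DegenerateSampleError(ValueError):
    """Raised when a statistic is undefined for the given sample."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    method: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _index_combinations(n_total: int, n_pick: int) -> np.ndarray:
    return np.array(list(combinations(range(n_total), n_pick)), dtype=np.intp)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (x, y) pairs with x > y, ties counting 1/2."""
    n1 = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney(x, y, exact: bool | None = None) -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``exact=None`` (default) enumerates the exact null when both samples
    have <= 10 observations and falls back to the tie/continuity-corrected
    normal approximation otherwise.  The reported statistic is U of the
    first sample.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs >= 1 observation")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    if exact is None:
        exact = n1 <= 10 and n2 <= 10

    if exact:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        idx = _index_combinations(n1 + n2, n1)
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        p_le = np.mean(u_all <= u_obs + _EPS)
        p_ge = np.mean(u_all >= u_obs - _EPS)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult("mann-whitney (exact)", u_obs, float(p))

    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return TestResult("mann-whitney (normal approx)", u_obs, 1.0)
    diff = u_obs - mu
    # continuity correction toward the mean
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult("mann-whitney (normal approx)", u_obs, float(p))


def _kw_h(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    rbar = (n + 1) / 2.0
    start = 0
    num = 0.0
    for g in groups:
        ri = ranks[start : start + g.size].mean()
        num += g.size * (ri - rbar) ** 2
        start += g.size
    h = 12.0 / (n * (n + 1)) * num
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / float(n**3 - n)
    if correction <= 0:  # every observation identical
        return 0.0
    return float(h / correction)


def _assignments(values: np.ndarray, sizes: list[int]):
    """Yield every split of ``values`` into ordered groups of given sizes."""

    def rec(idx: np.ndarray, sizes: list[int], acc: list[np.ndarray]):
        if not sizes:
            yield [values[a] for a in acc]
            return
        k = sizes[0]
        if len(sizes) == 1:
            yield [values[a] for a in acc] + [values[idx]]
            return
        for chosen in combinations(range(idx.size), k):
            chosen = np.asarray(chosen, dtype=np.intp)
            rest = np.delete(idx, chosen)
            yield from rec(rest, sizes[1:], acc + [idx[chosen]])

    yield from rec(np.arange(values.size, dtype=np.intp), sizes, [])


def kruskal_wallis(groups, exact: bool | None = None) -> TestResult:
    """Kruskal–Wallis H test with tie correction across >= 2 groups."""
    gs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    n = sum(g.size for g in gs)
    if n < 3:
        raise ValueError("need >= 3 observations in total")
    h_obs = _kw_h(gs)
    pooled = np.concatenate(gs)
    if np.unique(pooled).size == 1:
        return TestResult("kruskal-wallis", 0.0, 1.0)
    if exact is None:
        exact = n <= 8
    if exact:
        sizes = [g.size for g in gs]
        h_all = np.array([_kw_h(split) for split in _assignments(pooled, sizes)])
        p = float(np.mean(h_all >= h_obs - _EPS))
        return TestResult("kruskal-wallis (exact)", h_obs, p)
    p = float(sps.chi2.sf(h_obs, df=len(gs) - 1))
    return TestResult("kruskal-wallis (chi2 approx)", h_obs, min(p, 1.0))


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    xs = np.sort(x)
    ys = np.sort(y)
    fx = np.searchsorted(xs, pooled, side="right") / x.size
    fy = np.searchsorted(ys, pooled, side="right") / y.size
    return float(np.abs(fx - fy).max())


def ks_two_sample(x, y, exact: bool | None = None) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test, D = sup|F̂x − F̂y|."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    n1, n2 = x.size, y.size
    d_obs = _ks_d(x, y)
    if exact is None:
        exact = n1 <= 10 and n2 <= 10
    if exact:
        pooled = np.concatenate([x, y])
        idx = _index_combinations(n1 + n2, n1)
        all_idx = np.arange(n1 + n2, dtype=np.intp)
        d_all = np.empty(idx.shape[0])
        for i, chosen in enumerate(idx):
            rest = np.setdiff1d(all_idx, chosen, assume_unique=True)
            d_all[i] = _ks_d(pooled[chosen], pooled[rest])
        p = float(np.mean(d_all >= d_obs - _EPS))
        return TestResult("ks-2samp (exact)", d_obs, p)
    en = np.sqrt(n1 * n2 / (n1 + n2))
    p = float(np.clip(special.kolmogorov(en * d_obs), 0.0, 1.0))
    return TestResult("ks-2samp (asymptotic)", d_obs, p)


def skewness(values) -> float:
    """Adjusted Fisher–Pearson sample skewness g1·√(n(n−1))/(n−2)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 3:
        raise DegenerateSampleError("skewness needs >= 3 observations")
    if np.unique(v).size == 1:
        raise DegenerateSampleError("skewness undefined for a constant sample")
    return float(sps.skew(v, bias=False))
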