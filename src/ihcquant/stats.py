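"""Non-parametric statistics for small ordinal-scored cohorts.

The tests a bench scientist would run on scored arthritis cohorts:
the exact two-sided Mann–Whitney test (full permutation distribution of
the rank sum, so that at n = 5 vs 5 complete separation yields the
characteristic floor p = 2/252 ≈ 0.0079), the tie-corrected
Kruskal–Wallis H with its chi-square approximation, Dunn's pairwise
post-hoc z tests with Bonferroni-style multiplicity adjustment (the
convention of the common graphing software), and tie-corrected Spearman
rank correlation with an exact permutation p at small n.

The test statistics and exact p-values are computed here from the rank
definitions; only the chi-square / normal / t distribution functions
come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _spstats

__all__ = [
    "GroupData",
    "TestResult",
    "mann_whitney_exact",
    "kruskal_wallis",
    "dunn_multiple_comparisons",
    "spearman",
    "EXACT_MAX_N",
]

#: Combined sample size up to which the Mann–Whitney p is exact.
EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    adjusted: bool = False
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class GroupData:
    """Named groups of measurements for omnibus tests."""

    groups: tuple[tuple[str, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("omnibus tests need at least 2 groups")
        for name, values in self.groups:
            if len(values) == 0:
                raise ValueError(f"group {name!r} is empty")

    @classmethod
    def from_dict(cls, d: dict[str, Sequence[float]]) -> "GroupData":
        return cls(tuple((k, tuple(float(x) for x in v)) for k, v in d.items()))

    @classmethod
    def from_dataframe(cls, df, group_col: str, value_col: str) -> "GroupData":
        grouped = {
            str(name): sub[value_col].to_numpy(dtype=float)
            for name, sub in df.groupby(group_col, sort=False)
        }
        return cls.from_dict(grouped)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(v) for _, v in self.groups)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # average of 1-based ranks i+1..j+1
        i = j + 1
    return ranks


def _tie_counts(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def _rank_sum_distribution(ranks2: np.ndarray, nx: int) -> np.ndarray:
    """Exact permutation distribution of the doubled rank sum.

    ``counts[s]`` = number of size-``nx`` subsets of the pooled doubled
    midranks summing to ``s``; equivalent to enumerating all C(N, nx)
    group-label assignments, computed by subset-sum dynamic programming.
    Midranks are half-integers at worst, so doubling makes them exact
    integers.
    """
    total = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((nx + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        kmax = nx  # iterate k downward so each rank is used once
        for k in range(kmax, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[nx]


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> TestResult:
    """Two-sided Mann–Whitney U test, exact at small combined n.

    For combined n ≤ ``exact_max_n`` the p-value is exact, from the full
    permutation distribution of the rank sum over all C(N, n_x) group
    labelings (midranks under ties): twice the smaller tail probability,
    clipped at 1.  Larger samples fall back to the tie-corrected normal
    approximation, flagged in ``method``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rx = ranks[:nx].sum()
    U = rx - nx * (nx + 1) / 2  # U statistic for x

    N = nx + ny
    if N <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _rank_sum_distribution(ranks2, nx)
        ncomb = dist.sum()
        w2 = int(round(2 * rx))
        lower = dist[: w2 + 1].sum() / ncomb
        upper = dist[w2:].sum() / ncomb
        p = min(1.0, 2 * min(lower, upper))
        method = "Mann-Whitney exact (permutation)"
    else:
        mu = nx * ny / 2
        tie_term = sum(t**3 - t for t in _tie_counts(pooled))
        sigma2 = nx * ny / 12 * ((N + 1) - tie_term / (N * (N - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (U - mu) / math.sqrt(sigma2)
            p = min(1.0, 2 * _spstats.norm.sf(abs(z)))
        method = "Mann-Whitney normal approximation (tie-corrected)"
    return TestResult(
        statistic=float(U),
        p_value=float(p),
        method=method,
        n_per_group=(nx, ny),
    )


def kruskal_wallis(groups: GroupData) -> TestResult:
    """Kruskal–Wallis H test with tie correction.

    H = 12/(N(N+1)) · Σ nᵢ (R̄ᵢ − (N+1)/2)², divided by the tie factor
    1 − Σ(t³−t)/(N³−N); p from the chi-square approximation with k−1
    degrees of freedom.  All observations identical → H = 0, p = 1.
    """
    samples = [np.asarray(v, dtype=float) for _, v in groups.groups]
    if sum(len(s) for s in samples) < 3:
        raise ValueError("Kruskal-Wallis needs total n >= 3")
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = _midranks(pooled)
    H = 0.0
    start = 0
    for s in samples:
        r_mean = ranks[start : start + len(s)].mean()
        H += len(s) * (r_mean - (N + 1) / 2) ** 2
        start += len(s)
    H *= 12 / (N * (N + 1))
    tie_term = sum(t**3 - t for t in _tie_counts(pooled))
    correction = 1 - tie_term / (N**3 - N)
    if correction <= 0:  # every observation identical
        H, p = 0.0, 1.0
    else:
        H /= correction
        p = float(_spstats.chi2.sf(H, df=len(samples) - 1))
    return TestResult(
        statistic=float(H),
        p_value=p,
        method="Kruskal-Wallis (tie-corrected, chi-square approximation)",
        n_per_group=groups.sizes,
    )


def dunn_multiple_comparisons(groups: GroupData) -> list[TestResult]:
    """Dunn's pairwise post-hoc tests after Kruskal–Wallis.

    For each pair (i, j): z = (R̄ᵢ − R̄ⱼ) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))
    · (1/nᵢ + 1/nⱼ)] on the pooled midranks; the two-sided normal p is
    multiplied by the number of comparisons k(k−1)/2 and clipped at 1.
    """
    k = len(groups.groups)
    if k < 3:
        raise ValueError("Dunn's test needs >= 3 groups; use mann_whitney_exact for 2")
    samples = [np.asarray(v, dtype=float) for _, v in groups.groups]
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + len(s)].mean())
        start += len(s)
    tie_term = sum(t**3 - t for t in _tie_counts(pooled))
    var_base = N * (N + 1) / 12 - tie_term / (12 * (N - 1))
    m = k * (k - 1) // 2
    results: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(samples[i]), len(samples[j])
            se2 = var_base * (1 / ni + 1 / nj)
            if se2 <= 0:  # all observations identical
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
                p = min(1.0, m * 2 * float(_spstats.norm.sf(abs(z))))
            results.append(
                TestResult(
                    statistic=float(z),
                    p_value=p,
                    method="Dunn multiple comparison (Bonferroni-adjusted)",
                    n_per_group=(ni, nj),
                    adjusted=True,
                    details={
                        "comparison": (groups.names[i], groups.names[j]),
                        "n_comparisons": m,
                    },
                )
            )
    return results


def _rank_corr(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Pearson correlation of two rank vectors (tie-corrected Spearman rho)."""
    dx = rank_x - rank_x.mean()
    dy = rank_y - rank_y.mean()
    denom = math.sqrt((dx**2).sum() * (dy**2).sum())
    return float((dx * dy).sum() / denom)


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> TestResult:
    """Tie-corrected Spearman rank correlation.

    rho is the Pearson correlation of midranks.  The two-sided p is
    exact by enumerating all n! pairings for n ≤ ``exact_max_n``, and a
    t-approximation (t = rho·√((n−2)/(1−rho²)), n−2 df) otherwise.
    ``details`` also carries rho² for r²-style reporting.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    rank_x = _midranks(x)
    rank_y = _midranks(y)
    rho = _rank_corr(rank_x, rank_y)
    if n <= exact_max_n:
        observed = abs(rho) - 1e-12  # guard float noise at |rho| ties
        hits = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(_rank_corr(rank_x, rank_y[list(perm)])) >= observed:
                hits += 1
        p = hits / total
        method = "Spearman exact (permutation)"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = min(1.0, 2 * float(_spstats.t.sf(abs(t), df=n - 2)))
        method = "Spearman t-approximation"
    return TestResult(
        statistic=float(rho),
        p_value=float(p),
        method=method,
        n_per_group=(n,),
        details={"rho_squared": float(rho**2)},
    )
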