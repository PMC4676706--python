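"""Exact non-parametric tests against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from ihcquant import (
    GroupData,
    dunn_multiple_comparisons,
    kruskal_wallis,
    mann_whitney_exact,
    spearman,
)


def brute_force_mw_p(x, y):
    """Exact two-sided Mann–Whitney p by literal enumeration of C(N, nx)
    group labelings of the pooled midranks (the definition, no DP)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    observed = ranks[:nx].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), nx)]
    sums = np.asarray(sums)
    lower = np.mean(sums <= observed + 1e-9)
    upper = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2 * min(lower, upper))


class TestMannWhitney:
    def test_complete_separation_at_n5_gives_the_floor_p(self):
        r = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert r.p_value == pytest.approx(2 / 252)
        assert "exact" in r.method

    def test_identical_samples_give_p_one(self):
        assert mann_whitney_exact([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_small_separation_example(self):
        assert mann_whitney_exact([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)

    def test_swapping_samples_leaves_p_unchanged(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            assert mann_whitney_exact(x, y).p_value == pytest.approx(
                mann_whitney_exact(y, x).p_value
            )

    def test_matches_brute_force_enumeration_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            x = rng.integers(0, 4, size=rng.integers(3, 6)).astype(float)
            y = rng.integers(0, 4, size=rng.integers(3, 6)).astype(float)
            assert mann_whitney_exact(x, y).p_value == pytest.approx(
                brute_force_mw_p(x, y)
            )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            x = rng.normal(size=rng.integers(3, 8))
            y = rng.normal(size=rng.integers(3, 8))
            ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert mann_whitney_exact(x, y).p_value == pytest.approx(ref.pvalue)

    def test_exact_p_agrees_with_monte_carlo_permutation(self):
        rng = np.random.default_rng(4)
        x = np.array([0.2, 1.1, 2.5, 3.0, 4.7])
        y = np.array([1.9, 3.4, 4.1, 5.6, 6.2])
        p_exact = mann_whitney_exact(x, y).p_value
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        observed = ranks[:5].sum()
        n_draws = 100_000
        hits_lo = hits_hi = 0
        for _ in range(n_draws):
            perm = rng.permutation(10)[:5]
            s = ranks[perm].sum()
            hits_lo += s <= observed + 1e-9
            hits_hi += s >= observed - 1e-9
        p_mc = min(1.0, 2 * min(hits_lo / n_draws, hits_hi / n_draws))
        se = math.sqrt(p_exact * (1 - p_exact) / n_draws)
        assert abs(p_exact - p_mc) <= 3 * se + 2 / n_draws

    def test_large_samples_use_the_normal_approximation(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=15), rng.normal(1.0, size=15)
        r = mann_whitney_exact(x, y)
        assert "approximation" in r.method
        ref = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided",
                               use_continuity=False)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_test_is_conservative_under_the_null(self):
        # discrete achievable levels make the exact test conservative
        rejections = 0
        n_sim = 2000
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            x, y = rng.normal(size=5), rng.normal(size=5)
            rejections += mann_whitney_exact(x, y).p_value < 0.05
        assert rejections / n_sim <= 0.05

    def test_empty_sample_is_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1, 2])


class TestKruskalWallis:
    def test_hand_computed_h_for_three_separated_triples(self):
        g = GroupData.from_dict({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        r = kruskal_wallis(g)
        assert r.statistic == pytest.approx(7.2)

    def test_identical_groups_give_h_zero_p_one(self):
        g = GroupData.from_dict({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        r = kruskal_wallis(g)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_group_order_does_not_change_h(self):
        d = {"a": [1.0, 5.0, 2.0], "b": [3.0, 8.0], "c": [9.0, 4.0, 6.0]}
        h1 = kruskal_wallis(GroupData.from_dict(d)).statistic
        rev = dict(reversed(list(d.items())))
        h2 = kruskal_wallis(GroupData.from_dict(rev)).statistic
        assert h1 == pytest.approx(h2)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            samples = [rng.integers(0, 5, size=6).astype(float) for _ in range(3)]
            if np.ptp(np.concatenate(samples)) == 0:
                continue
            g = GroupData.from_dict({f"g{i}": s for i, s in enumerate(samples)})
            ref = sps.kruskal(*samples)
            r = kruskal_wallis(g)
            assert r.statistic == pytest.approx(ref.statistic)
            assert r.p_value == pytest.approx(ref.pvalue)


def dunn_oracle(samples):
    """Independent Dunn z computation straight from the definition."""
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    means, start = [], 0
    for s in samples:
        means.append(ranks[start : start + len(s)].mean())
        start += len(s)
    _, t = np.unique(pooled, return_counts=True)
    base = N * (N + 1) / 12 - ((t**3 - t).sum()) / (12 * (N - 1))
    out = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = math.sqrt(base * (1 / len(samples[i]) + 1 / len(samples[j])))
            out.append((means[i] - means[j]) / se)
    return out


class TestDunn:
    def test_z_values_match_the_formula_oracle(self):
        samples = [
            np.array([1.0, 2.0, 3.0]),
            np.array([4.0, 5.0, 6.0]),
            np.array([7.0, 8.0, 9.0]),
        ]
        g = GroupData.from_dict({"a": samples[0], "b": samples[1], "c": samples[2]})
        results = dunn_multiple_comparisons(g)
        for r, z in zip(results, dunn_oracle(samples)):
            assert r.statistic == pytest.approx(z)
            raw = 2 * sps.norm.sf(abs(z))
            assert r.p_value == pytest.approx(min(1.0, 3 * raw))
            assert r.adjusted

    def test_with_ties_matches_the_oracle(self):
        rng = np.random.default_rng(7)
        samples = [rng.integers(0, 4, size=5).astype(float) for _ in range(4)]
        g = GroupData.from_dict({f"g{i}": s for i, s in enumerate(samples)})
        results = dunn_multiple_comparisons(g)
        assert len(results) == 6  # k(k-1)/2 for k=4
        for r, z in zip(results, dunn_oracle(samples)):
            assert r.statistic == pytest.approx(z)

    def test_identical_data_gives_adjusted_p_one(self):
        g = GroupData.from_dict({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert all(r.p_value == 1.0 for r in dunn_multiple_comparisons(g))

    def test_fewer_than_three_groups_is_a_usage_error(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            dunn_multiple_comparisons(GroupData.from_dict({"a": [1.0], "b": [2.0]}))


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_hand_computed_rho_for_one_swap(self):
        r = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.statistic == pytest.approx(0.8)  # 1 - 6*2/60
        assert r.details["rho_squared"] == pytest.approx(r.statistic**2)

    def test_exact_permutation_p_matches_scipy_at_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        mine = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert mine.statistic == pytest.approx(ref.statistic)

    def test_t_approximation_at_larger_n_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        mine = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert "t-approximation" in mine.method
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


def test_group_data_validation():
    with pytest.raises(ValueError):
        GroupData.from_dict({"only": [1.0, 2.0]})
    with pytest.raises(ValueError):
        GroupData.from_dict({"a": [1.0], "b": []})
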