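"""Nonparametric test battery, effect sizes, and bootstrap CIs."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from soundhue.grouptests import (bootstrap_median_ci, cohens_d, dunn_posthoc,
                                 kruskal_wallis, normality_screen,
                                 significance_stars, tukey_hsd,
                                 wilcoxon_rank_sum)


def mw_permutation_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group labellings."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2
    u_obs = u_of(range(n))
    mu = len(x) * len(y) / 2
    us = [u_of(c) for c in combinations(range(len(pooled)), n)]
    extreme = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us)
    return extreme / len(us)


def kw_permutation_oracle(groups):
    """Exact p for the Kruskal-Wallis H over all assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    def h_of(parts):
        return stats.kruskal(*parts).statistic
    h_obs = h_of(groups)
    idx = list(range(len(pooled)))
    count = total = 0
    for first in combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in first]
        for second in combinations(rest, sizes[1]):
            parts = [pooled[list(first)], pooled[list(second)]]
            if len(sizes) == 3:
                third = [i for i in rest if i not in second]
                parts.append(pooled[third])
            total += 1
            if h_of(parts) >= h_obs - 1e-12:
                count += 1
    return count / total


class TestNormalityScreen:
    def test_gaussian_quantiles_pass(self):
        x = stats.norm.ppf((np.arange(10) + 0.5) / 10)
        w, p = normality_screen(x)
        assert 0 < w <= 1 and p > 0.05

    def test_skewed_sample_fails_in_most_seeds(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).exponential(size=50)
            rejections += normality_screen(x)[1] < 0.05
        assert rejections >= 38  # >= 95% of seeds

    def test_validation(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_screen([3.0] * 10)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[2, 2], [2, 2]])

    def test_four_by_five_layout(self, rng):
        groups = [rng.normal(size=38) for _ in range(5)]
        res = kruskal_wallis(groups, labels=list("ABCDE"))
        assert 0 <= res.p <= 1 and res.groups == list("ABCDE")

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        a = kruskal_wallis(groups).statistic
        b = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert a == pytest.approx(b, abs=1e-12)


class TestTukeyHSD:
    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        tab = tukey_hsd([a, b], labels=["lo", "hi"])
        assert tab["significant"].all()

    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(size=10)
        tab = tukey_hsd([g, g + 1e-12, g - 1e-12])
        assert not tab["significant"].any()

    def test_five_groups_ten_pairs(self, rng):
        tab = tukey_hsd([rng.normal(size=5) for _ in range(5)])
        assert len(tab) == 10

    def test_dunn_alternative_agrees_on_separation(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(8, 1, 12)
        tab = dunn_posthoc([a, b], labels=["lo", "hi"])
        assert tab["significant"].all()


class TestWilcoxon:
    def test_exact_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p == pytest.approx(1 / 3)

    def test_equal_vectors_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_unequal_lengths_asymptotic(self, rng):
        x = rng.normal(0.6, 1, 297)
        y = rng.normal(0, 1, 216)
        res = wilcoxon_rank_sum(x, y)
        assert "asymptotic" in res.test
        assert res.p < 1e-6 and res.effect_size_d > 0

    def test_matches_permutation_oracle_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 5))
            y = rng.normal(size=rng.integers(2, 5))
            res = wilcoxon_rank_sum(x, y)
            assert res.p == pytest.approx(mw_permutation_oracle(x, y), abs=1e-10)

    def test_matches_permutation_oracle_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(1, 4, size=rng.integers(2, 5)).astype(float)
            y = rng.integers(1, 4, size=rng.integers(2, 5)).astype(float)
            res = wilcoxon_rank_sum(x, y)
            assert res.p == pytest.approx(mw_permutation_oracle(x, y), abs=1e-10)

    def test_rank_transform_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=25)
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert a.statistic == b.statistic and a.p == pytest.approx(b.p)


def kw_h_oracle(groups):
    """Independently coded tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rsum = [r.sum() for r in np.split(ranks, splits)]
    h = 12 / (n * (n + 1)) * sum(s**2 / len(g) for s, g in zip(rsum, groups)) \
        - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


class TestKruskalOracle:
    def test_statistic_matches_independent_formula(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 5, size=rng.integers(2, 4)).astype(float)
                      for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(kw_h_oracle(groups), abs=1e-12)

    def test_extreme_data_is_extreme_under_enumeration(self):
        groups = [[1.0, 2.0, 3.0], [7.0, 8.0, 9.0]]
        assert kw_permutation_oracle(groups) == pytest.approx(0.1, abs=1e-9)


class TestCohensD:
    def test_unit_difference(self):
        # pooled sd is exactly 1, so d equals the mean difference
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0])
        assert cohens_d(x, y) == pytest.approx(1.0)

    def test_identical_groups_zero_and_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=12)
        assert cohens_d(x, x) == 0
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])


class TestBootstrapMedianCI:
    def test_constant_data_degenerate_interval(self):
        med, lo, hi = bootstrap_median_ci([4.2] * 10, n_boot=200, seed=0)
        assert med == lo == hi == 4.2

    def test_contains_sample_median(self, rng):
        x = rng.normal(size=39)  # odd n: median is a data point
        med, lo, hi = bootstrap_median_ci(x, n_boot=2000, seed=1)
        assert lo <= med <= hi and med == np.median(x)

    def test_deterministic_per_seed(self, rng):
        x = rng.normal(size=20)
        assert bootstrap_median_ci(x, seed=5) == bootstrap_median_ci(x, seed=5)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci([1.0, 2.0])


def test_significance_stars():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.04, 0.2)] == \
        ["***", "**", "*", ""]
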