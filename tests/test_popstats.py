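"""Expected distributions, rank tests, KS, and Holm adjustment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from paralocus.popstats import (
    ExpectedDistributionSpec,
    POLYGENIC_PROBS,
    dunn_test,
    expected_polygenic_sample,
    expected_ukb_mean,
    expected_ukb_sample,
    holm_adjust,
    kruskal_wallis,
    ks_two_sample,
    simons_expected_spec,
)


def brute_force_h(groups):
    """Independent rank-sum computation of the Kruskal-Wallis H (with ties)."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    # average ranks with ties
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        avg = (i + 1 + j) / 2
        for k in range(i, j):
            pooled[k] = (*pooled[k], avg)
        i = j
    rank_sums = {}
    sizes = {}
    for value, gi, rank in pooled:
        rank_sums[gi] = rank_sums.get(gi, 0) + rank
        sizes[gi] = sizes.get(gi, 0) + 1
    h = 12 / (n * (n + 1)) * sum(rank_sums[g] ** 2 / sizes[g] for g in rank_sums) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique([v for v, *_ in pooled], return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


class TestExpectedPolygenic:
    def test_zero_jitter_returns_exact_support(self):
        spec = ExpectedDistributionSpec((0, 1, 2, 3, 4), POLYGENIC_PROBS, 500, 0.0, seed=1)
        vals = expected_polygenic_sample(spec)
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0, 3.0, 4.0}

    def test_two_allele_fraction_matches_six_sixteenths(self):
        vals = expected_polygenic_sample(simons_expected_spec(seed=5))
        frac = np.mean(np.round(vals) == 2)
        p = 6 / 16
        se = np.sqrt(p * (1 - p) / vals.size)
        assert abs(frac - p) <= 3 * se

    def test_sample_mean_is_two(self):
        vals = expected_polygenic_sample(simons_expected_spec(seed=2))
        assert vals.mean() == pytest.approx(2.0, abs=0.1)

    def test_category_proportions_converge(self):
        spec = ExpectedDistributionSpec((0, 1, 2, 3, 4), POLYGENIC_PROBS, 100_000, 0.0, seed=3)
        vals = expected_polygenic_sample(spec)
        for k, p in enumerate(POLYGENIC_PROBS):
            frac = np.mean(vals == k)
            se = np.sqrt(p * (1 - p) / vals.size)
            assert abs(frac - p) <= 3 * se

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ExpectedDistributionSpec((0, 1), (0.5, 0.6), 10, 0.1)

    def test_reproducible_under_seed(self):
        spec = simons_expected_spec(seed=11)
        assert np.array_equal(expected_polygenic_sample(spec), expected_polygenic_sample(spec))


class TestExpectedUkb:
    def test_zero_loss_zero_sd_values_on_support(self):
        vals = expected_ukb_sample(n=2000, jitter_sd=0.0, seed=1)
        assert set(np.round(np.unique(vals), 10)) <= {0.0, 0.1, 0.2, 0.3, 0.4}

    def test_bitwise_reproducible(self):
        a = expected_ukb_sample(n=5000, loss_rate_nlc=0.1, loss_rate_nlr=0.05, seed=9)
        b = expected_ukb_sample(n=5000, loss_rate_nlc=0.1, loss_rate_nlr=0.05, seed=9)
        assert np.array_equal(a, b)

    def test_loss_rate_shifts_mean_by_closed_form(self):
        rc, rr = 0.2, 0.1
        vals = expected_ukb_sample(n=200_000, loss_rate_nlc=rc, loss_rate_nlr=rr, seed=4)
        want = expected_ukb_mean(rc, rr)
        assert vals.mean() == pytest.approx(want, abs=3 * vals.std() / np.sqrt(vals.size))

    def test_invalid_loss_rate_rejected(self):
        with pytest.raises(ValueError, match="loss rates"):
            expected_ukb_sample(loss_rate_nlc=1.5)


class TestKruskalWallis:
    def test_identical_constant_groups_degenerate(self):
        res = kruskal_wallis([[3, 3, 3], [3, 3], [3, 3, 3, 3]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_clean_groups_match_hand_formula(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(brute_force_h(groups), abs=1e-12)

    def test_agrees_with_rank_sum_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.integers(0, 8, size=rng.integers(3, 12)).tolist() for _ in range(k)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(brute_force_h(groups), abs=1e-10)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2 groups"):
            kruskal_wallis([[1, 2, 3]])

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha=0.05 stays within 5% +/- 2% over
        1,000 simulated three-group datasets."""
        rng = np.random.default_rng(123)
        rejections = 0
        for _ in range(1000):
            groups = rng.normal(size=(3, 30))
            rejections += kruskal_wallis(list(groups)).p_value < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07


class TestDunn:
    def test_identical_groups_give_zero_z_unit_p(self):
        res = dunn_test([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        for _, _, z, raw, adj in res.pairwise:
            assert z == pytest.approx(0.0)
            assert adj == 1.0

    def test_three_group_z_matches_direct_formula(self):
        groups = [[1.0, 2.0, 4.0], [3.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        res = dunn_test(groups, labels=["a", "b", "c"], adjustment="none")
        # independent computation of the z statistic
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        mean_ranks = [ranks[:3].mean(), ranks[3:6].mean(), ranks[6:].mean()]
        var = n * (n + 1) / 12.0  # no ties in this dataset
        for (a, b, z, raw, adj), (i, j) in zip(res.pairwise, [(0, 1), (0, 2), (1, 2)]):
            zij = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var * (2 / 3))
            assert z == pytest.approx(zij, abs=1e-12)
            assert raw == pytest.approx(2 * sps.norm.sf(abs(zij)), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            dunn_test([[1, 2], []])

    def test_holm_adjusted_pairwise_monotone(self):
        rng = np.random.default_rng(7)
        res = dunn_test([rng.normal(size=10), rng.normal(1, size=10), rng.normal(2, size=10)])
        raws = [p[3] for p in res.pairwise]
        adjs = [p[4] for p in res.pairwise]
        assert all(a >= r for a, r in zip(adjs, raws))
        order = np.argsort(raws)
        assert np.all(np.diff(np.asarray(adjs)[order]) >= 0)


class TestKsAndHolm:
    def test_identical_samples_d_zero(self):
        a = np.arange(10.0)
        res = ks_two_sample(a, a)
        assert res.statistic == 0.0

    def test_disjoint_samples_d_one(self):
        a = np.arange(0, 1, 0.1)
        assert ks_two_sample(a, a + 10).statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            ks_two_sample([], [1.0])

    def test_holm_worked_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_holm_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=12)
        want = multipletests(p, method="holm")[1]
        assert np.allclose(holm_adjust(p), want)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_holm_properties(self, p):
        adj = holm_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(0 <= a <= 1 for a in adj)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)
        # idempotent on already-adjusted monotone inputs
        again = holm_adjust(sorted(adj))
        assert np.all(np.asarray(again) >= np.asarray(sorted(adj)) - 1e-15)
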