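"""CV², running-median trend, DM, binning, bootstrap and rank-sum."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstvar.noise import (
    bin_genes,
    bootstrap_dm_test,
    cv2,
    dm,
    ranksum_test,
    running_median_trend,
)


class TestCV2:
    def test_constant_vector_is_noiseless(self):
        assert cv2([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_example(self):
        # mean 1, unbiased variance 2
        assert cv2([0.0, 2.0]) == pytest.approx(2.0)

    def test_poisson_counts_follow_one_over_mu(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(200.0, size=20_000)
        assert cv2(x) == pytest.approx(1 / 200.0, rel=0.1)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv2([0.0, 0.0])


class TestRunningMedianTrend:
    def test_reproduces_exact_powerlaw(self):
        """Points on an exact line in log-log space map onto themselves."""
        mus = np.geomspace(1, 1000, 200)
        cv2s = 5.0 / mus
        trend = running_median_trend(mus, cv2s, window=11)
        inner = slice(10, -10)
        np.testing.assert_allclose(trend[inner], cv2s[inner], rtol=1e-9)

    def test_outlier_is_local(self):
        mus = np.geomspace(1, 1000, 200)
        cv2s = 5.0 / mus
        bumped = cv2s.copy()
        bumped[0] *= 100  # outlier at the low-expression end
        a = running_median_trend(mus, cv2s, window=11)
        b = running_median_trend(mus, bumped, window=11)
        np.testing.assert_allclose(a[50:], b[50:], rtol=1e-12)

    def test_slope_of_poisson_cloud(self):
        """1/μ shot noise + scatter gives a log-log trend slope of −1."""
        rng = np.random.default_rng(1)
        mus = 10 ** rng.uniform(0.5, 3.5, size=3000)
        cv2s = (1 / mus) * 10 ** rng.normal(0, 0.2, size=3000)
        trend = running_median_trend(mus, cv2s, window=301)
        slope = np.polyfit(np.log10(mus), np.log10(trend), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            running_median_trend([1, 2, 3], [1, 1, 1], window=2)


class TestDM:
    def test_gene_on_trend_scores_zero(self):
        mus = np.geomspace(1, 1000, 101)
        cv2s = 5.0 / mus
        d = dm(mus, cv2s, window=11)
        assert abs(d[50]) < 1e-9

    def test_tenfold_excess_scores_one(self):
        # flat noise profile so the windowed median is provably unmoved
        mus = np.geomspace(1, 1000, 101)
        cv2s = np.full(101, 5.0)
        cv2s[50] *= 10
        d = dm(mus, cv2s, window=11)
        assert d[50] == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_global_cv2_rescaling(self):
        rng = np.random.default_rng(2)
        mus = 10 ** rng.uniform(0, 3, 500)
        cv2s = (1 / mus) * 10 ** rng.normal(0, 0.3, 500)
        np.testing.assert_allclose(
            dm(mus, cv2s, window=51), dm(mus, 2.0 * cv2s, window=51), atol=1e-12
        )

    def test_nonpositive_cv2_flagged_not_fatal(self):
        mus = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        cv2s = np.array([1.0, 0.0, 0.5, 0.25, 0.125])
        d = dm(mus, cv2s, window=3)
        assert np.isnan(d[1]) and np.isfinite(d[0])

    def test_residuals_centred_over_large_cloud(self):
        rng = np.random.default_rng(3)
        mus = 10 ** rng.uniform(0, 3, 6000)
        cv2s = (2 / mus) * 10 ** rng.normal(0, 0.4, 6000)
        assert abs(np.nanmean(dm(mus, cv2s, window=500))) < 0.05


class TestBinGenes:
    def test_block_sizes(self):
        mus = np.linspace(10, 100, 1200)
        bins = bin_genes(mus, bin_size=500, floor=10)
        sizes = np.bincount(bins[bins >= 0])
        assert list(sizes) == [500, 500, 200]

    def test_floor_excludes_low_expression(self):
        bins = bin_genes(np.array([1.0, 5.0, 9.99]), bin_size=2, floor=10)
        assert (bins == -1).all()

    def test_borders_partition_above_floor_genes(self):
        rng = np.random.default_rng(4)
        mus = rng.uniform(0, 100, 999)
        bins = bin_genes(mus, bin_size=100, floor=10)
        above = mus >= 10
        assert (bins[above] >= 0).all() and (bins[~above] == -1).all()
        # bins are contiguous blocks along expression
        order = np.argsort(mus[above], kind="stable")
        assert (np.diff(bins[above][order]) >= 0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=300),
        st.integers(1, 50),
    )
    def test_partition_property(self, mus, bin_size):
        mus = np.asarray(mus)
        bins = bin_genes(mus, bin_size=bin_size, floor=10)
        above = mus >= 10
        assert (bins[~above] == -1).all()
        if above.any():
            counts = np.bincount(bins[above])
            assert counts.sum() == above.sum()
            assert counts.max() <= bin_size


class TestBootstrap:
    def test_identical_groups_one_sided_p_is_half(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 150)
        res = bootstrap_dm_test(x, x.copy(), n_boot=4000, seed=0, alternative="greater")
        assert res.t_obs == pytest.approx(0.0)
        assert abs(res.p_h0 - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_extreme_separation_hits_formula_floor(self):
        rng = np.random.default_rng(6)
        up = 1.0 + 0.01 * rng.normal(size=100)
        down = -1.0 + 0.01 * rng.normal(size=100)
        res = bootstrap_dm_test(up, down, n_boot=10_000, seed=1)
        assert res.p_h0 == pytest.approx(1 / 10_001)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_p_within_formula_bounds(self, seed):
        rng = np.random.default_rng(seed)
        res = bootstrap_dm_test(
            rng.normal(size=30), rng.normal(size=40), n_boot=500, seed=seed
        )
        assert 1 / 501 <= res.p_h0 <= 1.0

    def test_power_increases_with_separation(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 100)
        other = rng.normal(0, 1, 100)
        ps = []
        for delta in (0.0, 0.6, 1.2):
            res = bootstrap_dm_test(base + delta, other, n_boot=2000, seed=8)
            ps.append(res.p_h0)
        assert ps[2] < ps[0]
        assert ps[2] < 0.01

    def test_degenerate_replicates_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = bootstrap_dm_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], n_boot=50, seed=0)
        # every t_i forced to 0, none strictly exceeds |t_obs| = 0
        assert res.t_obs == 0.0
        assert res.p_h0 == pytest.approx(1 / 51)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_dm_test([1.0], [1.0, 2.0])


class TestRankSum:
    def test_exact_small_sample_against_enumeration(self):
        """Brute-force enumeration of all rank assignments as the oracle."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = sorted(x + y)
        n = len(x)
        u_obs = sum(1 for xi in x for yj in y if xi > yj)
        u_all = []
        for combo in itertools.combinations(range(len(pooled)), n):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u_all.append(sum(1 for xi in xs for yj in ys if xi > yj))
        u_all = np.array(u_all)
        mid = n * len(y) / 2
        p_exact = np.mean(np.abs(u_all - mid) >= abs(u_obs - mid))
        assert p_exact == pytest.approx(0.1)
        assert ranksum_test(x, y) == pytest.approx(p_exact)

    def test_identical_samples_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ranksum_test(x, x) == pytest.approx(1.0, abs=0.01)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.7, 1, 35)
        assert ranksum_test(x, y) == pytest.approx(
            ranksum_test(np.exp(x), np.exp(y))
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])
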