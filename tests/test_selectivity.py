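"""Timescale selectivity profiles, T-bar, and cross-condition comparison."""

import numpy as np
import pytest

from timescales.filterbank import band_timescales
from timescales.selectivity import (
    compare_selectivity,
    compute_selectivity,
    group_aggregate,
    per_band_comparison,
    profile_correlation,
    selectivity_profile,
    timescale_selectivity,
)

T8 = band_timescales()


class TestProfile:
    def test_rectified_normalisation(self):
        split = np.array([[0.2, -0.1, 0.2, 0, 0, 0, 0, 0]]).T  # (8, 1)
        profile, defined = selectivity_profile(split)
        np.testing.assert_allclose(profile[0], [0.5, 0, 0.5, 0, 0, 0, 0, 0])
        assert defined[0]

    def test_single_positive_entry_gives_one_hot(self):
        split = np.zeros((8, 1))
        split[5] = 0.3
        profile, _ = selectivity_profile(split)
        expected = np.zeros(8)
        expected[5] = 1.0
        np.testing.assert_array_equal(profile[0], expected)

    def test_all_nonpositive_flagged_undefined(self):
        split = -np.ones((8, 2))
        profile, defined = selectivity_profile(split)
        assert not defined.any()
        assert np.isnan(profile).all()

    def test_rows_sum_to_one_where_defined(self, rng):
        split = rng.standard_normal((8, 100))
        profile, defined = selectivity_profile(split)
        np.testing.assert_allclose(profile[defined].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(profile[defined] >= 0)


class TestTbar:
    def test_one_hot_recovers_band_timescale(self):
        profile = np.zeros((1, 8))
        profile[0, 3] = 1.0
        np.testing.assert_allclose(timescale_selectivity(profile, T8), 24.0)

    def test_equal_weights_give_geometric_mean(self):
        profile = np.array([[0.5, 0.5]])
        np.testing.assert_allclose(
            timescale_selectivity(profile, np.array([3.0, 6.0])), np.sqrt(18.0)
        )

    def test_uniform_profile_gives_full_geometric_mean(self):
        profile = np.full((1, 8), 1 / 8)
        np.testing.assert_allclose(
            timescale_selectivity(profile, T8), np.prod(T8) ** (1 / 8)
        )

    def test_tbar_bounded_by_extreme_timescales(self, rng):
        split = rng.standard_normal((8, 200))
        result = compute_selectivity(split, T8)
        t = result.tbar[result.defined]
        assert np.all(t >= T8.min() - 1e-9) and np.all(t <= T8.max() + 1e-9)

    def test_undefined_profile_propagates_nan(self):
        result = compute_selectivity(-np.ones((8, 1)), T8)
        assert np.isnan(result.tbar[0])

    def test_nonpositive_timescale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            timescale_selectivity(np.full((1, 2), 0.5), np.array([3.0, 0.0]))


class TestComparison:
    def test_identical_selectivity_gives_unit_correlation(self, rng):
        tbar = rng.uniform(3, 384, 50)
        mask = np.ones(50, bool)
        res = compare_selectivity(tbar, tbar, mask)
        assert res.r == pytest.approx(1.0)
        assert np.isnan(res.p)  # no null inputs supplied

    def test_shift_invariance(self, rng):
        a = rng.uniform(3, 384, 40)
        b = rng.uniform(3, 384, 40)
        mask = np.ones(40, bool)
        r1 = compare_selectivity(a, b, mask).r
        r2 = compare_selectivity(a + 100.0, b, mask).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_small_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="3 voxels"):
            compare_selectivity(np.ones(5), np.ones(5), np.array([1, 1, 0, 0, 0], bool))

    def test_permutation_null_detects_shared_structure(self, rng):
        """Matched predictions give high r with small p; the null r values
        scatter around zero."""
        n, v = 120, 30
        y_a = rng.standard_normal((n, v))
        y_b = rng.standard_normal((n, v))
        # predictions dominated by one band per voxel, with small
        # components in every band (as a fitted model would produce)
        bands_a = [0.2 * rng.standard_normal((n, v)) for _ in range(8)]
        bands_b = [0.2 * rng.standard_normal((n, v)) for _ in range(8)]
        true_band = np.arange(v) % 8
        for vox, band in enumerate(true_band):
            bands_a[band][:, vox] += y_a[:, vox]
            bands_b[band][:, vox] += y_b[:, vox]
        yhat_a = sum(bands_a)
        yhat_b = sum(bands_b)
        split_a = np.stack([ (b * y_a).sum(0) / np.sqrt((yhat_a**2).sum(0) * (y_a**2).sum(0)) for b in bands_a])
        split_b = np.stack([ (b * y_b).sum(0) / np.sqrt((yhat_b**2).sum(0) * (y_b**2).sum(0)) for b in bands_b])
        res_a = compute_selectivity(split_a, T8)
        res_b = compute_selectivity(split_b, T8)
        mask = res_a.defined & res_b.defined
        res = compare_selectivity(
            res_a.tbar, res_b.tbar, mask,
            null_a=(bands_a, yhat_a, y_a), null_b=(bands_b, yhat_b, y_b),
            timescales=T8, n_perm=200, seed=0,
        )
        assert res.r > 0.95
        assert res.p <= 0.01
        # null correlations sit well below the observed correlation
        assert np.nanmax(res.null) < res.r
        assert abs(np.nanmean(res.null)) < 0.5

    def test_per_band_identical_profiles_give_unit_correlations(self, rng):
        profile = rng.dirichlet(np.ones(8), size=30)
        jittered = profile + 1e-9 * rng.standard_normal(profile.shape)
        r, p = per_band_comparison(profile, jittered, np.ones(30, bool))
        np.testing.assert_allclose(r, 1.0, atol=1e-5)
        assert np.isnan(p).all()

    def test_independent_profiles_center_on_zero(self, rng):
        r_values = []
        for _ in range(30):
            a = rng.dirichlet(np.ones(8), size=100)
            b = rng.dirichlet(np.ones(8), size=100)
            r, _ = per_band_comparison(a, b, np.ones(100, bool))
            r_values.append(r)
        assert abs(np.mean(r_values)) < 0.05


class TestProfileCorrelation:
    def test_identical_profiles(self, rng):
        profile = rng.dirichlet(np.ones(8), size=10)
        out = profile_correlation(profile, profile)
        np.testing.assert_allclose(out, 1.0)

    def test_reversed_monotone_profile_is_negative(self):
        a = np.linspace(0.01, 0.3, 8)[None, :]
        a = a / a.sum()
        out = profile_correlation(a, a[:, ::-1])
        assert out[0] < -0.9

    def test_uniform_profile_undefined(self):
        a = np.full((1, 8), 1 / 8)
        assert np.isnan(profile_correlation(a, a)[0])

    def test_mask_and_nan_rows_excluded(self, rng):
        profile = rng.dirichlet(np.ones(8), size=4)
        profile_b = profile.copy()
        profile_b[2] = np.nan
        out = profile_correlation(profile, profile_b, np.array([1, 0, 1, 1], bool))
        assert np.isnan(out[1]) and np.isnan(out[2]) and out[3] == pytest.approx(1.0)


class TestGroupAggregate:
    def test_mean_over_selective_subjects(self):
        values = np.array([[3.0], [6.0], [12.0], [99.0]])
        masks = np.array([[1], [1], [1], [0]], bool)
        mean, mask = group_aggregate(values, masks, min_fraction=1 / 3)
        assert mean[0] == pytest.approx(7.0)
        assert mask[0]

    def test_one_third_threshold_inclusive(self):
        masks = np.zeros((9, 1), bool)
        masks[:3] = True
        values = np.ones((9, 1))
        _, mask = group_aggregate(values, masks, min_fraction=1 / 3)
        assert mask[0]
        masks[2] = False
        _, mask = group_aggregate(values, masks, min_fraction=1 / 3)
        assert not mask[0]

    def test_unselected_vertex_is_nan(self):
        mean, mask = group_aggregate(np.ones((3, 1)), np.zeros((3, 1), bool))
        assert np.isnan(mean[0]) and not mask[0]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            group_aggregate(np.ones((2, 3)), np.ones((2, 4), bool))

    def test_log_domain_geometric_mean(self):
        values = np.array([[4.0], [16.0]])
        masks = np.ones((2, 1), bool)
        mean, _ = group_aggregate(values, masks, log_domain=True)
        assert mean[0] == pytest.approx(8.0)
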