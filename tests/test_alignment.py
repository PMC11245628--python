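"""Temporal alignment: interpolation, resampling, trimming, z-scoring,
FIR delays and BOLD preprocessing."""

import numpy as np
import pytest
from scipy.signal import savgol_filter

from timescales.alignment import (
    add_fir_delays,
    average_test_repeats,
    dense_grid,
    lanczos_downsample,
    preprocess_bold,
    rbf_interpolate,
    savgol_window_trs,
    tr_midpoints,
    trim_runs,
    zscore_features,
)

TR = 2.0


class TestRBFInterpolation:
    def test_constant_word_signal_gives_constant_interpolant(self):
        times = np.linspace(1.0, 39.0, 50)
        out = rbf_interpolate(np.full(50, 3.5), times, n_trs=20, tr=TR)
        np.testing.assert_allclose(out, 3.5, atol=1e-12)

    def test_single_word_produces_bump_at_word_time(self):
        out = rbf_interpolate(np.array([1.0]), np.array([20.0]), n_trs=20, tr=TR,
                              sigma=1.0)
        grid = dense_grid(20, TR)
        # normalised single kernel is identically 1; check the kernel itself peaks
        np.testing.assert_allclose(out, 1.0)
        assert abs(grid[np.argmin(np.abs(grid - 20.0))] - 20.0) < TR / 25

    def test_dense_equal_spacing_interpolates_word_values(self):
        """Direct evaluation of the stated kernel sum at the word times."""
        spacing = 0.5
        times = np.arange(2.0, 38.0, spacing)
        values = np.sin(2 * np.pi * times / 20.0)
        out = rbf_interpolate(values, times, n_trs=20, tr=TR, sigma=spacing)[0]
        grid = dense_grid(20, TR)
        for t, v in zip(times[4:-4:7], values[4:-4:7]):
            k = np.argmin(np.abs(grid - t))
            assert abs(out[k] - v) <= 0.05 * max(abs(v), 0.2)

    def test_zero_words_yields_zeros_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = rbf_interpolate(np.empty((2, 0)), np.empty(0), n_trs=4, tr=TR)
        assert out.shape == (2, 100)
        assert np.all(out == 0)

    def test_word_outside_run_rejected(self):
        with pytest.raises(ValueError, match="time span"):
            rbf_interpolate(np.array([1.0]), np.array([100.0]), n_trs=4, tr=TR)


class TestLanczosDownsampling:
    def make_dense(self, signal_fn, n_trs=100):
        t = dense_grid(n_trs, TR)
        return signal_fn(t), t

    def test_constant_preserved_exactly(self):
        dense, _ = self.make_dense(lambda t: np.full_like(t, 2.7))
        out = lanczos_downsample(dense, 100, TR)
        np.testing.assert_allclose(out, 2.7, atol=1e-12)

    def test_passband_sinusoid_amplitude_preserved(self):
        dense, _ = self.make_dense(lambda t: np.sin(2 * np.pi * 0.05 * t))
        out = lanczos_downsample(dense, 100, TR)[0]
        t_out = tr_midpoints(100, TR)
        expected = np.sin(2 * np.pi * 0.05 * t_out)
        core = slice(10, 90)
        amp = np.abs(out[core]).max()
        assert abs(amp - 1.0) < 0.05
        np.testing.assert_allclose(out[core], expected[core], atol=0.06)

    def test_stopband_sinusoid_attenuated(self):
        dense, _ = self.make_dense(lambda t: np.sin(2 * np.pi * 0.45 * t))
        out = lanczos_downsample(dense, 100, TR)[0]
        assert np.abs(out[10:-10]).max() <= 0.2

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            lanczos_downsample(np.zeros(100 * 25), 100, TR, cutoff=0.0)

    def test_interpolate_then_downsample_constant_is_exact(self):
        times = np.linspace(2.0, 198.0, 400)
        dense = rbf_interpolate(np.full(400, 1.3), times, n_trs=100, tr=TR)
        out = lanczos_downsample(dense, 100, TR)
        np.testing.assert_allclose(out, 1.3, atol=1e-6)


class TestTrim:
    def test_single_run_arithmetic(self):
        out = trim_runs(np.zeros((300, 2)), (300,), trim=10)
        assert out.shape == (280, 2)

    def test_zero_trim_is_identity(self):
        x = np.arange(12.0).reshape(6, 2)
        np.testing.assert_array_equal(trim_runs(x, (6,), 0), x)

    def test_two_runs(self):
        out = trim_runs(np.zeros((620, 1)), (300, 320), trim=10)
        assert out.shape == (580, 1)

    def test_too_short_run_named(self):
        with pytest.raises(ValueError, match="run 1"):
            trim_runs(np.zeros((315, 1)), (300, 15), trim=10)


class TestZScore:
    def test_train_channel_standardised(self):
        x = np.array([[1.0], [2.0], [3.0], [10.0]])
        mask = np.array([True, True, True, False])
        z, mean, std, flags = zscore_features(x, mask)
        assert abs(z[:3, 0].mean()) < 1e-12
        assert abs(z[:3, 0].std() - 1) < 1e-12
        assert mean[0] == 2.0 and not flags[0]

    def test_constant_channel_flagged_and_zeroed(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        z, _, _, flags = zscore_features(x, np.ones(5, bool))
        assert flags[0] and not flags[1]
        np.testing.assert_array_equal(z[:, 0], 0.0)

    def test_test_rows_not_centred(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((100, 1))
        x[80:] += 5.0
        mask = np.zeros(100, bool)
        mask[:80] = True
        z, *_ = zscore_features(x, mask)
        assert abs(z[80:].mean()) > 1.0  # train stats applied, test mean far from 0


class TestFIRDelays:
    def test_channel_count_multiplies_by_delays(self):
        out, tags = add_fir_delays(np.zeros((40, 3)), (20, 20), delays=(1, 2, 3, 4))
        assert out.shape == (40, 12)
        assert tags.tolist() == [1] * 3 + [2] * 3 + [3] * 3 + [4] * 3

    def test_impulse_shifts_within_run(self):
        x = np.zeros((20, 1))
        x[0, 0] = 1.0
        out, _ = add_fir_delays(x, (20,), delays=(2,))
        assert out[2, 0] == 1.0 and out.sum() == 1.0

    def test_shift_never_crosses_run_boundary(self):
        x = np.zeros((20, 1))
        x[9, 0] = 1.0  # last TR of run 1
        out, _ = add_fir_delays(x, (10, 10), delays=(2,))
        assert np.all(out[10:] == 0.0)

    def test_delay_exceeding_run_rejected(self):
        with pytest.raises(ValueError, match="shortest run"):
            add_fir_delays(np.zeros((8, 1)), (4, 4), delays=(4,))


class TestBOLDPreprocessing:
    def test_slow_cosine_removed(self):
        t = np.arange(300) * TR
        slow = np.cos(2 * np.pi * t / 400.0)[:, None]
        window = savgol_window_trs(TR)
        resid = slow - savgol_filter(slow, window, 3, axis=0)
        assert resid.std() <= 0.1 * slow.std()  # oracle: the stated SG smooth
        # within preprocess_bold, detrending lets a fast component dominate
        fast = np.sin(2 * np.pi * t / 20.0)[:, None]
        x = 10.0 * slow + fast
        out_detr = preprocess_bold(x, (300,), TR, detrend=True)
        out_raw = preprocess_bold(x, (300,), TR, detrend=False)
        assert np.corrcoef(out_detr[:, 0], fast[:, 0])[0, 1] > 0.95
        assert np.corrcoef(out_raw[:, 0], fast[:, 0])[0, 1] < 0.5

    def test_white_noise_variance_roughly_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((400, 5))
        window = savgol_window_trs(TR)
        resid = x - savgol_filter(x, window, 3, axis=0)
        assert abs(resid.var() / x.var() - 1.0) <= 0.15

    def test_output_standardised_per_run(self):
        rng = np.random.default_rng(2)
        x = 3.0 + 2.0 * rng.standard_normal((200, 4))
        out = preprocess_bold(x, (100, 100), TR, detrend=False)
        for sl in (slice(0, 100), slice(100, 200)):
            np.testing.assert_allclose(out[sl].mean(axis=0), 0.0, atol=1e-9)
            np.testing.assert_allclose(out[sl].std(axis=0), 1.0, atol=1e-9)

    def test_short_run_skips_detrend_with_warning(self):
        x = np.random.default_rng(3).standard_normal((30, 2))
        with pytest.warns(UserWarning, match="skipped"):
            preprocess_bold(x, (30,), TR, detrend=True)

    def test_window_is_nearest_odd_tr_count(self):
        assert savgol_window_trs(2.0045) == 59  # 120 s / 2.0045 s = 59.87
        assert savgol_window_trs(2.0) == 59  # 60.0 is a tie; the lower odd wins


class TestRepeatAveraging:
    def test_identity_and_cancellation(self):
        y = np.arange(6.0).reshape(3, 2)
        np.testing.assert_array_equal(average_test_repeats(y, y), y)
        np.testing.assert_array_equal(average_test_repeats(y, -y), np.zeros_like(y))

    def test_noise_variance_halves(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 5000, 3))
        avg = average_test_repeats(a, b)
        assert abs(avg.var() / a.var() - 0.5) < 0.05

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            average_test_repeats(np.zeros((3, 2)), np.zeros((4, 2)))
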