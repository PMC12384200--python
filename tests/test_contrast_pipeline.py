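"""Noise-corrected contrast chain: dark stats, masking, correction, BFi."""

import numpy as np
import pytest
from scipy.stats import norm

from dsca import (
    ContrastSeries,
    DarkModel,
    DarkStatistics,
    FrameStack,
    PixelMask,
    bfi_from_contrast,
    corrected_contrast_sq,
    estimate_dark_statistics,
    flag_bad_pixels,
    generate_dark_frames,
    generate_speckle_frames,
    normalize_bfi,
    process_stack,
    smooth_series,
)
from dsca.contrast_pipeline import smooth


def _stack(counts, frame_rate=100.0):
    return FrameStack(np.asarray(counts, dtype=np.uint32), 1e-3, frame_rate, 10.0)


class TestDarkStatistics:
    def test_constant_stack(self):
        st = _stack(np.full((10, 4, 4), 7))
        ds = estimate_dark_statistics(st)
        assert np.all(ds.mean_map == 7.0)
        assert np.all(ds.var_map == 0.0)
        assert ds.n_frames_used == 10

    def test_poisson_mean_matches_variance(self, rng):
        st = _stack(rng.poisson(5.0, size=(2000, 8, 8)))
        ds = estimate_dark_statistics(st)
        assert ds.mean_map.mean() == pytest.approx(5.0, abs=0.05)
        assert ds.var_map.mean() == pytest.approx(5.0, abs=0.15)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            estimate_dark_statistics(_stack(np.zeros((1, 4, 4))))


class TestBadPixelFlagging:
    def test_uniform_image_flags_nothing(self):
        mask = flag_bad_pixels(np.full((16, 16), 3.0))
        assert mask.n_flagged == 0

    def test_planted_outlier_flagged(self, rng):
        img = rng.normal(10.0, 1.0, size=(32, 32))
        img[5, 7] = 10.0 + 100.0
        mask = flag_bad_pixels(img)
        assert not mask.valid[5, 7]

    def test_gaussian_flagged_fraction_near_two_sided_tail(self, rng):
        img = rng.normal(0.0, 1.0, size=(512, 512))
        mask = flag_bad_pixels(img)
        frac = mask.n_flagged / img.size
        expect = 2 * norm.cdf(-3)  # ~0.0027
        se = np.sqrt(expect * (1 - expect) / img.size)
        assert abs(frac - expect) < 5 * se

    def test_rejects_nonfinite_reference(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            flag_bad_pixels(img)


class TestCorrectedContrast:
    def test_pure_poisson_flat_field_corrects_to_zero(self):
        """Shot-noise-only frames: kappa_m^2 ~ 1/<I>, kappa_c^2 centered on 0."""
        rng = np.random.default_rng(4)
        frames = rng.poisson(40.0, size=(300, 64, 64))
        km, kc = [], []
        for f in frames:
            m, c, mu, budget = corrected_contrast_sq(f)
            km.append(m)
            kc.append(c)
            assert budget.kappa_r_sq == 0.0 and budget.kappa_q_sq == 0.0
        km, kc = np.array(km), np.array(kc)
        se = kc.std(ddof=1) / np.sqrt(len(kc))
        assert abs(kc.mean()) < 3 * se
        assert km.mean() == pytest.approx(1.0 / 40.0, rel=0.05)

    def test_gamma_poisson_recovers_target(self):
        st = generate_speckle_frames(0.25, 50.0, n_frames=200, shape=(64, 64), seed=8)
        series = process_stack(st)
        se = series.kappa_c_sq.std(ddof=1) / np.sqrt(len(series))
        assert abs(series.kappa_c_sq.mean() - 0.25) < 3 * se + 0.005

    def test_noise_budget_identity_per_frame(self):
        """kappa_m^2 - kappa_c^2 == 1/<Ic> + kappa_d^2 exactly."""
        rng = np.random.default_rng(6)
        dark = DarkStatistics(
            mean_map=np.full((32, 32), 2.0), var_map=rng.uniform(1, 3, (32, 32)),
            n_frames_used=100,
        )
        frame = rng.poisson(30.0, size=(32, 32))
        km, kc, mu, budget = corrected_contrast_sq(frame, dark)
        assert km - kc == pytest.approx(1.0 / mu + budget.kappa_d_sq, rel=1e-12)
        assert budget.kappa_s_sq == pytest.approx(1.0 / mu, rel=1e-12)

    def test_masked_pixels_never_contribute(self):
        rng = np.random.default_rng(7)
        frame = rng.poisson(30.0, size=(16, 16)).astype(float)
        mask = PixelMask.all_valid((16, 16))
        mask.valid[3, 3] = False
        ref = corrected_contrast_sq(frame, mask=mask)
        poisoned = frame.copy()
        poisoned[3, 3] = 1e9
        got = corrected_contrast_sq(poisoned, mask=mask)
        assert got[:3] == ref[:3]

    def test_nonpositive_mean_yields_missing(self):
        dark = DarkStatistics(np.full((8, 8), 10.0), np.zeros((8, 8)), 10)
        km, kc, mu, _ = corrected_contrast_sq(np.zeros((8, 8)), dark)
        assert np.isnan(km) and np.isnan(kc)

    def test_under_two_valid_pixels_rejected(self):
        mask = PixelMask(np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            corrected_contrast_sq(np.ones((4, 4)), mask=mask)

    def test_process_stack_matches_per_frame_loop(self):
        st = generate_speckle_frames(0.2, 30.0, n_frames=7, shape=(16, 16), seed=12)
        dark = DarkStatistics(
            np.full((16, 16), 1.0), np.full((16, 16), 1.2), 50
        )
        series = process_stack(st, dark, chunk_frames=3)
        for i, frame in enumerate(st.counts):
            km, kc, mu, _ = corrected_contrast_sq(frame, dark)
            assert series.kappa_m_sq[i] == pytest.approx(km, rel=1e-12)
            assert series.kappa_c_sq[i] == pytest.approx(kc, rel=1e-12)
            assert series.mean_intensity[i] == pytest.approx(mu, rel=1e-12)


class TestEstimatorConsistency:
    @pytest.mark.parametrize("target", [0.05, 0.5])
    def test_bias_small_at_full_array(self, target):
        """Mean kappa_c^2 within 2% of target at 128x128, mean >= 10 photons."""
        st = generate_speckle_frames(
            target, 10.0, n_frames=150, shape=(128, 128), seed=int(target * 1000)
        )
        series = process_stack(st)
        assert series.kappa_c_sq.mean() == pytest.approx(target, rel=0.02)


class TestBfi:
    def test_reciprocal_values(self):
        assert bfi_from_contrast(0.25) == 4.0
        assert bfi_from_contrast(1.0) == 1.0
        assert bfi_from_contrast(0.125) == 2 * bfi_from_contrast(0.25)

    def test_nonpositive_contrast_is_missing_not_infinite(self):
        out = bfi_from_contrast(np.array([0.25, 0.0, -0.1]))
        assert out[0] == 4.0
        assert np.isnan(out[1]) and np.isnan(out[2])


def _series(bfi, frame_rate=10.0):
    n = len(bfi)
    bfi = np.asarray(bfi, dtype=float)
    kappa = np.where(bfi > 0, 1.0 / bfi, np.nan)
    return ContrastSeries(
        timestamps=np.arange(n) / frame_rate,
        kappa_m_sq=kappa,
        kappa_c_sq=kappa,
        mean_intensity=np.full(n, 50.0),
        bfi=bfi,
    )


class TestNormalization:
    def test_constant_series_normalizes_to_one(self):
        s = normalize_bfi(_series(np.full(50, 7.0)), (0.0, 2.0))
        np.testing.assert_allclose(s.rbfi, 1.0)

    def test_relative_value(self):
        bfi = np.concatenate([np.full(20, 2.0), np.full(20, 5.0)])
        s = normalize_bfi(_series(bfi), (0.0, 2.0))
        assert s.rbfi[-1] == pytest.approx(2.5)

    def test_baseline_mean_is_one_exactly(self, rng):
        s = normalize_bfi(_series(rng.uniform(1, 3, 100)), (0.0, 4.0))
        sel = s.timestamps < 4.0
        assert s.rbfi[sel].mean() == pytest.approx(1.0, rel=1e-12)

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValueError):
            normalize_bfi(_series(np.ones(10)), (100.0, 101.0))


class TestSmoothing:
    def test_constant_series_unchanged(self):
        s = smooth_series(_series(np.full(60, 3.0)), 20)
        np.testing.assert_allclose(s.bfi, 3.0)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(200)
        x[100] = 1.0
        y = smooth(x, 20)
        assert np.sum(np.isclose(y, 1.0 / 20)) == 20
        assert y.sum() == pytest.approx(1.0, rel=1e-9)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_array_equal(smooth(x, 1), x)

    def test_nan_values_excluded_from_windows(self):
        x = np.full(50, 2.0)
        x[25] = np.nan
        y = smooth(x, 5)
        np.testing.assert_allclose(y, 2.0)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.ones(5), 6)


class TestHotPixelRecovery:
    def test_planted_hot_pixels_recovered_by_sigma_rule(self):
        """1% planted hot pixels at 50x dark rate: sensitivity >= 0.99."""
        dm = DarkModel(base_rate=2.0, hot_fraction=0.01, hot_multiplier=50.0)
        stack = generate_dark_frames(dm, n_frames=300, shape=(128, 128), seed=21)
        stats = estimate_dark_statistics(stack)
        mask = flag_bad_pixels(stats.mean_map)
        hot = np.zeros(128 * 128, dtype=bool)
        hot[np.array(stack.metadata["hot_pixel_flat_indices"])] = True
        flagged = ~mask.valid.ravel()
        sensitivity = flagged[hot].mean()
        assert sensitivity >= 0.99
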