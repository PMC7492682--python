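"""Luminance computation, alignment, regression and residual properties."""

import numpy as np
import pytest

from gazemotion.luminance import (
    LuminanceModel,
    LuminanceSeries,
    align_luminance,
    fit_luminance_model,
    frame_luminance,
    luminance_diagnostics,
    neighbourhood_luminance,
    neighbourhood_series,
    remove_luminance_effect,
    variant_correlation,
)
from gazemotion.recording import ScreenGeometry

from conftest import make_recording


class TestFrameLuminance:
    def test_black_white_and_half(self):
        assert frame_luminance(np.zeros((8, 8))) == 0.0
        assert frame_luminance(np.full((8, 8), 255, dtype=np.uint8)) == 1.0
        half = np.zeros((8, 8))
        half[:, 4:] = 1.0
        assert frame_luminance(half) == pytest.approx(0.5)

    def test_colour_frame_uses_value_channel(self):
        frame = np.zeros((4, 4, 3), dtype=np.uint8)
        frame[..., 2] = 255  # pure blue: V = 1
        assert frame_luminance(frame) == 1.0

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            frame_luminance(np.zeros((0, 5)))


class TestNeighbourhood:
    def test_uniform_frame_independent_of_gaze(self):
        frame = np.full((30, 40), 0.37)
        for gaze in [(0, 0), (20, 15), (39, 29)]:
            assert neighbourhood_luminance(frame, gaze, diameter_px=10) == pytest.approx(0.37)

    def test_dark_disk_containing_circle(self):
        frame = np.ones((60, 60))
        yy, xx = np.ogrid[:60, :60]
        frame[(xx - 30) ** 2 + (yy - 30) ** 2 <= 20**2] = 0.1
        assert neighbourhood_luminance(frame, (30, 30), diameter_px=16) == pytest.approx(0.1)

    def test_matches_brute_force_mask(self):
        rng = np.random.default_rng(5)
        frame = rng.random((50, 70))
        gx, gy, r = 33.0, 24.0, 9.0
        yy, xx = np.ogrid[:50, :70]
        mask = (xx - gx) ** 2 + (yy - gy) ** 2 <= r**2
        expected = frame[mask].mean()
        assert neighbourhood_luminance(frame, (gx, gy), diameter_px=2 * r) == pytest.approx(
            expected, abs=1e-12
        )

    def test_series_agrees_with_per_sample_calls(self):
        rng = np.random.default_rng(7)
        screen = ScreenGeometry(width_px=160, height_px=120)  # frame == screen grid
        frames = rng.random((4, 120, 160))
        gx = np.array([10, 50, 100, 140, 20, 80], float)
        gy = np.array([10, 60, 100, 15, 110, 55], float)
        rec = make_recording(gx, gy, rate=1.5)  # 1.5 Hz samples over 4 x 1 Hz frames
        got = neighbourhood_series(frames, rec, frame_rate=1.0, diameter_px=14, screen=screen)
        t = rec.timestamps
        fidx = np.clip(np.floor(t * 1.0).astype(int), 0, 3)
        for k in range(len(gx)):
            expected = neighbourhood_luminance(frames[fidx[k]], (gx[k], gy[k]), diameter_px=14)
            assert got[k] == pytest.approx(expected, abs=1e-12)


class TestAlignment:
    def test_equal_rates_identity_pairing(self):
        series = LuminanceSeries(np.arange(10) / 10.0, frame_rate=60.0)
        rec = make_recording(np.zeros(10), np.zeros(10), rate=60.0)
        np.testing.assert_array_equal(align_luminance(series, rec), series.values)

    def test_25fps_versus_60hz_repeats_frames(self):
        series = LuminanceSeries(np.arange(25) / 25.0, frame_rate=25.0)
        rec = make_recording(np.zeros(60), np.zeros(60), rate=60.0)
        aligned = align_luminance(series, rec)
        assert aligned.size == 60
        counts = np.unique(np.round(aligned * 25).astype(int), return_counts=True)[1]
        assert set(counts) <= {2, 3}

    def test_step_change_lands_on_the_right_sample(self):
        values = np.r_[np.zeros(10), np.ones(10)]
        series = LuminanceSeries(values, frame_rate=25.0)
        rec = make_recording(np.zeros(48), np.zeros(48), rate=60.0)
        aligned = align_luminance(series, rec)
        step_sample = int(np.argmax(aligned > 0.5))
        assert abs(step_sample - 24) <= 1  # 10 frames / 25 fps * 60 Hz

    def test_empty_series_rejected(self):
        rec = make_recording(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            align_luminance(LuminanceSeries(np.array([]), 25.0), rec)


class TestRegression:
    def test_noise_free_exact_recovery(self):
        x = np.linspace(0, 1, 500)
        y = 30.0 - 11.0 * x
        model = fit_luminance_model(y, x)
        assert model.b0 == pytest.approx(30.0, abs=1e-9)
        assert model.b1 == pytest.approx(-11.0, abs=1e-9)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(11)
        n = 10_000
        x = rng.uniform(0, 1, n)
        noise_sd = 0.8
        y = 29.84 - 11.23 * x + rng.normal(0, noise_sd, n)
        model = fit_luminance_model(y, x)
        se_b1 = noise_sd / (np.std(x) * np.sqrt(n))
        se_b0 = noise_sd * np.sqrt(1 / n + x.mean() ** 2 / (n * np.var(x)))
        assert abs(model.b1 - (-11.23)) < 3 * se_b1
        assert abs(model.b0 - 29.84) < 3 * se_b0

    def test_constant_luminance_unidentifiable(self):
        with pytest.raises(ValueError):
            fit_luminance_model(np.array([1.0, 2.0]), np.array([0.5, 0.5]))

    def test_residual_orthogonality_on_fitting_data(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 2000)
        y = 28.0 - 10.0 * x + rng.normal(0, 0.5, 2000)
        model = fit_luminance_model(y, x)
        resid = remove_luminance_effect(y, model, x)
        assert abs(resid.mean()) < 1e-10
        assert abs(np.corrcoef(resid, x)[0, 1]) < 1e-10

    def test_correction_idempotent(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 1000)
        y = 31.0 - 12.0 * x + rng.normal(0, 0.3, 1000)
        resid = remove_luminance_effect(y, fit_luminance_model(y, x), x)
        refit = fit_luminance_model(resid, x)
        assert refit.b1 == pytest.approx(0.0, abs=1e-9)

    def test_zero_slope_model_is_pure_centering(self):
        y = np.array([3.0, 4.0, 5.0])
        x = np.array([0.1, 0.5, 0.9])
        resid = remove_luminance_effect(y, LuminanceModel(b0=4.0, b1=0.0), x)
        np.testing.assert_allclose(resid, y - 4.0)


class TestDiagnostics:
    def test_identical_variants_fully_correlated(self):
        rng = np.random.default_rng(2)
        r = rng.normal(size=300)
        assert variant_correlation(r, r) == pytest.approx(1.0)

    def test_localized_bright_patch_separates_variants(self):
        # background brightens steadily while gaze alternates between a
        # fixed bright patch and the background: whole-frame luminance rises
        # monotonically but the neighbourhood series oscillates
        frames = np.empty((6, 40, 60))
        gaze = []
        for i in range(6):
            frames[i] = 0.2 + 0.05 * i
            frames[i, 10:20, 5:15] = 0.95  # localized bright patch
            gaze.append((10, 15) if i % 2 == 0 else (50, 35))
        whole = np.array([frame_luminance(f) for f in frames])
        neigh = np.array(
            [neighbourhood_luminance(f, g, diameter_px=6) for f, g in zip(frames, gaze)]
        )
        assert np.all(np.diff(whole) > 0)
        assert abs(variant_correlation(whole, neigh)) < 0.9

    def test_correction_shrinks_per_movie_correlation(self):
        rng = np.random.default_rng(17)
        pupil, lum, resid = {}, {}, {}
        for pid in ("S01", "S02", "S03"):
            b0, b1 = rng.uniform(28, 32), rng.uniform(-13, -9)
            for mid in ("m1", "m2", "m3", "m4"):
                x = rng.uniform(0.2, 0.8) + rng.normal(0, 0.05, 400)
                y = b0 + b1 * x + rng.normal(0, 0.4, 400)
                pupil[(pid, mid)], lum[(pid, mid)] = y, x
        for pid in ("S01", "S02", "S03"):
            keys = [k for k in pupil if k[0] == pid]
            from gazemotion.luminance import fit_luminance_model as fit
            model = fit(np.concatenate([pupil[k] for k in keys]),
                        np.concatenate([lum[k] for k in keys]))
            for k in keys:
                resid[k] = remove_luminance_effect(pupil[k], model, lum[k])
        diag = luminance_diagnostics(pupil, lum, resid)
        assert diag["mean_pre"] < -0.5
        assert abs(diag["mean_post"]) < 0.05
        assert abs(diag["per_movie_post_median"]) < abs(diag["per_movie_pre_median"])
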