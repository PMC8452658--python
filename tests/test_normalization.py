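import numpy as np
import pytest

from lairef import Grid, aggregate_mean, apply_normalization, \
    fit_band_normalization, ndvi
from lairef.normalization import load_normalization, save_normalization
from lairef.synthetic import SceneConfig, generate_landscape, \
    render_reflectance, simulate_coarse_reference


def fine_band(seed=0, shape=(40, 40), label="red"):
    rng = np.random.default_rng(seed)
    return Grid(rng.uniform(0.05, 0.6, shape), band_label=label)


class TestFitBandNormalization:
    def test_identity_pairs(self):
        fine = fine_band()
        coarse = aggregate_mean(fine, 10)
        m = fit_band_normalization(fine, coarse, 10)
        assert m.mode == "regression"
        assert m.slope == pytest.approx(1.0, abs=1e-9)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0)

    def test_exact_affine_distortion_recovered(self):
        fine = fine_band(1)
        agg = aggregate_mean(fine, 10)
        coarse = agg.with_values(0.9 * agg.values + 0.02)
        m = fit_band_normalization(fine, coarse, 10)
        assert m.mode == "regression"
        assert m.slope == pytest.approx(0.9, abs=1e-9)
        assert m.intercept == pytest.approx(0.02, abs=1e-9)

    def test_uncorrelated_pairs_fall_back_to_mean_ratio(self):
        # shuffled coarse values: r^2 ~ 0, means fixed at 0.30 vs 0.25
        rng = np.random.default_rng(2)
        fine_vals = rng.uniform(0.1, 0.4, (40, 40))
        fine = Grid(fine_vals - fine_vals.mean() + 0.25, band_label="red")
        agg = aggregate_mean(fine, 10)
        shuffled = rng.permutation(agg.values.ravel()).reshape(agg.shape)
        coarse = agg.with_values(shuffled - shuffled.mean() + 0.30)
        m = fit_band_normalization(fine, coarse, 10)
        assert m.mode == "ratio"
        assert m.ratio == pytest.approx(0.30 / 0.25, rel=1e-6)

    def test_zero_variance_forces_ratio_mode(self):
        fine = Grid(np.full((20, 20), 0.25), band_label="red")
        agg = aggregate_mean(fine, 10)
        coarse = agg.with_values(np.full(agg.shape, 0.30))
        m = fit_band_normalization(fine, coarse, 10)
        assert m.mode == "ratio"
        assert m.ratio == pytest.approx(1.2)

    def test_too_few_pairs(self):
        fine = Grid(np.random.default_rng(0).random((10, 10)))
        coarse = aggregate_mean(fine, 10)
        with pytest.raises(ValueError, match="3 valid"):
            fit_band_normalization(fine, coarse, 10)


class TestApplyNormalization:
    def test_identity_model_leaves_grid(self):
        fine = fine_band(3)
        m = fit_band_normalization(fine, aggregate_mean(fine, 10), 10)
        out = apply_normalization(fine, m)
        np.testing.assert_allclose(out.values, fine.values, atol=1e-12)

    def test_affine_arithmetic(self):
        fine = Grid(np.full((2, 2), 0.5), band_label="red")
        from lairef import NormalizationModel
        m = NormalizationModel("red", "regression", slope=0.9, intercept=0.02)
        assert apply_normalization(fine, m).values[0, 0] == pytest.approx(0.47)

    def test_ratio_clips_to_physical_range(self):
        fine = Grid(np.full((2, 2), 0.9), band_label="red")
        from lairef import NormalizationModel
        m = NormalizationModel("red", "ratio", ratio=1.2)
        assert apply_normalization(fine, m).values[0, 0] == 1.0

    def test_band_mismatch_warns(self):
        fine = fine_band(4, label="nir")
        from lairef import NormalizationModel
        m = NormalizationModel("red", "ratio", ratio=1.1)
        with pytest.warns(UserWarning):
            apply_normalization(fine, m)

    def test_serialization_round_trip(self, tmp_path):
        fine = fine_band(5)
        agg = aggregate_mean(fine, 10)
        coarse = agg.with_values(0.95 * agg.values + 0.01)
        m = fit_band_normalization(fine, coarse, 10)
        path = str(tmp_path / "norm.txt")
        save_normalization(m, path)
        back = load_normalization(path)
        assert back.mode == m.mode
        assert back.slope == pytest.approx(m.slope)
        assert back.n_pairs == m.n_pairs


class TestNormalizationProperties:
    def test_distort_then_normalize_round_trip(self):
        """Normalized fine band re-aggregates onto the distorted reference."""
        cfg = SceneConfig(seed=9, ndvi_noise_sd=0.0, crop_fraction=0.8,
                          sensor_gain=0.93, sensor_offset=0.015)
        truth = simulate_coarse_reference(
            render_reflectance(generate_landscape(cfg), cfg), cfg)
        m = fit_band_normalization(truth.red, truth.coarse_red,
                                   cfg.coarse_factor)
        normalized = apply_normalization(truth.red, m)
        re_agg = aggregate_mean(normalized, cfg.coarse_factor)
        assert np.mean(np.abs(re_agg.values - truth.coarse_red.values)) <= 1e-6

    def test_refit_after_normalization_is_identity(self):
        cfg = SceneConfig(seed=10, ndvi_noise_sd=0.0, crop_fraction=0.8,
                          sensor_gain=0.9, sensor_offset=0.02)
        truth = simulate_coarse_reference(
            render_reflectance(generate_landscape(cfg), cfg), cfg)
        m = fit_band_normalization(truth.red, truth.coarse_red,
                                   cfg.coarse_factor)
        normalized = apply_normalization(truth.red, m)
        m2 = fit_band_normalization(normalized, truth.coarse_red,
                                    cfg.coarse_factor)
        assert m2.slope == pytest.approx(1.0, abs=1e-9)
        assert m2.intercept == pytest.approx(0.0, abs=1e-9)

    def test_red_offset_biases_ndvi_low_and_normalization_corrects(self):
        """An inflated fine red band depresses NDVI; normalization moves the
        NDVI regression slope back toward 1."""
        cfg = SceneConfig(seed=12, ndvi_noise_sd=0.0, crop_fraction=0.7,
                          soil_brightness="bright")
        truth = render_reflectance(generate_landscape(cfg), cfg)
        f = cfg.coarse_factor
        ref_red = aggregate_mean(truth.red, f)
        ref_nir = aggregate_mean(truth.nir, f)
        ref_ndvi = ndvi(ref_red, ref_nir).values.ravel()
        distorted_red = truth.red.with_values(
            np.clip(truth.red.values + 0.05, 0.01, 0.99))

        pre_ndvi = ndvi(aggregate_mean(distorted_red, f),
                        ref_nir).values.ravel()
        assert pre_ndvi.mean() < ref_ndvi.mean()

        m = fit_band_normalization(distorted_red, ref_red, f)
        corrected = apply_normalization(distorted_red, m)
        post_ndvi = ndvi(aggregate_mean(corrected, f), ref_nir).values.ravel()

        pre_slope = np.polyfit(ref_ndvi, pre_ndvi, 1)[0]
        post_slope = np.polyfit(ref_ndvi, post_ndvi, 1)[0]
        assert abs(post_slope - 1.0) < abs(pre_slope - 1.0)
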