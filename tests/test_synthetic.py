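import numpy as np
import pytest

from lairef import ModelParams, SceneConfig, forward_ndvi, ndvi, \
    generate_landscape, render_reflectance, sample_field_plots, \
    simulate_coarse_reference, simulate_product, aggregate_mean
from lairef.synthetic import CROP_CODE, generate_scene


class TestLandscape:
    def test_full_crop_limit(self):
        cfg = SceneConfig(seed=0, crop_fraction=1.0)
        truth = generate_landscape(cfg)
        assert np.all(truth.landcover.values == CROP_CODE)
        lo, hi = cfg.lai_range
        assert truth.lai_true.values.min() >= lo
        assert truth.lai_true.values.max() <= hi

    def test_zero_crop_limit(self):
        truth = generate_landscape(SceneConfig(seed=0, crop_fraction=0.0))
        assert np.all(truth.lai_true.values == 0.0)

    def test_deterministic_given_seed(self):
        cfg = SceneConfig(seed=42, crop_fraction=0.6)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        np.testing.assert_array_equal(a.lai_true.values, b.lai_true.values)
        np.testing.assert_array_equal(a.landcover.values, b.landcover.values)

    def test_realized_crop_fraction_near_target(self):
        for frac in (0.3, 0.5, 0.75, 0.9):
            truth = generate_landscape(SceneConfig(seed=1, crop_fraction=frac))
            realized = np.mean(truth.landcover.values == CROP_CODE)
            assert abs(realized - frac) <= 0.05

    def test_noncrop_pixels_have_zero_lai(self):
        truth = generate_landscape(SceneConfig(seed=3, crop_fraction=0.5))
        noncrop = truth.landcover.values != CROP_CODE
        assert np.all(truth.lai_true.values[noncrop] == 0.0)

    def test_block_larger_than_scene_rejected(self):
        with pytest.raises(ValueError, match="block"):
            generate_landscape(SceneConfig(n_rows=50, n_cols=50,
                                           field_block_pixels=60,
                                           coarse_factor=10))


class TestReflectance:
    def test_bare_soil_pixel_has_soil_ndvi(self):
        cfg = SceneConfig(seed=0, crop_fraction=0.0, ndvi_noise_sd=0.0)
        truth = render_reflectance(generate_landscape(cfg), cfg)
        nd = ndvi(truth.red, truth.nir)
        np.testing.assert_allclose(nd.values, cfg.true_params.ndvi_bs,
                                   atol=1e-12)

    def test_noise_free_bands_reproduce_model_ndvi(self, noisefree_scene):
        cfg, truth = noisefree_scene
        nd = ndvi(truth.red, truth.nir)
        expected = forward_ndvi(truth.lai_true.values, cfg.true_params)
        assert np.max(np.abs(nd.values - expected)) <= 1e-6

    def test_noise_reproducible_with_seed(self):
        cfg = SceneConfig(seed=5, ndvi_noise_sd=0.02)
        a = render_reflectance(generate_landscape(cfg), cfg)
        b = render_reflectance(generate_landscape(cfg), cfg)
        np.testing.assert_array_equal(a.red.values, b.red.values)

    def test_soil_brightness_levels(self):
        for kind, total in (("bright", 0.6), ("dark", 0.2)):
            cfg = SceneConfig(seed=0, crop_fraction=0.0, ndvi_noise_sd=0.0,
                              soil_brightness=kind)
            truth = render_reflectance(generate_landscape(cfg), cfg)
            np.testing.assert_allclose(truth.red.values + truth.nir.values,
                                       total, atol=1e-12)


class TestCoarseReference:
    def test_identity_distortion_equals_aggregation(self, noisefree_scene):
        cfg, truth = noisefree_scene
        agg = aggregate_mean(truth.red, cfg.coarse_factor)
        np.testing.assert_allclose(truth.coarse_red.values, agg.values,
                                   atol=1e-12)

    def test_affine_distortion_on_constant_band(self):
        cfg = SceneConfig(seed=0, crop_fraction=0.0, ndvi_noise_sd=0.0,
                          sensor_gain=0.9, sensor_offset=0.02)
        truth = render_reflectance(generate_landscape(cfg), cfg)
        truth.red.values[:] = 0.5
        truth = simulate_coarse_reference(truth, cfg)
        np.testing.assert_allclose(truth.coarse_red.values, 0.47, atol=1e-12)

    def test_offset_clipped_at_one(self):
        cfg = SceneConfig(seed=0, crop_fraction=0.0, ndvi_noise_sd=0.0,
                          sensor_gain=1.0, sensor_offset=0.9)
        truth = render_reflectance(generate_landscape(cfg), cfg)
        truth = simulate_coarse_reference(truth, cfg)
        assert truth.coarse_nir.values.max() == 1.0


class TestProduct:
    def test_unbiased_noise_free_equals_aggregated_truth(self, noisefree_scene):
        cfg, truth = noisefree_scene
        agg = aggregate_mean(truth.lai_true, cfg.coarse_factor)
        np.testing.assert_allclose(truth.product_lai.values, agg.values,
                                   atol=1e-12)

    def test_bias_scales_product(self):
        cfg = SceneConfig(seed=2, ndvi_noise_sd=0.0, crop_fraction=1.0)
        truth = generate_scene(cfg, product_bias=-0.25)
        agg = aggregate_mean(truth.lai_true, cfg.coarse_factor)
        np.testing.assert_allclose(truth.product_lai.values,
                                   0.75 * agg.values, atol=1e-12)

    def test_noise_only_unbiased_over_seeds(self):
        # Monte-Carlo: mean product equals mean aggregated truth
        deviations = []
        for seed in range(50):
            cfg = SceneConfig(seed=seed, n_rows=50, n_cols=50,
                              ndvi_noise_sd=0.0, crop_fraction=1.0,
                              coarse_factor=10)
            truth = generate_scene(cfg, product_noise_sd=0.3)
            agg = aggregate_mean(truth.lai_true, cfg.coarse_factor)
            deviations.append(truth.product_lai.values.mean()
                              - agg.values.mean())
        assert abs(np.mean(deviations)) <= 0.05


class TestFieldPlots:
    def test_plot_weights_invert_to_pixel_lai(self, noisefree_scene,
                                              noisefree_plots):
        _, truth = noisefree_scene
        for s in noisefree_plots:
            r, c = truth.lai_true.point_to_index(s.x, s.y)
            assert abs(s.lai - truth.lai_true.values[r, c]) <= 1e-9

    def test_count_and_crop_mask(self):
        cfg = SceneConfig(seed=4, crop_fraction=0.9)
        truth = generate_scene(cfg)
        samples = sample_field_plots(truth, n_plots=22, seed=4)
        assert len(samples) == 22
        for s in samples:
            r, c = truth.landcover.point_to_index(s.x, s.y)
            assert truth.landcover.values[r, c] == CROP_CODE

    def test_no_crop_pixels_rejected(self):
        truth = generate_scene(SceneConfig(seed=0, crop_fraction=0.0))
        with pytest.raises(ValueError, match="crop pixels"):
            sample_field_plots(truth, n_plots=5, seed=0)

    def test_stratification_spans_lai_range(self, noisefree_scene,
                                            noisefree_plots):
        cfg, _ = noisefree_scene
        lai = sorted(s.lai for s in noisefree_plots)
        lo, hi = cfg.lai_range
        assert lai[0] < lo + 0.3 * (hi - lo)
        assert lai[-1] > hi - 0.3 * (hi - lo)
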