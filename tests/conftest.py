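import numpy as np
import pytest

from lairef import ModelParams, SceneConfig, generate_scene, sample_field_plots

BJ_PARAMS = ModelParams(0.93, 0.15, 1.58)


@pytest.fixture(scope="session")
def bj_params():
    """The worked-example stage parameters (asymptote 0.93, soil 0.15, K 1.58)."""
    return BJ_PARAMS


@pytest.fixture(scope="session")
def noisefree_scene():
    """A noise-free, all-crop, identity-sensor scene: the self-consistent stack."""
    cfg = SceneConfig(seed=7, ndvi_noise_sd=0.0, crop_fraction=1.0,
                      sensor_gain=1.0, sensor_offset=0.0)
    return cfg, generate_scene(cfg)


@pytest.fixture(scope="session")
def noisefree_plots(noisefree_scene):
    cfg, truth = noisefree_scene
    return sample_field_plots(truth, n_plots=22, seed=cfg.seed)


@pytest.fixture(scope="session")
def heterogeneous_bright_scene():
    """Bright soil, half-crop scene whose coarse pixels mix canopy and soil."""
    cfg = SceneConfig(seed=11, ndvi_noise_sd=0.0, crop_fraction=0.5,
                      field_block_pixels=5, soil_brightness="bright")
    return cfg, generate_scene(cfg, product_bias=-0.25)
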