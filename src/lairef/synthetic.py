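"""Synthetic crop landscapes with reflectance physics matching the pipeline.

The generator builds everything the production/validation chain consumes at
desk scale: a block-mosaic of square farm fields with stage-like true LAI, a
cropland mask, fine-resolution red/NIR reflectance tied to LAI through the
Beer–Lambert NDVI model, a radiometrically distorted coarse reference sensor
view, a coarse LAI "product under validation" with controllable bias, and
1 m x 1 m destructive plot samples whose leaf weights invert exactly to the
pixel's true LAI.

Reflectance construction: per pixel the model NDVI (plus optional Gaussian
noise) is combined with a total brightness T = red + nir that interpolates
linearly in LAI from the bare-soil level (bright soil 0.6, dark soil 0.2)
to a fixed closed-canopy level; then nir = T(1+NDVI)/2, red = T(1-NDVI)/2,
so the rendered bands reproduce the intended NDVI identically wherever the
[0.01, 0.99] reflectance clip is inactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date as Date
from typing import List, Optional, Tuple

import numpy as np

from .field import FieldSample
from .grid import Grid, aggregate_mean
from .model import ModelParams, forward_ndvi

__all__ = ["SceneConfig", "SceneTruth", "generate_landscape",
           "render_reflectance", "simulate_coarse_reference",
           "simulate_product", "sample_field_plots", "generate_scene"]

CROP_CODE = 1
SOIL_BRIGHTNESS = {"bright": 0.6, "dark": 0.2}  # bare-soil red + nir
CANOPY_BRIGHTNESS = 0.45                        # closed-canopy red + nir
LAI_FULL_COVER = 3.0                            # LAI at which canopy dominates

# fixed per-operation offsets on config.seed, so each stage's random stream
# is independently reproducible
_SEED_LANDSCAPE = 0
_SEED_REFLECTANCE = 1
_SEED_PRODUCT = 2
_SEED_PLOTS = 3


@dataclass
class SceneConfig:
    """Parameters of one synthetic study scene."""

    n_rows: int = 100
    n_cols: int = 100
    resolution_m: float = 30.0
    field_block_pixels: int = 10
    crop_fraction: float = 0.9
    lai_range: Tuple[float, float] = (0.2, 4.0)
    soil_brightness: str = "bright"
    true_params: ModelParams = dc_field(
        default_factory=lambda: ModelParams(0.93, 0.15, 1.58))
    ndvi_noise_sd: float = 0.01
    sensor_gain: float = 1.0
    sensor_offset: float = 0.0
    coarse_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must be in [0, 1]")
        if self.lai_range[0] < 0 or self.lai_range[1] < self.lai_range[0]:
            raise ValueError("invalid lai_range")
        if self.ndvi_noise_sd < 0:
            raise ValueError("ndvi_noise_sd must be >= 0")
        if self.n_rows % self.coarse_factor or self.n_cols % self.coarse_factor:
            raise ValueError("grid dimensions must be divisible by coarse_factor")
        if self.soil_brightness not in SOIL_BRIGHTNESS:
            raise ValueError(f"soil_brightness must be one of {set(SOIL_BRIGHTNESS)}")


@dataclass
class SceneTruth:
    """All grids of one synthetic scene, filled in stage by stage."""

    lai_true: Optional[Grid] = None
    landcover: Optional[Grid] = None
    red: Optional[Grid] = None
    nir: Optional[Grid] = None
    coarse_red: Optional[Grid] = None
    coarse_nir: Optional[Grid] = None
    product_lai: Optional[Grid] = None


def generate_landscape(config: SceneConfig) -> SceneTruth:
    """Lay out the field mosaic: true LAI and the cropland mask.

    The scene is tiled with field_block_pixels-sized square fields; each is
    cropland with probability crop_fraction and then carries one stage LAI
    drawn uniformly from lai_range plus a small within-field jitter.
    Deterministic given config.seed.
    """
    if config.field_block_pixels > min(config.n_rows, config.n_cols):
        raise ValueError("field block larger than the scene")
    rng = np.random.default_rng(config.seed + _SEED_LANDSCAPE)
    nb_r = -(-config.n_rows // config.field_block_pixels)
    nb_c = -(-config.n_cols // config.field_block_pixels)
    # draw an exact number of crop blocks so the realized crop fraction
    # tracks the target up to block quantization
    n_blocks = nb_r * nb_c
    n_crop = int(round(config.crop_fraction * n_blocks))
    is_crop_block = np.zeros(n_blocks, dtype=bool)
    is_crop_block[rng.permutation(n_blocks)[:n_crop]] = True
    is_crop_block = is_crop_block.reshape(nb_r, nb_c)
    lo, hi = config.lai_range
    block_lai = rng.uniform(lo, hi, size=(nb_r, nb_c))

    lai = np.zeros((config.n_rows, config.n_cols))
    cover = np.zeros((config.n_rows, config.n_cols))
    bp = config.field_block_pixels
    # within-field jitter: +-2% of the field LAI, kept above lai_range min
    jitter = rng.normal(0.0, 0.02, size=(config.n_rows, config.n_cols))
    for br in range(nb_r):
        for bc in range(nb_c):
            if not is_crop_block[br, bc]:
                continue
            r0, c0 = br * bp, bc * bp
            r1, c1 = min(r0 + bp, config.n_rows), min(c0 + bp, config.n_cols)
            v = block_lai[br, bc] * (1.0 + jitter[r0:r1, c0:c1])
            lai[r0:r1, c0:c1] = np.clip(v, lo, hi)
            cover[r0:r1, c0:c1] = CROP_CODE

    geo = dict(resolution_m=config.resolution_m, origin=(0.0, 0.0))
    return SceneTruth(
        lai_true=Grid(lai, band_label="lai", **geo),
        landcover=Grid(cover, band_label="landcover", **geo))


def render_reflectance(truth: SceneTruth, config: SceneConfig) -> SceneTruth:
    """Add fine-resolution red/NIR bands consistent with the NDVI model."""
    if truth.lai_true is None:
        raise ValueError("generate_landscape must run first")
    rng = np.random.default_rng(config.seed + _SEED_REFLECTANCE)
    lai = truth.lai_true.values
    ndvi = forward_ndvi(lai, config.true_params)
    if config.ndvi_noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, config.ndvi_noise_sd, size=lai.shape)
    ndvi = np.clip(ndvi, -0.99, 0.99)
    t_soil = SOIL_BRIGHTNESS[config.soil_brightness]
    w = np.clip(lai / LAI_FULL_COVER, 0.0, 1.0)
    brightness = t_soil + (CANOPY_BRIGHTNESS - t_soil) * w
    nir = np.clip(brightness * (1.0 + ndvi) / 2.0, 0.01, 0.99)
    red = np.clip(brightness * (1.0 - ndvi) / 2.0, 0.01, 0.99)
    truth.red = truth.lai_true.with_values(red, band_label="red")
    truth.nir = truth.lai_true.with_values(nir, band_label="nir")
    return truth


def simulate_coarse_reference(truth: SceneTruth, config: SceneConfig) -> SceneTruth:
    """Add the coarse reference sensor's (affinely distorted) bands."""
    if truth.red is None or truth.nir is None:
        raise ValueError("render_reflectance must run first")
    for attr, band in (("coarse_red", truth.red), ("coarse_nir", truth.nir)):
        agg = aggregate_mean(band, config.coarse_factor)
        distorted = np.clip(
            config.sensor_gain * agg.values + config.sensor_offset, 0.0, 1.0)
        setattr(truth, attr, agg.with_values(distorted))
    return truth


def simulate_product(truth: SceneTruth, config: SceneConfig,
                     bias: float = 0.0, noise_sd: float = 0.0) -> SceneTruth:
    """Add the coarse LAI product under validation.

    product = aggregated true LAI * (1 + bias) + Gaussian(0, noise_sd),
    floored at 0; ``bias`` is a relative bias (-0.25 means 25 % low).
    """
    if truth.lai_true is None:
        raise ValueError("generate_landscape must run first")
    rng = np.random.default_rng(config.seed + _SEED_PRODUCT)
    agg = aggregate_mean(truth.lai_true, config.coarse_factor)
    vals = agg.values * (1.0 + bias)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    truth.product_lai = agg.with_values(np.maximum(vals, 0.0),
                                        band_label="product_lai")
    return truth


def sample_field_plots(truth: SceneTruth, n_plots: int,
                       seed: int, sample_date: Date = Date(2004, 4, 1),
                       crop: str = "wheat", site: str = "synthetic") -> List[FieldSample]:
    """Draw destructive 1 m x 1 m plots on crop pixels, stratified over LAI.

    Crop pixels are ranked by true LAI and one pixel is drawn per LAI
    quantile stratum (without replacement), so the sample spans the range
    the curve fit needs. Leaf weights are synthesized to invert exactly:
    SLW uniform in [0.004, 0.010] g/cm2, DW = LAI * SLW * As, and the
    subsample satisfies A0 = (DW)0 / SLW.
    """
    if truth.lai_true is None or truth.landcover is None:
        raise ValueError("generate_landscape must run first")
    if n_plots < 3:
        raise ValueError("need at least 3 plots")
    rng = np.random.default_rng(seed + _SEED_PLOTS)
    crop_rows, crop_cols = np.nonzero(truth.landcover.values == CROP_CODE)
    if crop_rows.size < n_plots:
        raise ValueError(
            f"scene has {crop_rows.size} crop pixels, fewer than {n_plots}")
    lai_vals = truth.lai_true.values[crop_rows, crop_cols]
    order = np.argsort(lai_vals, kind="stable")
    # one draw per quantile stratum
    edges = np.linspace(0, crop_rows.size, n_plots + 1).astype(int)
    chosen = [int(rng.integers(edges[i], max(edges[i + 1], edges[i] + 1)))
              for i in range(n_plots)]
    samples: List[FieldSample] = []
    area_plot = 10000.0  # 1 m2 in cm2
    for j, idx in enumerate(chosen):
        r, c = crop_rows[order[idx]], crop_cols[order[idx]]
        pixel_lai = float(truth.lai_true.values[r, c])
        slw = float(rng.uniform(0.004, 0.010))       # g/cm2
        dw_total = pixel_lai * slw * area_plot       # g
        frac = float(rng.uniform(0.05, 0.15))        # subsample mass fraction
        dw_sub = dw_total * frac
        area_sub = dw_sub / slw                      # cm2, so (DW)0/A0 == slw
        x, y = truth.lai_true.index_to_point(int(r), int(c))
        samples.append(FieldSample(
            sample_id=f"P{j + 1:03d}", site=site, date=sample_date, crop=crop,
            x=x, y=y, dw_total=dw_total, dw_sub=dw_sub, area_sub=area_sub,
            area_plot=area_plot))
    return samples


def generate_scene(config: SceneConfig, product_bias: float = 0.0,
                   product_noise_sd: float = 0.0) -> SceneTruth:
    """Run the full generator chain for one scene."""
    truth = generate_landscape(config)
    render_reflectance(truth, config)
    simulate_coarse_reference(truth, config)
    simulate_product(truth, config, bias=product_bias, noise_sd=product_noise_sd)
    return truth
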