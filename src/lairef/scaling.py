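"""U1/U2 upscaling of fine-resolution data and the scale-effect difference.

Two routes lead from fine-resolution reflectance to a coarse LAI map:

* U1, "invert first and then average" — retrieve LAI per fine pixel from its
  NDVI, then block-average the LAI map to the coarse resolution.
* U2, "average first and then invert" — block-average the reflectance bands,
  compute NDVI at the coarse resolution, and invert once per coarse pixel.

Because the NDVI-to-LAI inverse is nonlinear, the two routes disagree on
heterogeneous coarse pixels; the per-pixel difference U1 - U2 quantifies
the spatial scale effect that a coarse retrieval inherits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid, aggregate_mean, ndvi
from .model import ModelParams, invert_lai

__all__ = ["ScalingResult", "upscale_u1", "upscale_u2", "scaling_difference"]


@dataclass
class ScalingResult:
    """Both coarse LAI maps, their pixelwise difference, and summary means."""

    lai_u1: Grid
    lai_u2: Grid
    difference: Grid
    mean_u1: float
    mean_u2: float
    mean_difference: float


def upscale_u1(fine_ndvi: Grid, params: ModelParams, factor: int) -> Grid:
    """Invert NDVI to LAI at fine resolution, then block-average."""
    return aggregate_mean(invert_lai(fine_ndvi, params), factor)


def upscale_u2(fine_red: Grid, fine_nir: Grid, params: ModelParams,
               factor: int) -> Grid:
    """Block-average the bands, then compute NDVI and invert once."""
    coarse_ndvi = ndvi(aggregate_mean(fine_red, factor),
                       aggregate_mean(fine_nir, factor))
    return invert_lai(coarse_ndvi, params)


def scaling_difference(u1: Grid, u2: Grid) -> ScalingResult:
    """Pixelwise and mean scale-effect difference, U1 - U2."""
    if u1.shape != u2.shape:
        raise ValueError(f"shape mismatch {u1.shape} vs {u2.shape}")
    valid = u1.mask() & u2.mask()
    diff = np.where(valid, u1.values - u2.values, u1.nodata)
    mean_u1 = float(np.mean(u1.values[valid]))
    mean_u2 = float(np.mean(u2.values[valid]))
    return ScalingResult(
        lai_u1=u1, lai_u2=u2,
        difference=u1.with_values(diff, band_label="scaling_difference"),
        mean_u1=mean_u1, mean_u2=mean_u2,
        mean_difference=mean_u1 - mean_u2)
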