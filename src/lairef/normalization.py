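"""Cross-sensor radiometric normalization of fine-resolution bands.

The fine sensor's band is aggregated onto the coarse reference sensor's
grid, an ordinary-least-squares line coarse = slope * fine + intercept is
fit over the valid pixel pairs, and the line is applied to the full-resolution
band when the pairs correlate well enough (R^2 above a gate, default 0.75).
Poorly correlated bands fall back to a mean-ratio rescaling so their mean
still lands on the reference sensor's mean. Either way the corrected fine
band sits in the coarse sensor's radiometric units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid import Grid, aggregate_mean

__all__ = ["NormalizationModel", "fit_band_normalization", "apply_normalization",
           "save_normalization", "load_normalization"]


@dataclass
class NormalizationModel:
    """Per-band normalization: an affine regression or a mean-ratio rescale."""

    band_label: str
    mode: str                    # "regression" | "ratio"
    slope: float = float("nan")
    intercept: float = float("nan")
    ratio: float = float("nan")
    r_squared: float = float("nan")
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("regression", "ratio"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "ratio" and not self.ratio > 0:
            raise ValueError("ratio mode requires a positive ratio")


def fit_band_normalization(fine_band: Grid, coarse_band: Grid, factor: int,
                           r2_threshold: float = 0.75) -> NormalizationModel:
    """Fit one band's normalization against the coarse reference sensor.

    The fine band is block-averaged by ``factor`` to the coarse grid and the
    valid pairs regressed (coarse on aggregated fine). Regression mode is
    used only when the pairs' squared Pearson correlation strictly exceeds
    ``r2_threshold`` and the aggregated band has variance; otherwise the
    mean-ratio fallback applies.
    """
    agg = aggregate_mean(fine_band, factor)
    if agg.shape != coarse_band.shape:
        raise ValueError(
            f"aggregated fine shape {agg.shape} != coarse shape {coarse_band.shape}")
    valid = agg.mask() & coarse_band.mask()
    x = agg.values[valid]
    y = coarse_band.values[valid]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 valid pixel pairs, got {n}")
    label = fine_band.band_label

    if np.std(x) == 0:  # regression singular: forced ratio mode
        return _ratio_model(label, x, y, n, r_squared=0.0)

    slope, intercept = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    if r2 > r2_threshold:
        return NormalizationModel(band_label=label, mode="regression",
                                  slope=float(slope), intercept=float(intercept),
                                  r_squared=r2, n_pairs=n)
    return _ratio_model(label, x, y, n, r_squared=r2)


def _ratio_model(label: str, x: np.ndarray, y: np.ndarray, n: int,
                 r_squared: float) -> NormalizationModel:
    mean_fine = float(np.mean(x))
    if mean_fine == 0:
        raise ValueError("mean of aggregated fine band is zero: ratio undefined")
    return NormalizationModel(band_label=label, mode="ratio",
                              ratio=float(np.mean(y)) / mean_fine,
                              r_squared=r_squared, n_pairs=n)


def apply_normalization(fine_band: Grid, model: NormalizationModel,
                        strict_band: bool = False) -> Grid:
    """Apply a fitted normalization to a full-resolution band.

    Results are clipped to physical reflectance [0, 1]; nodata passes
    through. A band-label mismatch warns by default (set ``strict_band``
    to make it an error).
    """
    if model.band_label and fine_band.band_label and \
            model.band_label != fine_band.band_label:
        msg = (f"normalization for band {model.band_label!r} applied to "
               f"{fine_band.band_label!r}")
        if strict_band:
            raise ValueError(msg)
        import warnings
        warnings.warn(msg)
    valid = fine_band.mask()
    out = fine_band.values.copy()
    if model.mode == "regression":
        out[valid] = model.slope * out[valid] + model.intercept
    else:
        out[valid] = model.ratio * out[valid]
    out[valid] = np.clip(out[valid], 0.0, 1.0)
    return fine_band.with_values(out)


def save_normalization(model: NormalizationModel, path: str) -> None:
    """Serialize a normalization model as a small key=value audit record."""
    with open(path, "w") as fh:
        for key in ("band_label", "mode", "slope", "intercept", "ratio",
                    "r_squared", "n_pairs"):
            fh.write(f"{key}={getattr(model, key)}\n")


def load_normalization(path: str) -> NormalizationModel:
    fields: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            fields[key] = value
    return NormalizationModel(
        band_label=fields["band_label"], mode=fields["mode"],
        slope=float(fields["slope"]), intercept=float(fields["intercept"]),
        ratio=float(fields["ratio"]), r_squared=float(fields["r_squared"]),
        n_pairs=int(fields["n_pairs"]))
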