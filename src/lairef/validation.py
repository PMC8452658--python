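"""Validation of a coarse-resolution LAI product against reference data.

Three comparison modes mirror how a coarse product is judged in practice:

* U1 mode — one pair per reference map: the mean of the product pixels
  inside the 3 km x 3 km window against the map's fine-resolution (U1)
  mean LAI.
* U2 mode — one pair per coarse pixel inside each window: the product value
  against the U2 (average-then-invert) reference value, which removes the
  scale effect from the comparison.
* direct mode — one pair per field plot: the product value of the pixel
  containing the plot against the destructively measured LAI.

Each report row carries R^2, RMSE, RRMSE and the relative bias
(mean_ref_product - mean_reference)/mean_reference expressed in percent,
computed from pooled means (the "All" row pools pairs across areas rather
than averaging area rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .field import FieldSample
from .grid import Grid, Window, extract_window
from .model import fit_metrics
from .reference import ReferenceMap

__all__ = ["relative_bias", "pair_product_with_reference",
           "pair_product_with_field", "validation_report", "ValidationReport"]

logger = logging.getLogger(__name__)

MODES = ("U1", "U2", "direct")


def relative_bias(ref_mean: float, field_mean: float) -> float:
    """Signed relative bias (ref - field)/field as a fraction."""
    if field_mean == 0:
        raise ValueError("relative bias undefined for zero mean")
    return (ref_mean - field_mean) / field_mean


def pair_product_with_reference(product: Grid, refmaps: Sequence[ReferenceMap],
                                mode: str = "U1") -> Tuple[List[float], List[float]]:
    """Pair product values with reference values in U1 or U2 mode.

    Returns (product_values, reference_values). U1 mode yields one pair per
    map (window mean of the product vs the map's mean fine LAI); U2 mode
    yields one pair per coarse pixel within each window. Windows with no
    valid product pixels are skipped with a log entry.
    """
    if mode not in ("U1", "U2"):
        raise ValueError("mode must be 'U1' or 'U2'")
    prod_vals: List[float] = []
    ref_vals: List[float] = []
    for rm in refmaps:
        size_m = rm.lai_u1_map.shape[0] * rm.lai_u1_map.resolution_m
        window = Window(center_point=rm.center, size_m=size_m)
        try:
            prod_win = extract_window(product, window)
        except ValueError as exc:
            logger.info("map %s skipped: %s", rm.map_id, exc)
            continue
        valid = prod_win.mask()
        if not valid.any():
            logger.info("map %s skipped: no valid product pixels", rm.map_id)
            continue
        if mode == "U1":
            prod_vals.append(float(np.mean(prod_win.values[valid])))
            ref_vals.append(rm.stats.mean_lai_u1)
        else:
            ref_win = rm.lai_u2_map
            both = valid & ref_win.mask()
            prod_vals.extend(prod_win.values[both].tolist())
            ref_vals.extend(ref_win.values[both].tolist())
    return prod_vals, ref_vals


def pair_product_with_field(product: Grid, samples: Sequence[FieldSample]
                            ) -> Tuple[List[float], List[float]]:
    """Pair each field plot with the product pixel containing it.

    Plots outside the product extent (or on nodata pixels) are skipped and
    counted in the log; plots sharing a pixel each contribute a pair.
    """
    prod_vals: List[float] = []
    field_vals: List[float] = []
    skipped = 0
    nr, nc = product.shape
    valid = product.mask()
    for s in samples:
        row, col = product.point_to_index(s.x, s.y)
        if not (0 <= row < nr and 0 <= col < nc) or not valid[row, col]:
            skipped += 1
            continue
        prod_vals.append(float(product.values[row, col]))
        field_vals.append(float(s.lai))
    if skipped:
        logger.info("%d field samples outside product extent or on nodata",
                    skipped)
    return prod_vals, field_vals


@dataclass
class ValidationReport:
    """Metric rows keyed by (study area | 'All') x comparison mode."""

    table: pd.DataFrame

    def row(self, area: str, mode: str) -> pd.Series:
        match = self.table[(self.table["Study area"] == area)
                           & (self.table["Mode"] == mode)]
        if len(match) == 0:
            raise KeyError(f"no row for ({area}, {mode})")
        return match.iloc[0]

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        return self.table.to_string(
            index=False, float_format=lambda v: f"{v:.3f}")


def validation_report(pairs: Dict[Tuple[str, str], Tuple[Sequence[float], Sequence[float]]]
                      ) -> ValidationReport:
    """Build the metric table from paired (product, reference) lists.

    ``pairs`` maps (study_area, mode) to (product_values, reference_values).
    An 'All' row per mode is computed over the pooled pairs of that mode.
    Relative bias is (mean product - mean reference)/mean reference in
    percent. Rows with degenerate variance are flagged.
    """
    rows = []
    pooled: Dict[str, Tuple[List[float], List[float]]] = {}
    for (area, mode), (prod, ref) in pairs.items():
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        pooled.setdefault(mode, ([], []))
        pooled[mode][0].extend(prod)
        pooled[mode][1].extend(ref)
        rows.append(_metric_row(area, mode, prod, ref))
    for mode, (prod, ref) in pooled.items():
        areas = {a for (a, m) in pairs if m == mode}
        if len(areas) > 1:
            rows.append(_metric_row("All", mode, prod, ref))
    order = {m: i for i, m in enumerate(MODES)}
    rows.sort(key=lambda r: (order[r["Mode"]], r["Study area"] != "All",
                             r["Study area"]))
    return ValidationReport(pd.DataFrame(rows))


def _metric_row(area: str, mode: str, prod: Sequence[float],
                ref: Sequence[float]) -> dict:
    prod = np.asarray(prod, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if prod.size < 2:
        raise ValueError(f"({area}, {mode}): need >= 2 pairs")
    metrics = fit_metrics(prod, ref)
    rb = relative_bias(float(np.mean(prod)), float(np.mean(ref)))
    return {"Study area": area, "Mode": mode, "R2": metrics.r_squared,
            "RMSE": metrics.rmse, "RRMSE": metrics.rrmse,
            "RB_percent": 100.0 * rb, "n_pairs": int(prod.size),
            "degenerate": metrics.r2_degenerate}
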