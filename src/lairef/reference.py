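"""Reference LAI maps: construction gates, statistics rows, area summaries.

A reference map is a 3 km x 3 km fine-resolution LAI window centred on a
field campaign, retrieved from normalized reflectance with the stage's
fitted NDVI-LAI model. A window qualifies only when its cropland fraction
strictly exceeds a threshold (default 75 %). Each accepted map carries a
statistics row: mean LAI via the U1 route, its uncertainty (mean LAI times
the stage model's relative RMSE), the spatial standard deviation of the
fine LAI, the mean via the U2 route, and the U1 - U2 scaling difference.

The package also ships, as packaged CSV fixtures, the published per-map
statistics tables of the four study areas of the reference dataset
(Beijing, Henan, Heilongjiang, Anhui; 80 maps in total) together with the
published per-stage model equations; :func:`summarize_area` reproduces the
per-area summary statistics from those rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .grid import Grid, Window, extract_window, ndvi
from .model import FittedStageModel, ModelParams, invert_lai
from .scaling import upscale_u1, upscale_u2, scaling_difference

__all__ = ["ReferenceMapStats", "ReferenceMap", "MapRejection",
           "build_reference_map", "map_statistics", "summarize_area",
           "load_stats_fixture", "load_stage_model_fixture",
           "STATS_COLUMNS", "AREAS"]

AREAS = ("beijing", "henan", "heilongjiang", "anhui")

STATS_COLUMNS = ["ID", "Date", "Latitude", "Longitude", "Crop cover",
                 "Mean_LAI_U1", "Uncertainty", "Standard deviation",
                 "Mean_LAI_U2", "Scaling difference"]


@dataclass
class ReferenceMapStats:
    """One statistics row of a reference map."""

    mean_lai_u1: float
    uncertainty: float      # mean_lai_u1 x stage RRMSE
    std_dev: float          # spatial heterogeneity of the fine LAI window
    mean_lai_u2: float
    scaling_diff: float     # mean_lai_u1 - mean_lai_u2


@dataclass
class ReferenceMap:
    """An accepted 3 km x 3 km reference LAI window with its statistics."""

    map_id: str
    date: str
    center: Tuple[float, float]
    crop_cover: float
    lai_u1_map: Grid        # fine-resolution LAI
    lai_u1_coarse: Grid     # U1-aggregated coarse LAI
    lai_u2_map: Grid        # coarse-resolution LAI via U2
    stats: ReferenceMapStats


@dataclass
class MapRejection:
    """Machine-readable reason a candidate window was not accepted."""

    map_id: str
    reason: str
    crop_cover: Optional[float] = None


def build_reference_map(red: Grid, nir: Grid, model: FittedStageModel,
                        center: Tuple[float, float], landcover: Grid,
                        crop_code: int = 1, size_m: float = 3000.0,
                        crop_threshold: float = 0.75, coarse_factor: int = 10,
                        map_id: str = "", date: str = ""):
    """Build one reference map, or return a :class:`MapRejection`.

    The window is extracted from the co-registered bands and land cover;
    the cropland-fraction gate is strict (cover must exceed, not merely
    reach, ``crop_threshold``). Accepted windows get a fine U1 LAI map, a
    coarse U2 map at ``coarse_factor``, and a statistics row whose
    uncertainty uses the stage model's RRMSE.
    """
    if not (red.same_georeference(nir) and red.same_georeference(landcover)):
        raise ValueError("red, nir and landcover are not co-registered")
    window = Window(center_point=center, size_m=size_m)
    try:
        lc_win = extract_window(landcover, window)
    except ValueError as exc:
        return MapRejection(map_id=map_id, reason=f"window out of bounds: {exc}")
    crop_cover = float(np.mean(lc_win.values == crop_code))
    if not crop_cover > crop_threshold:
        return MapRejection(
            map_id=map_id, crop_cover=crop_cover,
            reason=(f"crop cover {crop_cover:.3f} not larger than "
                    f"threshold {crop_threshold}"))
    red_win = extract_window(red, window)
    nir_win = extract_window(nir, window)
    fine_ndvi = ndvi(red_win, nir_win)
    lai_fine = invert_lai(fine_ndvi, model.params)
    lai_u1_coarse = upscale_u1(fine_ndvi, model.params, coarse_factor)
    lai_u2 = upscale_u2(red_win, nir_win, model.params, coarse_factor)
    stats = map_statistics(lai_fine, lai_u1_coarse, lai_u2, model.rrmse)
    return ReferenceMap(map_id=map_id, date=date, center=center,
                        crop_cover=crop_cover, lai_u1_map=lai_fine,
                        lai_u1_coarse=lai_u1_coarse, lai_u2_map=lai_u2,
                        stats=stats)


def map_statistics(lai_fine: Grid, lai_u1_coarse: Grid, lai_u2: Grid,
                   stage_rrmse: float) -> ReferenceMapStats:
    """Statistics row for a reference map.

    Means are over valid pixels; the uncertainty is the window's mean LAI
    scaled by the stage model's relative RMSE; the standard deviation is the
    population form over the fine LAI pixels.
    """
    fine_valid = lai_fine.valid_values()
    if fine_valid.size == 0:
        raise ValueError("no valid fine LAI pixels in the window")
    result = scaling_difference(lai_u1_coarse, lai_u2)
    mean_u1 = float(np.mean(fine_valid))
    return ReferenceMapStats(
        mean_lai_u1=mean_u1,
        uncertainty=mean_u1 * stage_rrmse,
        std_dev=float(np.std(fine_valid)),
        mean_lai_u2=result.mean_u2,
        scaling_diff=mean_u1 - result.mean_u2)


def summarize_area(stats: pd.DataFrame) -> dict:
    """Per-area summary of reference-map statistics rows.

    Accepts a DataFrame with the standard statistics columns and returns
    min/max of the per-map mean LAI plus arithmetic means of uncertainty,
    standard deviation and scaling difference, each rounded to 3 decimals,
    and the row count.
    """
    if len(stats) == 0:
        raise ValueError("no statistics rows to summarize")
    r3 = lambda v: float(np.round(float(v), 3))
    return {
        "n_maps": int(len(stats)),
        "min_mean_lai": r3(stats["Mean_LAI_U1"].min()),
        "max_mean_lai": r3(stats["Mean_LAI_U1"].max()),
        "mean_uncertainty": r3(stats["Uncertainty"].mean()),
        "mean_std_dev": r3(stats["Standard deviation"].mean()),
        "mean_scaling_diff": r3(stats["Scaling difference"].mean()),
    }


def stats_rows_to_frame(rows: List[ReferenceMapStats],
                        ids: Optional[List[str]] = None) -> pd.DataFrame:
    """Arrange computed statistics rows in the standard table layout."""
    frame = pd.DataFrame({
        "ID": ids if ids is not None else [str(i + 1) for i in range(len(rows))],
        "Mean_LAI_U1": [r.mean_lai_u1 for r in rows],
        "Uncertainty": [r.uncertainty for r in rows],
        "Standard deviation": [r.std_dev for r in rows],
        "Mean_LAI_U2": [r.mean_lai_u2 for r in rows],
        "Scaling difference": [r.scaling_diff for r in rows],
    })
    return frame


def load_stats_fixture(area: str) -> pd.DataFrame:
    """Load the packaged per-map statistics table for one study area."""
    area = area.lower()
    if area not in AREAS:
        raise ValueError(f"unknown study area {area!r}; expected one of {AREAS}")
    ref = resources.files("lairef.data") / f"refmap_stats_{area}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_stage_model_fixture() -> pd.DataFrame:
    """Load the packaged per-stage model equation coefficients.

    Columns: date, site, k_ndvi, amplitude (NDVI_inf - NDVI_bs), ndvi_inf.
    """
    ref = resources.files("lairef.data") / "stage_models.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def stage_model_params(row: pd.Series) -> ModelParams:
    """ModelParams from one stage-equation fixture row."""
    return ModelParams(ndvi_inf=float(row["ndvi_inf"]),
                       ndvi_bs=float(row["ndvi_inf"]) - float(row["amplitude"]),
                       k_ndvi=float(row["k_ndvi"]))
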