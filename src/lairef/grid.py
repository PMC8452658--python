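"""Georeferenced single-band raster grids: I/O, aggregation, windows, NDVI.

A :class:`Grid` is the spatial substrate for every stage of the pipeline —
reflectance bands, LAI maps and categorical land cover all live on the same
simple planar model: a rectangular array of square pixels, row-major, origin
at the top-left corner, x increasing with column and y decreasing with row.
Files are single-band float32 GeoTIFFs carrying the pixel scale, top-left
tiepoint and nodata value as standard GeoTIFF/GDAL tags; whitespace-delimited
text matrices are accepted as a convenience for small inputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import tifffile

__all__ = ["Grid", "Window", "read_grid", "write_grid", "aggregate_mean",
           "extract_window", "ndvi"]

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values : ndarray
        2-D float array. Cells equal to ``nodata`` are masked.
    resolution_m : float
        Pixel edge length in metres (> 0).
    origin : (float, float)
        Planar (x, y) of the top-left corner of the top-left pixel.
    nodata : float
        Sentinel for masked cells.
    band_label : str
        Free text, e.g. ``"red"``, ``"nir"``, ``"lai"``, ``"landcover"``.
    """

    values: np.ndarray
    resolution_m: float = 30.0
    origin: Tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA
    band_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not self.resolution_m > 0:
            raise ValueError("resolution_m must be > 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is valid (not nodata)."""
        return ~(np.isclose(self.values, self.nodata) | np.isnan(self.values))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]

    def same_georeference(self, other: "Grid") -> bool:
        return (self.shape == other.shape
                and math.isclose(self.resolution_m, other.resolution_m)
                and math.isclose(self.origin[0], other.origin[0])
                and math.isclose(self.origin[1], other.origin[1]))

    def point_to_index(self, x: float, y: float) -> Tuple[int, int]:
        """Row/col of the pixel containing planar point (x, y)."""
        col = int(math.floor((x - self.origin[0]) / self.resolution_m))
        row = int(math.floor((self.origin[1] - y) / self.resolution_m))
        return row, col

    def index_to_point(self, row: int, col: int) -> Tuple[float, float]:
        """Planar (x, y) of the centre of pixel (row, col)."""
        x = self.origin[0] + (col + 0.5) * self.resolution_m
        y = self.origin[1] - (row + 0.5) * self.resolution_m
        return x, y

    def with_values(self, values: np.ndarray, band_label: Optional[str] = None,
                    resolution_m: Optional[float] = None) -> "Grid":
        return replace(
            self, values=np.asarray(values, dtype=float),
            band_label=self.band_label if band_label is None else band_label,
            resolution_m=self.resolution_m if resolution_m is None else resolution_m,
        )


@dataclass
class Window:
    """A square analysis window, e.g. the 3 km x 3 km reference-map footprint.

    ``center_point`` is in planar metres; ``size_m`` must be an integer
    multiple of the grid resolution. The pixel containing the centre point
    lands at 0-based index (n/2, n/2) of the extracted n x n subgrid.
    """

    center_point: Tuple[float, float]
    size_m: float = 3000.0

    def n_pixels(self, resolution_m: float) -> int:
        ratio = self.size_m / resolution_m
        n = round(ratio)
        if not math.isclose(ratio, n):
            raise ValueError(
                f"window size {self.size_m} m is not an integer multiple of "
                f"the {resolution_m} m resolution")
        return int(n)

    def row_col_bounds(self, grid: Grid) -> Tuple[int, int, int, int]:
        """Half-open (row0, row1, col0, col1) pixel bounds on ``grid``."""
        n = self.n_pixels(grid.resolution_m)
        crow, ccol = grid.point_to_index(*self.center_point)
        row0 = crow - n // 2
        col0 = ccol - n // 2
        return row0, row0 + n, col0, col0 + n


def read_grid(path: str, band_label: str = "") -> Grid:
    """Read a Grid from a GeoTIFF or a whitespace-delimited text matrix.

    GeoTIFFs must carry ModelPixelScale and ModelTiepoint tags; text files
    get a default georeference (30 m pixels, origin (0, 0)).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".tif", ".tiff")):
        return _read_geotiff(path, band_label)
    return _read_text_matrix(path, band_label)


def _read_geotiff(path: str, band_label: str) -> Grid:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        if values.ndim == 3:  # band-interleaved single image: take first band
            values = values[..., 0]
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if not math.isclose(sx, sy):
            raise ValueError(f"{path}: non-square pixels unsupported")
        # tiepoint (i, j, k, x, y, z) maps raster (i, j) to model (x, y);
        # we require the conventional top-left anchor (0, 0).
        tp = tiepoint.value
        origin = (float(tp[3]) - float(tp[0]) * sx,
                  float(tp[4]) + float(tp[1]) * sy)
        nd_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nd_tag.value) if nd_tag is not None else DEFAULT_NODATA
    return Grid(np.asarray(values, dtype=float), resolution_m=sx,
                origin=origin, nodata=nodata, band_label=band_label)


def _read_text_matrix(path: str, band_label: str) -> Grid:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: malformed matrix (ragged rows)")
    return Grid(np.array(rows, dtype=float), band_label=band_label)


def write_grid(grid: Grid, path: str) -> None:
    """Write ``grid`` as a single-band float32 GeoTIFF with geo tags."""
    if not isinstance(grid, Grid):
        raise TypeError("write_grid expects a Grid")
    res = float(grid.resolution_m)
    ox, oy = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata))),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float32), extratags=extratags)


def aggregate_mean(grid: Grid, factor: int) -> Grid:
    """Block-average ``grid`` by an integer ``factor``.

    Each output cell is the arithmetic mean of the valid cells of its
    factor x factor block; a block that is entirely nodata stays nodata.
    Used for the fine-to-coarse resolution step (e.g. 30 m bands averaged
    onto the coarse sensor's grid).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    nr, nc = grid.shape
    if nr % factor or nc % factor:
        raise ValueError(
            f"grid shape {grid.shape} not divisible by factor {factor}; "
            f"crop to ({nr - nr % factor}, {nc - nc % factor}) or pad first")
    if factor == 1:
        return grid.with_values(grid.values.copy())
    blocks = grid.values.reshape(nr // factor, factor, nc // factor, factor)
    valid = grid.mask().reshape(nr // factor, factor, nc // factor, factor)
    counts = valid.sum(axis=(1, 3))
    sums = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), grid.nodata)
    return grid.with_values(means, resolution_m=grid.resolution_m * factor)


def extract_window(grid: Grid, window: Window) -> Grid:
    """Extract the square subgrid covered by ``window``.

    The window must lie fully inside the grid; partial windows are refused
    so every reference map covers its full stated footprint.
    """
    row0, row1, col0, col1 = window.row_col_bounds(grid)
    nr, nc = grid.shape
    if row0 < 0 or col0 < 0 or row1 > nr or col1 > nc:
        raise ValueError(
            f"window out of bounds: rows [{row0},{row1}) cols [{col0},{col1}) "
            f"on a {nr}x{nc} grid")
    sub = grid.values[row0:row1, col0:col1].copy()
    origin = (grid.origin[0] + col0 * grid.resolution_m,
              grid.origin[1] - row0 * grid.resolution_m)
    return Grid(sub, resolution_m=grid.resolution_m, origin=origin,
                nodata=grid.nodata, band_label=grid.band_label)


def ndvi(red: Grid, nir: Grid) -> Grid:
    """Normalized difference vegetation index, (NIR - red)/(NIR + red).

    Nodata where either band is nodata or where the denominator vanishes.
    """
    if not red.same_georeference(nir):
        raise ValueError("red and nir grids are not co-registered")
    denom = nir.values + red.values
    valid = red.mask() & nir.mask() & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid, (nir.values - red.values) / np.where(denom == 0, 1, denom),
                       DEFAULT_NODATA)
    return Grid(out, resolution_m=red.resolution_m, origin=red.origin,
                nodata=DEFAULT_NODATA, band_label="ndvi")
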