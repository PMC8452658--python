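"""Destructive field LAI: specific leaf weight, plot LAI and campaign tables.

Each field sample is one 1 m x 1 m destructive plot. A subsample of typical
leaves is scanned and dried to get the specific leaf weight SLW = (DW)0 / A0
(dry mass per leaf area, g/cm2); the plot's total leaf dry weight DW then
converts to leaf area index as LAI = DW / (SLW * As) with As the sampling
area in cm2 (10000 for the 1 m2 plot). Combining the two steps,
LAI = DW * A0 / ((DW)0 * As), so any common rescaling of the two weights
cancels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date as Date, datetime
from typing import List, Optional, Sequence

__all__ = ["FieldSample", "Acquisition", "specific_leaf_weight", "plot_lai",
           "load_field_table", "save_field_table", "match_acquisition",
           "DEFAULT_PLOT_AREA_CM2"]

DEFAULT_PLOT_AREA_CM2 = 10000.0  # 1 m x 1 m


@dataclass
class FieldSample:
    """One destructive plot measurement with derived LAI."""

    sample_id: str
    site: str
    date: Date
    crop: str
    x: float
    y: float
    dw_total: float          # total leaf dry weight DW (g)
    dw_sub: float            # subsample dry weight (DW)0 (g)
    area_sub: float          # subsample leaf area A0 (cm2)
    area_plot: float = DEFAULT_PLOT_AREA_CM2  # sampling area As (cm2)
    lai: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lai is None:
            self._check_weights()
            slw = specific_leaf_weight(self.dw_sub, self.area_sub)
            self.lai = plot_lai(self.dw_total, slw, self.area_plot)
        if self.lai < 0:
            raise ValueError(f"sample {self.sample_id}: negative LAI")

    def _check_weights(self) -> None:
        if not (self.dw_sub > 0 and self.dw_total >= self.dw_sub):
            raise ValueError(
                f"sample {self.sample_id}: need dw_total >= dw_sub > 0 "
                f"(got {self.dw_total}, {self.dw_sub})")
        if not (self.area_sub > 0 and self.area_plot > 0):
            raise ValueError(f"sample {self.sample_id}: areas must be positive")


@dataclass
class Acquisition:
    """A candidate satellite scene for matching to a field campaign date."""

    scene_id: str
    date: Date
    cloud_free: bool = True


def specific_leaf_weight(dw_sub: float, area_sub: float) -> float:
    """SLW = (DW)0 / A0 in g/cm2."""
    if dw_sub <= 0 or area_sub <= 0:
        raise ValueError("subsample weight and area must be positive")
    return dw_sub / area_sub


def plot_lai(dw_total: float, slw: float, area_plot: float = DEFAULT_PLOT_AREA_CM2) -> float:
    """LAI = DW / (SLW * As); dimensionless (m2 leaf per m2 ground)."""
    if dw_total <= 0 or slw <= 0 or area_plot <= 0:
        raise ValueError("dw_total, slw and area_plot must be positive")
    return dw_total / (slw * area_plot)


_REQUIRED_ANY = ("sample_id", "date")
_WEIGHT_COLS = ("dw_total", "dw_sub", "area_sub")


def _parse_date(text: str) -> Date:
    text = text.strip()
    for fmt in ("%Y-%m-%d", "%Y/%m/%d"):
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date {text!r} (expected ISO-8601)")


def load_field_table(path: str, delimiter: Optional[str] = None) -> List[FieldSample]:
    """Load a delimited field-sample table.

    Rows need either the raw destructive columns (dw_total, dw_sub, area_sub,
    optional area_plot) — LAI is then computed — or an explicit ``lai``
    column. Invariant violations are reported with their 1-based row number.
    """
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty table")
        cols = set(reader.fieldnames)
        missing = [c for c in _REQUIRED_ANY if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        has_weights = all(c in cols for c in _WEIGHT_COLS)
        has_lai = "lai" in cols
        if not (has_weights or has_lai):
            raise ValueError(
                f"{path}: need either columns {list(_WEIGHT_COLS)} or 'lai'")
        samples: List[FieldSample] = []
        errors: List[str] = []
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            try:
                kwargs = dict(
                    sample_id=row["sample_id"],
                    site=row.get("site", ""),
                    date=_parse_date(row["date"]),
                    crop=row.get("crop", ""),
                    x=float(row.get("x", "nan") or "nan"),
                    y=float(row.get("y", "nan") or "nan"),
                )
                if has_weights and row.get("dw_total", "") != "":
                    samples.append(FieldSample(
                        dw_total=float(row["dw_total"]),
                        dw_sub=float(row["dw_sub"]),
                        area_sub=float(row["area_sub"]),
                        area_plot=float(row.get("area_plot") or DEFAULT_PLOT_AREA_CM2),
                        **kwargs))
                else:
                    samples.append(FieldSample(
                        dw_total=1.0, dw_sub=1.0, area_sub=1.0,
                        lai=float(row["lai"]), **kwargs))
            except (ValueError, KeyError) as exc:
                errors.append(f"row {i}: {exc}")
        if errors:
            raise ValueError(f"{path}: invalid rows:\n  " + "\n  ".join(errors))
    return samples


def save_field_table(samples: Sequence[FieldSample], path: str) -> None:
    """Write samples as a comma-delimited table (ISO dates, raw weights, lai)."""
    cols = ["sample_id", "site", "date", "crop", "x", "y",
            "dw_total", "dw_sub", "area_sub", "area_plot", "lai"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for s in samples:
            writer.writerow([s.sample_id, s.site, s.date.isoformat(), s.crop,
                             repr(s.x), repr(s.y), repr(s.dw_total),
                             repr(s.dw_sub), repr(s.area_sub),
                             repr(s.area_plot), repr(s.lai)])


def match_acquisition(field_date: Date, acquisitions: Sequence[Acquisition],
                      max_gap_days: int = 7) -> Optional[Acquisition]:
    """Pick the usable scene closest in time to a field campaign.

    Cloud-free scenes within ``max_gap_days`` of the field date qualify;
    the smallest absolute gap wins, ties going to the earlier scene.
    Returns None when no scene qualifies.
    """
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    best: Optional[Acquisition] = None
    best_key = None
    for acq in acquisitions:
        if not acq.cloud_free:
            continue
        gap = (acq.date - field_date).days
        if abs(gap) > max_gap_days:
            continue
        key = (abs(gap), acq.date)
        if best_key is None or key < best_key:
            best, best_key = acq, key
    return best
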