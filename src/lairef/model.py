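"""Semiempirical Beer–Lambert NDVI–LAI model: forward, inverse, fitting, LOOCV.

The canopy is treated as a turbid medium whose vegetation index approaches an
asymptote NDVI_inf as leaf area accumulates and equals the bare-soil value
NDVI_bs at LAI = 0:

    forward:  NDVI(LAI) = NDVI_inf + (NDVI_bs - NDVI_inf) * exp(-LAI / K)
    inverse:  LAI(NDVI) = K * ln((NDVI_inf - NDVI_bs) / (NDVI_inf - NDVI))

The two forms are exact inverses of each other; K is the extinction-type
coefficient that also multiplies the logarithm in the published per-stage
equations ("LAI = 1.58*ln(0.78/(0.93-NDVI))" style). Fitting is bounded
nonlinear least squares in NDVI space with a deterministic multi-start, and
per-stage model selection uses leave-one-out cross-validation: refit once per
held-out sample, then keep the candidate whose inverse predictions have the
lowest RMSE against the full sample set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .grid import Grid

__all__ = ["ModelParams", "ParamBounds", "FitMetrics", "FittedStageModel",
           "DEFAULT_BOUNDS", "forward_ndvi", "invert_lai", "fit_params",
           "loocv_select", "fit_metrics"]


@dataclass(frozen=True)
class ModelParams:
    """The (NDVI_inf, NDVI_bs, K_ndvi) triple of the semiempirical model."""

    ndvi_inf: float
    ndvi_bs: float
    k_ndvi: float

    def __post_init__(self) -> None:
        if not self.ndvi_bs < self.ndvi_inf:
            raise ValueError("ndvi_bs must be below ndvi_inf")
        if not self.k_ndvi > 0:
            raise ValueError("k_ndvi must be positive")

    @property
    def amplitude(self) -> float:
        """NDVI dynamic range NDVI_inf - NDVI_bs (the log numerator)."""
        return self.ndvi_inf - self.ndvi_bs

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.ndvi_inf, self.ndvi_bs, self.k_ndvi)


@dataclass(frozen=True)
class ParamBounds:
    """Box constraints for fitting, (lo, hi) per parameter."""

    ndvi_inf: Tuple[float, float] = (0.91, 0.97)
    ndvi_bs: Tuple[float, float] = (0.01, 0.18)
    k_ndvi: Tuple[float, float] = (1.3, 1.8)

    def lower(self) -> np.ndarray:
        return np.array([self.ndvi_inf[0], self.ndvi_bs[0], self.k_ndvi[0]])

    def upper(self) -> np.ndarray:
        return np.array([self.ndvi_inf[1], self.ndvi_bs[1], self.k_ndvi[1]])

    def contains(self, p: ModelParams, tol: float = 1e-9) -> bool:
        lo, hi = self.lower() - tol, self.upper() + tol
        v = np.array(p.as_tuple())
        return bool(np.all(v >= lo) and np.all(v <= hi))


DEFAULT_BOUNDS = ParamBounds()


@dataclass
class FitMetrics:
    """RMSE, relative RMSE and squared Pearson correlation of a fit."""

    rmse: float
    rrmse: float
    r_squared: float
    r2_degenerate: bool = False  # True when a constant series made r2 undefined

    def __iter__(self) -> Iterator[float]:
        return iter((self.rmse, self.rrmse, self.r_squared))


@dataclass
class FittedStageModel:
    """A per-growth-stage model selected by LOOCV, with its fit diagnostics."""

    params: ModelParams
    stage_label: str = ""
    rmse: float = float("nan")
    rrmse: float = float("nan")
    r_squared: float = float("nan")
    fold_params: List[ModelParams] = field(default_factory=list)
    selected_fold: int = -1

    @property
    def equation_text(self) -> str:
        return render_equation(self.params)


def render_equation(params: ModelParams) -> str:
    """Human-readable per-stage equation, e.g. 'LAI = 1.58*ln(0.78/(0.93-NDVI))'."""
    return (f"LAI = {params.k_ndvi:.2f}*ln({params.amplitude:.2f}/"
            f"({params.ndvi_inf:.2f}-NDVI))")


ArrayLike = Union[float, Sequence[float], np.ndarray]


def forward_ndvi(lai: ArrayLike, params: ModelParams) -> Union[float, np.ndarray]:
    """NDVI predicted from LAI: exponential saturation toward the asymptote.

    Value at LAI = 0 is the bare-soil NDVI; strictly increasing in LAI.
    """
    arr = np.asarray(lai, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LAI must be non-negative")
    out = params.ndvi_inf + (params.ndvi_bs - params.ndvi_inf) * np.exp(
        -arr / params.k_ndvi)
    return float(out) if np.isscalar(lai) else out


def invert_lai(ndvi: Union[ArrayLike, Grid], params: ModelParams,
               saturation_margin: float = 0.001) -> Union[float, np.ndarray, Grid]:
    """LAI retrieved from NDVI via the log-form inverse.

    NDVI at or below the bare-soil value clamps to LAI 0; NDVI within
    ``saturation_margin`` of the asymptote is evaluated at the margin so
    the logarithm stays finite. Accepts scalars, arrays or a Grid (nodata
    passes through).
    """
    if isinstance(ndvi, Grid):
        valid = ndvi.mask()
        out = np.full(ndvi.shape, ndvi.nodata, dtype=float)
        out[valid] = invert_lai(ndvi.values[valid], params, saturation_margin)
        return ndvi.with_values(out, band_label="lai")
    arr = np.asarray(ndvi, dtype=float)
    clipped = np.clip(arr, params.ndvi_bs, params.ndvi_inf - saturation_margin)
    lai = params.k_ndvi * np.log(params.amplitude / (params.ndvi_inf - clipped))
    lai = np.maximum(lai, 0.0)
    return float(lai) if np.isscalar(ndvi) else lai


def _multistart_points(bounds: ParamBounds) -> np.ndarray:
    """Deterministic starts: box corners plus the centre."""
    lo, hi = bounds.lower(), bounds.upper()
    corners = np.array([[lo[i] if (k >> i) & 1 else hi[i] for i in range(3)]
                        for k in range(8)])
    centre = (lo + hi) / 2.0
    return np.vstack([centre, corners])


def fit_params(lai_obs: Sequence[float], ndvi_obs: Sequence[float],
               bounds: ParamBounds = DEFAULT_BOUNDS) -> ModelParams:
    """Bounded least-squares fit of the forward model in NDVI space.

    Minimizes sum((ndvi_obs - NDVI(lai_obs; p))^2) over the bound box using
    trust-region reflective least squares started from the box corners and
    centre, keeping the best converged solution (deterministic).
    """
    lai = np.asarray(lai_obs, dtype=float)
    ndvi = np.asarray(ndvi_obs, dtype=float)
    if lai.shape != ndvi.shape or lai.ndim != 1:
        raise ValueError("lai_obs and ndvi_obs must be 1-D and equal length")
    if lai.size < 3:
        raise ValueError("at least 3 (LAI, NDVI) observations required")
    if not (np.all(np.isfinite(lai)) and np.all(np.isfinite(ndvi))):
        raise ValueError("observations must be finite")
    if np.ptp(lai) == 0:
        raise ValueError(
            "all LAI observations identical: the exponential model is "
            "unidentifiable from a single abscissa")

    def residuals(p: np.ndarray) -> np.ndarray:
        inf, bs, k = p
        return inf + (bs - inf) * np.exp(-lai / k) - ndvi

    lo, hi = bounds.lower(), bounds.upper()
    best: Optional[np.ndarray] = None
    best_cost = np.inf
    for x0 in _multistart_points(bounds):
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if sol.cost < best_cost - 1e-15:
            best_cost = sol.cost
            best = sol.x
    assert best is not None
    return ModelParams(*(float(v) for v in best))


def fit_metrics(pred: Sequence[float], obs: Sequence[float]) -> FitMetrics:
    """RMSE, RRMSE (RMSE / mean(obs)) and squared Pearson correlation.

    A constant prediction or observation series has no defined correlation;
    r_squared is reported as 0 with the degenerate flag set.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("pred and obs must be equal-length 1-D, n >= 2")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    mean_obs = float(np.mean(o))
    if mean_obs == 0:
        raise ValueError("mean(obs) is zero: RRMSE undefined")
    rrmse = rmse / mean_obs
    degenerate = bool(np.std(p) == 0 or np.std(o) == 0)
    if degenerate:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    return FitMetrics(rmse, rrmse, r2, r2_degenerate=degenerate)


def loocv_select(lai_obs: Sequence[float], ndvi_obs: Sequence[float],
                 bounds: ParamBounds = DEFAULT_BOUNDS,
                 stage_label: str = "") -> FittedStageModel:
    """Leave-one-out model selection for one growth stage.

    Each of the n folds refits the model on the other n - 1 samples. Every
    candidate parameter set is then scored by the RMSE of its inverted LAI
    predictions against ALL n field samples, and the lowest-RMSE candidate
    wins (ties break toward the lowest fold index). The returned record
    carries the winner's full-sample RMSE, RRMSE and R^2 plus every fold's
    parameters for audit.
    """
    lai = np.asarray(lai_obs, dtype=float)
    ndvi = np.asarray(ndvi_obs, dtype=float)
    n = lai.size
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    folds: List[ModelParams] = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        folds.append(fit_params(lai[keep], ndvi[keep], bounds))
    best_idx = -1
    best_rmse = np.inf
    for i, cand in enumerate(folds):
        pred = invert_lai(ndvi, cand)
        rmse = float(np.sqrt(np.mean((pred - lai) ** 2)))
        if rmse < best_rmse - 1e-15:
            best_rmse = rmse
            best_idx = i
    winner = folds[best_idx]
    metrics = fit_metrics(invert_lai(ndvi, winner), lai)
    return FittedStageModel(params=winner, stage_label=stage_label,
                            rmse=metrics.rmse, rrmse=metrics.rrmse,
                            r_squared=metrics.r_squared, fold_params=folds,
                            selected_fold=best_idx)
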