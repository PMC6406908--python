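"""Polynomial trend fitting, extrapolation, and top-k ranking of fields.

Each field's Δ-AII history inside a sliding window (by default the last
five years) is fitted with an ordinary least-squares polynomial of degree
1, 2 or 3 on integer time indices 1..window_length, and the fitted curve
is evaluated ``horizon`` steps past the window to predict the fold change
one to three years ahead. Fields are then ranked by predicted Δ-AII
(largest first) and the top-k form the predicted "hot" set.

Degree 1 (the linear trend) is the recommended default: higher degrees
interpolate short windows too eagerly and extrapolate erratically.
Calendar years map affinely onto the 1..window_length axis, which leaves
polynomial predictions unchanged.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impact_index import DeltaSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FitError",
    "ForecastConfig",
    "ForecastRecord",
    "ForecastResult",
    "fit_polynomial_trend",
    "extrapolate",
    "forecast_all",
    "write_forecast_csv",
]


class FitError(ValueError):
    """A regression window cannot be fitted (too few or degenerate points)."""


@dataclass(frozen=True)
class ForecastConfig:
    """Knobs of the forecasting step.

    window_length
        Number of trailing Δ-AII years fitted (default 5).
    degree
        Polynomial degree, 1–3.
    horizon
        Years past the window end to predict, 1–3.
    top_k
        Size of the predicted "hot fields" set (default 20).
    """

    window_length: int = 5
    degree: int = 1
    horizon: int = 1
    top_k: int = 20

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        if self.horizon not in (1, 2, 3):
            raise ValueError(f"horizon must be 1, 2 or 3, got {self.horizon}")
        if self.window_length < self.degree + 1:
            raise ValueError(
                f"window_length={self.window_length} is too short to fit degree {self.degree}"
            )
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class ForecastRecord:
    field: str
    predicted_delta_aii: float
    rank: int


@dataclass(frozen=True)
class ForecastResult:
    """Ranked point predictions of Δ-AII at one target year.

    ``records`` are sorted by rank (1 = largest predicted fold change);
    ``top_k_fields`` are the first ``top_k`` of them in rank order.
    ``nonpositive_fields`` flags fields whose extrapolated value is ≤ 0 —
    kept and ranked as-is, since an undershooting extrapolation is still an
    ordering signal, but flagged because a true fold change is positive.
    """

    target_year: int
    records: tuple[ForecastRecord, ...]
    top_k_fields: tuple[str, ...]
    nonpositive_fields: tuple[str, ...] = ()

    def predicted(self) -> dict[str, float]:
        return {r.field: r.predicted_delta_aii for r in self.records}

    def to_frame(self, top_k: int | None = None) -> pd.DataFrame:
        k = len(self.top_k_fields) if top_k is None else top_k
        return pd.DataFrame(
            {
                "field": [r.field for r in self.records],
                "target_year": self.target_year,
                "predicted_delta_aii": [r.predicted_delta_aii for r in self.records],
                "rank": [r.rank for r in self.records],
                "in_top_k": [r.rank <= k for r in self.records],
            }
        )


def fit_polynomial_trend(
    points: Sequence[tuple[float, float]], degree: int
) -> np.ndarray:
    """Least-squares polynomial fit; returns coefficients c0..c_degree.

    Coefficients are in ascending power order, so the fitted value at time
    t is ``sum(c[i] * t**i)``. Solved through numpy's SVD-based ``lstsq``
    on the Vandermonde design, which is numerically stable on the short,
    well-scaled windows used here.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be (time, value) pairs")
    t, y = pts[:, 0], pts[:, 1]
    if len(t) < degree + 1:
        raise FitError(f"need at least {degree + 1} points for degree {degree}, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise FitError("time indices must be strictly increasing")
    design = np.vander(t, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coeffs


def extrapolate(coefficients: np.ndarray, window_length: int, horizon: int) -> float:
    """Evaluate a fitted window polynomial ``horizon`` steps past the window.

    The window occupies time indices 1..window_length, so the prediction
    point is index window_length + horizon.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return float(np.polynomial.polynomial.polyval(window_length + horizon, coefficients))


def forecast_all(
    delta: DeltaSeries, config: ForecastConfig, window_end_year: int
) -> ForecastResult:
    """Fit, extrapolate and rank every field of a Δ-AII series.

    The fitted window is the ``window_length`` years ending at
    ``window_end_year``; the target year is ``window_end_year + horizon``.
    Ranking is by predicted Δ-AII descending, ties broken by field name, so
    the result is independent of field input order.
    """
    w, h = config.window_length, config.horizon
    window_years = range(window_end_year - w + 1, window_end_year + 1)
    for y in window_years:
        if y not in delta.years:
            raise ValueError(
                f"window {window_years.start}-{window_end_year} not covered by the "
                f"Δ-AII series ({delta.years.start}-{delta.years.stop - 1})"
            )
    t = np.arange(1, w + 1, dtype=float)
    y0 = window_years.start - delta.years.start
    predictions: dict[str, float] = {}
    for fi, field in enumerate(delta.fields):
        window = delta.values[fi, y0 : y0 + w]
        coeffs = fit_polynomial_trend(list(zip(t, window)), config.degree)
        predictions[field] = extrapolate(coeffs, w, h)
    order = sorted(predictions, key=lambda f: (-predictions[f], f))
    records = tuple(
        ForecastRecord(field=f, predicted_delta_aii=predictions[f], rank=i + 1)
        for i, f in enumerate(order)
    )
    nonpositive = tuple(f for f in order if predictions[f] <= 0)
    if nonpositive:
        logger.info("extrapolated Δ-AII ≤ 0 for %d field(s): %s", len(nonpositive), nonpositive)
    return ForecastResult(
        target_year=window_end_year + h,
        records=records,
        top_k_fields=tuple(order[: config.top_k]),
        nonpositive_fields=nonpositive,
    )


def write_forecast_csv(result: ForecastResult, path, top_k: int | None = None) -> None:
    result.to_frame(top_k=top_k).to_csv(path, index=False)
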