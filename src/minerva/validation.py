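"""Backtesting forecasts against held-out years of the Δ-AII record.

Four accuracy notions are pooled over every sliding window whose target
year has actual data:

* **Accuracy A** — point accuracy: the fraction of (field, window) pairs
  whose predicted Δ-AII is within a tolerance (default 1.0 fold units) of
  the actual value; the headline figure is the horizon-1 value.
* **Accuracies B, C, D** — top-k set overlap between the predicted and the
  actual top-k fields at horizons 1, 2 and 3 years past the window.

Because a random guess already matches the actual top-k at rate
p0 = top_k / n_fields (20/79 ≈ 25.3% at the defaults), each pooled
overlap accuracy is tested against that coincidence baseline with a
one-sided exact binomial test (alternative: the forecaster matches more
often than chance).
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace, asdict

import pandas as pd
from scipy import stats

from .forecasting import ForecastConfig, forecast_all
from .impact_index import DeltaSeries

__all__ = [
    "WindowResult",
    "HorizonSummary",
    "BacktestReport",
    "point_accuracy",
    "topk_overlap",
    "binomial_match_test",
    "run_backtest",
    "write_backtest_json",
]


def point_accuracy(
    predicted: Mapping[str, float],
    actual: Mapping[str, float],
    tolerance: float = 1.0,
) -> float:
    """Fraction of fields whose prediction is within ``tolerance`` of the truth.

    The tolerance is an absolute difference in fold units: a predicted
    Δ-AII of 2.0 against an actual 1.5 is "accurate" at the default 1.0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if set(predicted) != set(actual):
        missing = set(predicted) ^ set(actual)
        raise ValueError(f"predicted and actual field sets differ: {sorted(missing)}")
    if not predicted:
        raise ValueError("empty field set")
    hits = sum(1 for f in predicted if abs(predicted[f] - actual[f]) <= tolerance)
    return hits / len(predicted)


def topk_overlap(
    predicted_topk: Sequence[str], actual_topk: Sequence[str]
) -> tuple[int, float]:
    """Rank-agnostic overlap between two top-k field lists.

    Returns (matches, matches / k): a field counts as matched if it appears
    anywhere in both lists, irrespective of position.
    """
    if len(predicted_topk) != len(actual_topk):
        raise ValueError(
            f"top-k lists must have equal length, got {len(predicted_topk)} and {len(actual_topk)}"
        )
    if len(set(predicted_topk)) != len(predicted_topk):
        raise ValueError("duplicate entries in predicted top-k list")
    if len(set(actual_topk)) != len(actual_topk):
        raise ValueError("duplicate entries in actual top-k list")
    if not predicted_topk:
        raise ValueError("top-k lists must be non-empty")
    matches = len(set(predicted_topk) & set(actual_topk))
    return matches, matches / len(predicted_topk)


def binomial_match_test(matches: int, trials: int, p0: float) -> float:
    """One-sided exact binomial tail P(X ≥ matches | trials, p0).

    The null is that matches arise at the coincidence rate p0; the
    alternative is "greater" (the forecaster beats chance).
    """
    if not 0 <= matches <= trials:
        raise ValueError(f"need 0 <= matches <= trials, got {matches}/{trials}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binomtest(matches, trials, p0, alternative="greater").pvalue)


@dataclass(frozen=True)
class WindowResult:
    """One (window, horizon) backtest trial: k prediction slots scored."""

    horizon: int
    window_start: int
    window_end: int
    target_year: int
    matches: int
    trials: int
    overlap_accuracy: float
    point_accuracy: float
    p_value: float


@dataclass(frozen=True)
class HorizonSummary:
    """Pooled match counts and significance for one forecast horizon."""

    horizon: int
    windows: int
    matches: int
    trials: int
    accuracy: float
    p_value: float
    point_accuracy: float


@dataclass(frozen=True)
class BacktestReport:
    degree: int
    top_k: int
    n_fields: int
    p0: float
    accuracy_a: float
    horizons: tuple[HorizonSummary, ...]
    windows: tuple[WindowResult, ...]

    def horizon(self, h: int) -> HorizonSummary:
        for s in self.horizons:
            if s.horizon == h:
                return s
        raise KeyError(f"no horizon {h} in report")

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "top_k": self.top_k,
            "n_fields": self.n_fields,
            "p0": self.p0,
            "accuracy_a": self.accuracy_a,
            "horizons": [asdict(s) for s in self.horizons],
            "windows": [asdict(w) for w in self.windows],
        }

    def windows_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(w) for w in self.windows])


def run_backtest(
    delta: DeltaSeries,
    config: ForecastConfig,
    tolerance: float = 1.0,
    horizons: Sequence[int] = (1, 2, 3),
) -> BacktestReport:
    """Backtest a forecaster over every window with held-out actual data.

    For each horizon h, every window of ``config.window_length`` Δ-AII
    years whose target year (window end + h) is still inside the series is
    forecast, the predicted top-k is compared with the actual top-k of the
    target year, and matches are pooled across windows (k slots per
    window). Point accuracy (Accuracy A) is pooled over all fields and
    windows per horizon; the reported ``accuracy_a`` is the smallest-
    horizon value. p0 = top_k / n_fields is the binomial null.
    """
    w = config.window_length
    n_fields = len(delta.fields)
    if config.top_k > n_fields:
        raise ValueError(f"top_k={config.top_k} exceeds the {n_fields} fields available")
    p0 = config.top_k / n_fields
    n_years = len(delta.years)
    if n_years < w + min(horizons):
        raise ValueError(
            f"backtest needs at least window_length + horizon = {w + min(horizons)} "
            f"Δ-AII years, got {n_years}"
        )
    window_results: list[WindowResult] = []
    summaries: list[HorizonSummary] = []
    for h in sorted(horizons):
        cfg = replace(config, horizon=h)
        pooled_matches = pooled_trials = 0
        point_hits = point_trials = 0
        n_windows = 0
        for end_year in range(delta.years.start + w - 1, delta.years.stop - h):
            result = forecast_all(delta, cfg, end_year)
            target = result.target_year
            actual = {f: delta.value(f, target) for f in delta.fields}
            actual_order = sorted(actual, key=lambda f: (-actual[f], f))
            matches, frac = topk_overlap(result.top_k_fields, actual_order[: config.top_k])
            pacc = point_accuracy(result.predicted(), actual, tolerance=tolerance)
            window_results.append(
                WindowResult(
                    horizon=h,
                    window_start=end_year - w + 1,
                    window_end=end_year,
                    target_year=target,
                    matches=matches,
                    trials=config.top_k,
                    overlap_accuracy=frac,
                    point_accuracy=pacc,
                    p_value=binomial_match_test(matches, config.top_k, p0),
                )
            )
            pooled_matches += matches
            pooled_trials += config.top_k
            point_hits += round(pacc * n_fields)
            point_trials += n_fields
            n_windows += 1
        if n_windows == 0:
            continue
        summaries.append(
            HorizonSummary(
                horizon=h,
                windows=n_windows,
                matches=pooled_matches,
                trials=pooled_trials,
                accuracy=pooled_matches / pooled_trials,
                p_value=binomial_match_test(pooled_matches, pooled_trials, p0),
                point_accuracy=point_hits / point_trials,
            )
        )
    if not summaries:
        raise ValueError(
            f"no valid backtest window: the series spans {n_years} Δ-AII years but "
            f"window_length + horizon requires at least {w + min(horizons)}"
        )
    return BacktestReport(
        degree=config.degree,
        top_k=config.top_k,
        n_fields=n_fields,
        p0=p0,
        accuracy_a=summaries[0].point_accuracy,
        horizons=tuple(summaries),
        windows=tuple(window_results),
    )


def write_backtest_json(report: BacktestReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
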