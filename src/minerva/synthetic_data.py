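"""Synthetic publication-count panels with planted trend regimes.

The generator emulates the corpus the pipeline is designed for: 79 field
keywords tracked across 30 journals over 10 contiguous years, with small
per-cell article counts (mostly 0–10) and journal impact factors spanning
roughly 1 to 45. Counts are Poisson draws around a field-level rate whose
time course follows one of four regimes:

* ``stationary`` — constant rate; expected Δ-AII ≡ 1.
* ``emerging``  — rate multiplied by a per-field growth factor g each
  year; expected Δ-AII ≡ g.
* ``burst``     — constant rate with a single year spiked by a large
  multiplier m (publication bursts of 5–25× are observed in real panels);
  expected Δ-AII is m at the burst year, 1/m the year after, 1 elsewhere.
* ``declining`` — rate multiplied by a per-field decay factor d < 1 each
  year; expected Δ-AII ≡ d.

Every field carries a ground-truth label and its generative parameters,
so parameter-recovery and null-calibration tests can check the whole
pipeline against what was planted.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np

from .corpus_io import CountPanel, FieldSpec, JournalSpec

__all__ = [
    "REGIMES",
    "SimulationConfig",
    "FieldTruth",
    "GroundTruth",
    "simulate_impact_factors",
    "simulate_panel",
    "expected_delta_trajectory",
    "write_ground_truth_json",
]

REGIMES = ("stationary", "emerging", "burst", "declining")

#: Default regime proportions: a majority of fields hold steady, a quarter
#: grow, and smaller shares burst or fade — the texture of a real panel in
#: which most keywords are mature and a handful take off.
DEFAULT_REGIME_MIX = {
    "stationary": 0.45,
    "emerging": 0.25,
    "burst": 0.15,
    "declining": 0.15,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic corpus.

    Defaults mirror the reference corpus shape: 79 fields × 30 journals ×
    10 years, impact factors from 1.081 (lowest tracked journal) to 44.405
    (highest), ~0.5 expected articles per (field, journal, year). Growth
    factors are drawn per emerging field from [1.2, growth_factor]; decay
    factors from [decay_factor, 0.9]; burst years are randomized per field
    so spikes do not coincide.
    """

    n_fields: int = 79
    n_journals: int = 30
    years: range = range(2008, 2018)
    seed: int = 0
    if_range: tuple[float, float] = (1.081, 44.405)
    regime_mix: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_REGIME_MIX)
    )
    base_rate: float = 0.5
    growth_factor: float = 2.0
    burst_multiplier: float = 25.0
    decay_factor: float = 0.7

    def __post_init__(self) -> None:
        if self.n_fields < 1 or self.n_journals < 1:
            raise ValueError("n_fields and n_journals must be >= 1")
        if self.years.step != 1 or len(self.years) < 2:
            raise ValueError("years must be a contiguous range of >= 2 years")
        low, high = self.if_range
        if not 0 < low <= high:
            raise ValueError(f"if_range must satisfy 0 < low <= high, got {self.if_range}")
        mix = dict(self.regime_mix)
        if set(mix) - set(REGIMES):
            raise ValueError(f"unknown regimes in mix: {set(mix) - set(REGIMES)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
            raise ValueError("regime_mix proportions must be non-negative and sum to 1")
        # base_rate 0 is allowed as a degenerate all-zero panel: it drives
        # every AII to zero and exercises the Δ-AII substitution path.
        if self.base_rate < 0 or not np.isfinite(self.base_rate):
            raise ValueError("base_rate must be a finite non-negative rate")
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must be > 1")
        if self.burst_multiplier <= 1:
            raise ValueError("burst_multiplier must be > 1")
        if not 0 < self.decay_factor < 1:
            raise ValueError("decay_factor must be in (0, 1)")


@dataclass(frozen=True)
class FieldTruth:
    """Planted regime and generative parameters of one simulated field."""

    regime: str
    growth_factor: float | None = None
    burst_year: int | None = None
    burst_multiplier: float | None = None
    decay_factor: float | None = None


@dataclass(frozen=True)
class GroundTruth:
    fields: Mapping[str, FieldTruth]
    years: range

    def regime(self, field: str) -> str:
        return self.fields[field].regime

    def fields_with_regime(self, regime: str) -> list[str]:
        return [f for f, t in self.fields.items() if t.regime == regime]


def simulate_impact_factors(config: SimulationConfig) -> list[JournalSpec]:
    """Draw a journal table with a right-skewed impact-factor spread.

    Most journals sit at low single-digit impact factors with a thin tail
    of very high ones, as in real journal tables. The range endpoints are
    always included (journals 1 and 2), so a substitution constant derived
    as min(IF) equals ``if_range[0]`` — 1.081 at the defaults.
    """
    low, high = config.if_range
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1F]))
    ifs = np.clip(rng.lognormal(mean=np.log(4.0), sigma=0.9, size=config.n_journals), low, high)
    ifs[0] = low
    if config.n_journals > 1:
        ifs[1] = high
    width = len(str(config.n_journals))
    return [
        JournalSpec(name=f"Journal {i + 1:0{width}d}", impact_factor=round(float(v), 3))
        for i, v in enumerate(ifs)
    ]


def _assign_regimes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    # largest-remainder apportionment keeps the mix exact up to rounding
    mix = {r: config.regime_mix.get(r, 0.0) for r in REGIMES}
    raw = {r: mix[r] * config.n_fields for r in REGIMES}
    counts = {r: int(np.floor(v)) for r, v in raw.items()}
    short = config.n_fields - sum(counts.values())
    for r in sorted(REGIMES, key=lambda r: raw[r] - counts[r], reverse=True)[:short]:
        counts[r] += 1
    labels = [r for r in REGIMES for _ in range(counts[r])]
    rng.shuffle(labels)
    return labels


def simulate_panel(
    config: SimulationConfig, noiseless: bool = False
) -> tuple[CountPanel, GroundTruth]:
    """Generate a count panel and its planted ground truth.

    Counts are independent Poisson draws per (field, journal, year) with
    mean λ(field, year) set by the field's regime. With ``noiseless=True``
    the Poisson step is skipped and counts are the rounded expected values
    — useful for exact parameter-recovery checks (pair it with a large
    ``base_rate`` so rounding error is negligible).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x2F]))
    years = config.years
    n_y = len(years)
    labels = _assign_regimes(config, rng)
    width = len(str(config.n_fields))
    names = [f"field-{i + 1:0{width}d}" for i in range(config.n_fields)]

    lam = np.empty((config.n_fields, n_y))
    truth: dict[str, FieldTruth] = {}
    t = np.arange(n_y)
    for fi, (name, regime) in enumerate(zip(names, labels)):
        if regime == "stationary":
            lam[fi] = config.base_rate
            truth[name] = FieldTruth(regime="stationary")
        elif regime == "emerging":
            g = float(rng.uniform(min(1.2, config.growth_factor), config.growth_factor))
            lam[fi] = config.base_rate * g**t
            truth[name] = FieldTruth(regime="emerging", growth_factor=g)
        elif regime == "burst":
            m = float(config.burst_multiplier)
            burst_year = int(rng.integers(years.start + 1, years.stop))
            lam[fi] = config.base_rate
            lam[fi, burst_year - years.start] *= m
            truth[name] = FieldTruth(regime="burst", burst_year=burst_year, burst_multiplier=m)
        else:  # declining
            d = float(rng.uniform(config.decay_factor, max(0.9, config.decay_factor)))
            lam[fi] = config.base_rate * d**t
            truth[name] = FieldTruth(regime="declining", decay_factor=d)

    if noiseless:
        counts = np.rint(np.broadcast_to(lam[:, None, :], (config.n_fields, config.n_journals, n_y))).astype(np.int64)
    else:
        counts = rng.poisson(
            np.broadcast_to(lam[:, None, :], (config.n_fields, config.n_journals, n_y))
        ).astype(np.int64)

    panel = CountPanel(
        fields=tuple(FieldSpec(n) for n in names),
        journals=tuple(simulate_impact_factors(config)),
        years=years,
        counts=counts,
    )
    return panel, GroundTruth(fields=truth, years=years)


def expected_delta_trajectory(ground_truth: GroundTruth, field: str) -> dict[int, float]:
    """Noiseless Δ-AII trajectory implied by a field's planted rate model.

    Returned over the Δ years (every simulated year but the first):
    constant 1 for stationary fields, constant g for emerging, constant d
    for declining; for burst fields the multiplier m appears at the burst
    year, its reciprocal the following year, and 1 elsewhere.
    """
    if field not in ground_truth.fields:
        raise KeyError(f"unknown field {field!r} in ground truth")
    t = ground_truth.fields[field]
    delta_years = range(ground_truth.years.start + 1, ground_truth.years.stop)
    if t.regime == "stationary":
        return {y: 1.0 for y in delta_years}
    if t.regime == "emerging":
        return {y: t.growth_factor for y in delta_years}
    if t.regime == "declining":
        return {y: t.decay_factor for y in delta_years}
    traj = {y: 1.0 for y in delta_years}
    if t.burst_year in delta_years:
        traj[t.burst_year] = t.burst_multiplier
    if t.burst_year + 1 in delta_years:
        traj[t.burst_year + 1] = 1.0 / t.burst_multiplier
    return traj


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "years": [truth.years.start, truth.years.stop - 1],
        "fields": {f: asdict(t) for f, t in truth.fields.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
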