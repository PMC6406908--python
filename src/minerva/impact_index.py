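"""Annual impact indices and their year-over-year fold changes.

The annual impact (AI) of a field in one journal in one year is
``N × IF`` — the article count weighted by the journal's impact factor.
Summing the AIs across all tracked journals gives the field's annual
impact index (AII), its impact-weighted publication mass for that year.

Because fields differ hugely in absolute mass (a broad field can dwarf an
emerging one by two orders of magnitude), trends are compared on the
year-over-year fold change Δ-AII = AII(y) / AII(y−1). A zero AII would
make the fold change undefined or degenerate, so zeros are replaced by a
small positive substitution constant before dividing; the default, 1.081,
equals the AI of a single article in the lowest-impact-factor tracked
journal, i.e. the smallest nonzero mass the panel can express.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .corpus_io import CountPanel, FormatError, JournalSpec, ValidationError

__all__ = [
    "SUB_CONSTANT_DEFAULT",
    "AIITable",
    "DeltaSeries",
    "Substitution",
    "annual_impact",
    "annual_impact_index",
    "compute_aii_table",
    "delta_aii",
    "derive_sub_constant",
    "read_aii_csv",
    "write_aii_csv",
    "read_delta_csv",
    "write_delta_csv",
]

#: Default zero-substitution constant: one article in the lowest-IF tracked
#: journal of the reference journal table (impact factor 1.081).
SUB_CONSTANT_DEFAULT = 1.081


@dataclass
class AIITable:
    """Per-field, per-year annual impact index values.

    ``values[f, y]`` is Σ_journals count × impact_factor for field ``f`` in
    year ``years[y]`` — always ≥ 0, and 0 exactly when the field published
    nothing in any tracked journal that year.
    """

    fields: tuple[str, ...]
    years: range
    values: np.ndarray

    _field_idx: dict[str, int] = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.fields = tuple(self.fields)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.step != 1 or len(self.years) == 0:
            raise ValidationError("years must be a non-empty contiguous range")
        if self.values.shape != (len(self.fields), len(self.years)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match (fields, years)"
            )
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValidationError("AII values must be finite and non-negative")
        self._field_idx = {k: i for i, k in enumerate(self.fields)}

    def value(self, field: str, year: int) -> float:
        if field not in self._field_idx:
            raise KeyError(f"unknown field {field!r}")
        if year not in self.years:
            raise KeyError(f"year {year} outside table range")
        return float(self.values[self._field_idx[field], year - self.years.start])

    def to_frame(self) -> pd.DataFrame:
        f, y = np.indices(self.values.shape).reshape(2, -1)
        return pd.DataFrame(
            {
                "field": [self.fields[i] for i in f],
                "year": [self.years.start + i for i in y],
                "aii": self.values[f, y],
            }
        )


@dataclass(frozen=True)
class Substitution:
    """Record of the zero-substitution rule firing at one ratio position."""

    field: str
    year: int  # the Δ-AII year (the ratio's numerator year)
    position: str  # "numerator" or "denominator"


@dataclass
class DeltaSeries:
    """Year-over-year AII fold changes (Δ-AII) for every field.

    The series starts one year after the AII table (a fold change needs a
    predecessor). Entries where a zero AII was replaced by the substitution
    constant are listed in ``substituted`` so the raw ratios stay auditable.
    All values are finite and strictly positive.
    """

    fields: tuple[str, ...]
    years: range
    values: np.ndarray
    sub_constant: float = SUB_CONSTANT_DEFAULT
    substituted: frozenset[Substitution] = frozenset()

    _field_idx: dict[str, int] = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.fields = tuple(self.fields)
        self.values = np.asarray(self.values, dtype=float)
        if self.sub_constant <= 0:
            raise ValidationError("sub_constant must be positive")
        if self.values.shape != (len(self.fields), len(self.years)):
            raise ValidationError("values shape does not match (fields, years)")
        if (self.values <= 0).any() or not np.isfinite(self.values).all():
            raise ValidationError("Δ-AII values must be finite and strictly positive")
        self._field_idx = {k: i for i, k in enumerate(self.fields)}

    def value(self, field: str, year: int) -> float:
        if field not in self._field_idx:
            raise KeyError(f"unknown field {field!r}")
        if year not in self.years:
            raise KeyError(f"year {year} outside series range")
        return float(self.values[self._field_idx[field], year - self.years.start])

    def field_series(self, field: str) -> dict[int, float]:
        row = self.values[self._field_idx[field]]
        return {y: float(v) for y, v in zip(self.years, row)}

    def to_frame(self) -> pd.DataFrame:
        subs: dict[tuple[str, int], list[str]] = {}
        for s in self.substituted:
            subs.setdefault((s.field, s.year), []).append(s.position)
        f, y = np.indices(self.values.shape).reshape(2, -1)
        return pd.DataFrame(
            {
                "field": [self.fields[i] for i in f],
                "year": [self.years.start + i for i in y],
                "delta_aii": self.values[f, y],
                "substituted": [
                    "+".join(sorted(subs.get((self.fields[i], self.years.start + j), [])))
                    for i, j in zip(f, y)
                ],
            }
        )


def annual_impact(count: int, impact_factor: float) -> float:
    """AI = N × IF: article count weighted by the journal's impact factor."""
    if count != int(count) or count < 0:
        raise ValueError(f"count must be a non-negative integer, got {count!r}")
    if impact_factor <= 0:
        raise ValueError(f"impact factor must be positive, got {impact_factor!r}")
    return int(count) * float(impact_factor)


def annual_impact_index(panel: CountPanel, field: str, year: int) -> float:
    """AII: the sum of a field's AIs over every journal in the panel for one year."""
    f = panel.field_index(field)
    y = panel.year_index(year)
    return float(panel.counts[f, :, y] @ panel.impact_factors)


def compute_aii_table(panel: CountPanel) -> AIITable:
    """Tabulate the AII for every (field, year) of a count panel."""
    values = np.einsum("fjy,j->fy", panel.counts.astype(float), panel.impact_factors)
    return AIITable(fields=panel.field_keywords, years=panel.years, values=values)


def derive_sub_constant(journals: Sequence[JournalSpec]) -> float:
    """Substitution constant implied by a journal table: one article in its lowest-IF journal."""
    if not journals:
        raise ValueError("cannot derive a substitution constant from an empty journal table")
    return min(j.impact_factor for j in journals)


def delta_aii(table: AIITable, sub_constant: float = SUB_CONSTANT_DEFAULT) -> DeltaSeries:
    """Compute Δ-AII(y) = AII(y) / AII(y−1) with zero substitution.

    Any AII value equal to 0 — numerator or denominator — is first replaced
    by ``sub_constant``, so every fold change is finite and positive and a
    0 → 0 transition reads as "no change" (Δ = 1). Each replacement is
    recorded in the returned series.
    """
    if sub_constant <= 0:
        raise ValidationError(f"sub_constant must be positive, got {sub_constant}")
    if len(table.years) < 2:
        raise ValidationError("Δ-AII needs at least two years of AII values")
    prev = table.values[:, :-1].copy()
    curr = table.values[:, 1:].copy()
    years = range(table.years.start + 1, table.years.stop)
    subs: set[Substitution] = set()
    for fi, f in enumerate(table.fields):
        for yi, y in enumerate(years):
            if curr[fi, yi] == 0:
                curr[fi, yi] = sub_constant
                subs.add(Substitution(field=f, year=y, position="numerator"))
            if prev[fi, yi] == 0:
                prev[fi, yi] = sub_constant
                subs.add(Substitution(field=f, year=y, position="denominator"))
    return DeltaSeries(
        fields=table.fields,
        years=years,
        values=curr / prev,
        sub_constant=sub_constant,
        substituted=frozenset(subs),
    )


# ---------------------------------------------------------------------------
# CSV round-trips (field,year,aii / field,year,delta_aii,substituted)

def write_aii_csv(table: AIITable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_aii_csv(path) -> AIITable:
    df = pd.read_csv(path)
    if list(df.columns) != ["field", "year", "aii"]:
        raise FormatError(f"AII table must have columns field,year,aii; got {list(df.columns)}")
    fields = tuple(dict.fromkeys(df["field"].astype(str)))
    years = range(int(df["year"].min()), int(df["year"].max()) + 1)
    values = np.zeros((len(fields), len(years)))
    fidx = {f: i for i, f in enumerate(fields)}
    for _, row in df.iterrows():
        values[fidx[str(row["field"])], int(row["year"]) - years.start] = float(row["aii"])
    return AIITable(fields=fields, years=years, values=values)


def write_delta_csv(series: DeltaSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_delta_csv(path, sub_constant: float = SUB_CONSTANT_DEFAULT) -> DeltaSeries:
    df = pd.read_csv(path)
    expected = ["field", "year", "delta_aii", "substituted"]
    if list(df.columns) != expected:
        raise FormatError(f"Δ-AII table must have columns {expected}; got {list(df.columns)}")
    fields = tuple(dict.fromkeys(df["field"].astype(str)))
    years = range(int(df["year"].min()), int(df["year"].max()) + 1)
    values = np.full((len(fields), len(years)), np.nan)
    fidx = {f: i for i, f in enumerate(fields)}
    subs: set[Substitution] = set()
    for _, row in df.iterrows():
        f, y = str(row["field"]), int(row["year"])
        values[fidx[f], y - years.start] = float(row["delta_aii"])
        if isinstance(row["substituted"], str) and row["substituted"]:
            for pos in row["substituted"].split("+"):
                subs.add(Substitution(field=f, year=y, position=pos))
    if np.isnan(values).any():
        raise ValidationError("Δ-AII table has missing (field, year) entries")
    return DeltaSeries(
        fields=fields, years=years, values=values,
        sub_constant=sub_constant, substituted=frozenset(subs),
    )
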