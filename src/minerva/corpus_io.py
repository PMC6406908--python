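"""Corpus input/output: journal tables, publication-count panels, query strings.

The raw material of the trend analysis is a panel of article counts — one
non-negative integer per (field keyword, journal, year) triple — together
with a table of journal impact factors. Counts of this kind are obtained
from PubMed hit counts for field-by-journal-by-year queries; this module
builds those query strings in the exact search-window dialect, and reads
and writes the tables as plain CSV/JSON so the rest of the pipeline never
touches the network.

A small word-frequency helper supports keyword-based selection of the
fields to track (the keywords are ranked by how often they occur in a
collection of titles/abstract terms).
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "JournalSpec",
    "FieldSpec",
    "CountPanel",
    "read_journal_table",
    "write_journal_table",
    "read_count_panel",
    "write_count_panel",
    "build_pubmed_query",
    "keyword_frequency",
]


class FormatError(ValueError):
    """A file does not have the expected tabular layout."""


class ValidationError(ValueError):
    """File contents violate a domain invariant (negative count, unknown name...)."""


@dataclass(frozen=True)
class JournalSpec:
    """A tracked journal and its impact factor.

    The impact factor acts as a fixed citations-per-article weight: every
    article counted in this journal contributes ``impact_factor`` units to
    the field's annual impact. A single impact-factor snapshot is applied
    to all years.
    """

    name: str
    impact_factor: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("journal name must be non-empty")
        if not np.isfinite(self.impact_factor) or self.impact_factor <= 0:
            raise ValidationError(
                f"impact factor for {self.name!r} must be positive, got {self.impact_factor!r}"
            )


@dataclass(frozen=True)
class FieldSpec:
    """A research field identified by its search keyword.

    ``directed`` marks broad keywords (e.g. "genetics", "single cell") whose
    PubMed query must be narrowed by AND-ing in an auxiliary disambiguation
    term, by default "brain tumor".
    """

    keyword: str
    directed: bool = False
    aux_term: str = "brain tumor"

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ValidationError("field keyword must be non-empty")


@dataclass
class CountPanel:
    """Article counts on a dense (field, journal, year) grid.

    ``counts[f, j, y]`` is the number of articles matching field ``f`` in
    journal ``j`` published in year ``years[y]``. Absent triples are zeros:
    a query with no hits is a count of 0, not missing data. Years are a
    contiguous inclusive range.
    """

    fields: tuple[FieldSpec, ...]
    journals: tuple[JournalSpec, ...]
    years: range
    counts: np.ndarray

    _field_idx: dict[str, int] = dc_field(init=False, repr=False)
    _journal_idx: dict[str, int] = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.fields = tuple(self.fields)
        self.journals = tuple(self.journals)
        kw = [f.keyword for f in self.fields]
        names = [j.name for j in self.journals]
        if len(set(kw)) != len(kw):
            raise ValidationError("duplicate field keywords in panel")
        if len(set(names)) != len(names):
            raise ValidationError("duplicate journal names in panel")
        if self.years.step != 1 or len(self.years) == 0:
            raise ValidationError("years must be a non-empty contiguous range")
        self.counts = np.asarray(self.counts)
        expected = (len(self.fields), len(self.journals), len(self.years))
        if self.counts.shape != expected:
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match (fields, journals, years) {expected}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.rint(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self._field_idx = {k: i for i, k in enumerate(kw)}
        self._journal_idx = {n: i for i, n in enumerate(names)}

    @property
    def field_keywords(self) -> tuple[str, ...]:
        return tuple(f.keyword for f in self.fields)

    @property
    def impact_factors(self) -> np.ndarray:
        return np.array([j.impact_factor for j in self.journals], dtype=float)

    def field_index(self, keyword: str) -> int:
        try:
            return self._field_idx[keyword]
        except KeyError:
            raise KeyError(f"unknown field keyword {keyword!r}") from None

    def journal_index(self, name: str) -> int:
        try:
            return self._journal_idx[name]
        except KeyError:
            raise KeyError(f"unknown journal {name!r}") from None

    def year_index(self, year: int) -> int:
        if year not in self.years:
            raise KeyError(f"year {year} outside panel range {self.years.start}-{self.years.stop - 1}")
        return year - self.years.start

    def count(self, field: str, journal: str, year: int) -> int:
        return int(
            self.counts[self.field_index(field), self.journal_index(journal), self.year_index(year)]
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, int, int]],
        journals: Sequence[JournalSpec],
        fields: Sequence[FieldSpec],
        years: range | None = None,
    ) -> "CountPanel":
        """Build a dense panel from (field, journal, year, count) records.

        The year range is inferred as [min, max] of the record years unless
        given explicitly; triples not mentioned get count 0.
        """
        journals = tuple(journals)
        fields = tuple(fields)
        f_idx = {f.keyword: i for i, f in enumerate(fields)}
        j_idx = {j.name: i for i, j in enumerate(journals)}
        rows = list(records)
        if years is None:
            if not rows:
                raise ValidationError("cannot infer a year range from an empty record set")
            yrs = [int(r[2]) for r in rows]
            years = range(min(yrs), max(yrs) + 1)
        counts = np.zeros((len(fields), len(journals), len(years)), dtype=np.int64)
        for fkw, jname, year, n in rows:
            if fkw not in f_idx:
                raise ValidationError(f"unknown field keyword {fkw!r} in count records")
            if jname not in j_idx:
                raise ValidationError(f"unknown journal {jname!r} in count records")
            year = int(year)
            if year not in years:
                raise ValidationError(f"year {year} outside range {years.start}-{years.stop - 1}")
            if not float(n) == int(n):
                raise ValidationError(f"count for ({fkw!r}, {jname!r}, {year}) is not an integer: {n!r}")
            n = int(n)
            if n < 0:
                raise ValidationError(f"negative count for ({fkw!r}, {jname!r}, {year}): {n}")
            counts[f_idx[fkw], j_idx[jname], year - years.start] += n
        return cls(fields=fields, journals=journals, years=years, counts=counts)

    def to_frame(self, include_zeros: bool = False) -> pd.DataFrame:
        """Long-format DataFrame with columns field, journal, year, count."""
        f, j, y = np.nonzero(self.counts if not include_zeros else np.ones_like(self.counts))
        return pd.DataFrame(
            {
                "field": [self.fields[i].keyword for i in f],
                "journal": [self.journals[i].name for i in j],
                "year": [self.years.start + i for i in y],
                "count": self.counts[f, j, y],
            }
        )


# ---------------------------------------------------------------------------
# file I/O

def read_journal_table(path) -> list[JournalSpec]:
    """Read a CSV with columns ``name,impact_factor`` into JournalSpecs.

    Row order is preserved. Duplicate names and non-positive impact factors
    are rejected with the offending row named. A completely empty file
    yields an empty list (with a warning).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("journal table %s is empty", path)
        return []
    if list(df.columns) != ["name", "impact_factor"]:
        raise FormatError(
            f"journal table must have exactly the columns name,impact_factor; got {list(df.columns)}"
        )
    specs: list[JournalSpec] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = str(row["name"])
        try:
            impact = float(row["impact_factor"])
        except (TypeError, ValueError):
            raise ValidationError(f"row {i + 1} ({name!r}): impact factor {row['impact_factor']!r} is not a number")
        if not np.isfinite(impact) or impact <= 0:
            raise ValidationError(f"row {i + 1} ({name!r}): impact factor must be positive, got {impact}")
        if name in seen:
            raise ValidationError(f"row {i + 1}: duplicate journal name {name!r}")
        seen.add(name)
        specs.append(JournalSpec(name=name, impact_factor=impact))
    return specs


def write_journal_table(journals: Sequence[JournalSpec], path) -> None:
    pd.DataFrame(
        {"name": [j.name for j in journals], "impact_factor": [j.impact_factor for j in journals]}
    ).to_csv(path, index=False)


def read_count_panel(
    path,
    journals: Sequence[JournalSpec],
    fields: Sequence[FieldSpec] | None = None,
) -> CountPanel:
    """Read a count panel from long-format CSV or nested JSON.

    CSV columns are ``field,journal,year,count``; the JSON alternative is a
    nested mapping field -> journal -> year -> count. When ``fields`` is
    None the field list is inferred from the file (first-appearance order,
    all undirected) — convenient for CLI use; passing explicit FieldSpecs
    keeps directedness information.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            nested: Mapping[str, Mapping[str, Mapping[str, int]]] = json.load(fh)
        records = [
            (fkw, jname, int(year), count)
            for fkw, per_journal in nested.items()
            for jname, per_year in per_journal.items()
            for year, count in per_year.items()
        ]
        inferred = [FieldSpec(k) for k in nested]
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise FormatError(f"count panel {path} is empty")
        if list(df.columns) != ["field", "journal", "year", "count"]:
            raise FormatError(
                f"count panel must have exactly the columns field,journal,year,count; got {list(df.columns)}"
            )
        for col in ("year", "count"):
            if not np.all(df[col].astype(float) == df[col].astype(float).round()):
                raise ValidationError(f"non-integer value in column {col!r}")
        records = list(
            zip(df["field"].astype(str), df["journal"].astype(str), df["year"].astype(int), df["count"])
        )
        inferred = [FieldSpec(k) for k in dict.fromkeys(df["field"].astype(str))]
    if fields is None:
        fields = inferred
    return CountPanel.from_records(records, journals=journals, fields=fields)


def write_count_panel(panel: CountPanel, path) -> None:
    """Write the nonzero counts of a panel as long-format CSV."""
    panel.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# query construction

def build_pubmed_query(field: FieldSpec | str, journal: JournalSpec | str, year: int) -> str:
    """Render the PubMed search-window command for one (field, journal, year).

    The dialect is::

        (({kw}) AND "{journal}" [Journal]) AND ("{year}" [Date-Publication]: "{year}" [Date-Publication])

    For a directed field the bare keyword clause ``({kw})`` is replaced by
    ``(({kw}) AND ({aux_term}))`` so that broad keywords stay anchored to
    the target domain.
    """
    if isinstance(field, str):
        field = FieldSpec(field)
    name = journal.name if isinstance(journal, JournalSpec) else journal
    year = int(year)
    if not 1000 <= year <= 9999:
        raise ValueError(f"year must be a 4-digit calendar year, got {year}")
    clause = f"({field.keyword})"
    if field.directed:
        clause = f"(({field.keyword}) AND ({field.aux_term}))"
    return (
        f'({clause} AND "{name}" [Journal]) AND '
        f'("{year}" [Date-Publication]: "{year}" [Date-Publication])'
    )


# ---------------------------------------------------------------------------
# keyword selection

_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def keyword_frequency(
    texts: Iterable[str],
    stopwords: Iterable[str] = (),
    top_n: int | None = None,
) -> list[tuple[str, int]]:
    """Rank terms in a text collection by occurrence count.

    Tokenization is case-folded and splits on non-alphanumeric characters,
    except that hyphenated compounds (PD-1, anti-mitotic) are kept as one
    token. Ties at equal count are broken lexicographically, so output is
    deterministic. ``top_n=None`` returns every term.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1 (or None for unbounded)")
    stop = {s.lower() for s in stopwords}
    counter: Counter[str] = Counter()
    for text in texts:
        counter.update(t for t in _TOKEN_RE.findall(text.lower()) if t not in stop)
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if top_n is None else ranked[:top_n]
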