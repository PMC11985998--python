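"""Reading, cleaning and reshaping species-occurrence records.

The raw input is a Darwin-Core-flavoured occurrence table: one row per
reported non-native species per country, with taxonomy, the year of first
record and two establishment-status columns (``degreeOfEstablishment``,
``occurrenceStatus``).  Cleaning removes records whose establishment status
is unclear (only CASUAL/ABSENT), restricts to a supplied set of European
countries and collapses duplicated species-country pairs.  The cleaned
records feed every downstream stage: a country × species presence matrix,
per-country annual first-record series and taxonomic composition summaries.
"""

from __future__ import annotations

import datetime
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column mapping; keys are internal names, values are CSV headers
DEFAULT_COLUMNS: dict[str, str] = {
    "species_name": "scientificName",
    "phylum": "phylum",
    "taxon_class": "class",
    "country": "country",
    "first_record_year": "firstRecordYear",
    "degree_of_establishment": "degreeOfEstablishment",
    "occurrence_status": "occurrenceStatus",
}

#: statuses whose exclusive presence marks an unclear establishment status
UNCLEAR_STATUSES = frozenset({"CASUAL", "ABSENT"})

MIN_YEAR = 1000


class SchemaError(ValueError):
    """Input table does not expose a required column."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One occurrence of a non-native species in a country."""

    species_name: str
    phylum: str | None
    taxon_class: str | None
    country: str
    first_record_year: int | None
    degree_of_establishment: str | None
    occurrence_status: str | None

    def __post_init__(self) -> None:
        if not self.species_name:
            raise ValueError("species_name must be non-empty")
        y = self.first_record_year
        if y is not None and not (MIN_YEAR <= y <= datetime.date.today().year):
            raise ValueError(f"first_record_year {y} outside plausible range")


@dataclass
class CleaningReport:
    """Accounting of record removals; every removal lands in exactly one bin."""

    n_input: int = 0
    n_removed_casual_absent: int = 0
    n_removed_non_european: int = 0
    n_removed_duplicates: int = 0
    n_output: int = 0

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_casual_absent
            + self.n_removed_non_european
            + self.n_removed_duplicates
        )
        if self.n_output != self.n_input - removed:
            raise ValueError("cleaning report does not balance")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class OccurrenceMatrix:
    """Boolean country × species presence matrix."""

    countries: list[str]
    species: list[str]
    presence: np.ndarray  # bool, shape (n_countries, n_species)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.countries), len(self.species)):
            raise ValueError("presence shape does not match labels")
        if len(set(self.countries)) != len(self.countries):
            raise ValueError("duplicate country labels")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")

    @property
    def richness(self) -> pd.Series:
        """Distinct species per country (row sums)."""
        return pd.Series(
            self.presence.sum(axis=1), index=self.countries, name="richness"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence, index=self.countries, columns=self.species
        )


@dataclass
class AnnualSeries:
    """Annual counts of newly reported established species for one country."""

    country: str
    years: np.ndarray  # consecutive ints
    counts: np.ndarray  # non-negative ints, aligned to years

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.years) != len(self.counts):
            raise ValueError("years and counts differ in length")
        if len(self.years) and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def normalize_species_name(
    name: str, synonym_map: Mapping[str, str] | None = None
) -> str:
    """Normalize a binomial: unicode NFC, lowercase, collapsed whitespace.

    ``synonym_map`` is an optional offline replacement for online name
    verification: applied after normalization, keys and values already
    normalized.
    """
    norm = unicodedata.normalize("NFKC", str(name))
    norm = re.sub(r"\s+", " ", norm).strip().lower()
    if synonym_map:
        norm = synonym_map.get(norm, norm)
    return norm


def _parse_year(raw: object) -> tuple[int | None, str | None]:
    """Parse a first-record year; return (year, problem)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None, None
    text = str(raw).strip()
    if text == "" or text.lower() in {"na", "nan", "none"}:
        return None, None
    try:
        value = int(text)
    except ValueError:
        return None, f"unparseable year {text!r}"
    if not (MIN_YEAR <= value <= datetime.date.today().year):
        return None, f"year {value} outside [{MIN_YEAR}, current]"
    return value, None


def read_species_records(
    path: str | Path,
    *,
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> list[SpeciesRecord]:
    """Read occurrence records from a CSV file.

    Parameters
    ----------
    path
        CSV with a header row.
    delimiter
        Field separator.
    columns
        Mapping from internal field names to CSV headers; missing keys fall
        back to :data:`DEFAULT_COLUMNS`.
    synonym_map
        Normalized-name → accepted-name replacements (offline stand-in for
        taxonomic name verification).

    Raises
    ------
    SchemaError
        If a required column is absent (named in the message).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [header for header in colmap.values() if header not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[SpeciesRecord] = []
    for i, row in frame.iterrows():
        year, problem = _parse_year(row[colmap["first_record_year"]])
        if problem:
            logger.warning("row %d: %s; year set to missing", i, problem)
        name = normalize_species_name(row[colmap["species_name"]], synonym_map)
        if not name:
            logger.warning("row %d: empty species name, row skipped", i)
            continue
        records.append(
            SpeciesRecord(
                species_name=name,
                phylum=row[colmap["phylum"]].strip() or None,
                taxon_class=row[colmap["taxon_class"]].strip() or None,
                country=row[colmap["country"]].strip(),
                first_record_year=year,
                degree_of_establishment=row[colmap["degree_of_establishment"]].strip()
                or None,
                occurrence_status=row[colmap["occurrence_status"]].strip() or None,
            )
        )
    return records


def _record_sort_key(r: SpeciesRecord):
    # earliest dated record wins; remaining fields break ties deterministically
    return (
        r.first_record_year if r.first_record_year is not None else 10**6,
        r.phylum or "",
        r.taxon_class or "",
        r.degree_of_establishment or "",
        r.occurrence_status or "",
    )


def clean_records(
    records: Sequence[SpeciesRecord],
    european_countries: Iterable[str],
) -> tuple[list[SpeciesRecord], CleaningReport]:
    """Apply the status, geography and duplicate filters.

    A species-country pair is dropped as *unclear* only when every status
    listed for it (over both status columns and all its rows) lies in
    {CASUAL, ABSENT} — pairs that also carry an established-type status
    survive.  Records for countries outside ``european_countries`` are
    removed next, then duplicated (species, country) pairs are collapsed to
    a single representative (the earliest dated record, with a
    deterministic tie-break), making the result independent of input order.
    """
    europe = set(european_countries)
    n_input = len(records)

    statuses: dict[tuple[str, str], set[str]] = {}
    for r in records:
        key = (r.species_name, r.country)
        bucket = statuses.setdefault(key, set())
        for s in (r.degree_of_establishment, r.occurrence_status):
            if s:
                bucket.add(s.upper())

    def unclear(r: SpeciesRecord) -> bool:
        listed = statuses[(r.species_name, r.country)]
        return bool(listed) and listed <= UNCLEAR_STATUSES

    kept = [r for r in records if not unclear(r)]
    n_casual_absent = n_input - len(kept)

    kept2 = [r for r in kept if r.country in europe]
    n_non_european = len(kept) - len(kept2)

    groups: dict[tuple[str, str], SpeciesRecord] = {}
    for r in sorted(kept2, key=_record_sort_key):
        groups.setdefault((r.species_name, r.country), r)
    deduped = [groups[k] for k in sorted(groups)]
    n_duplicates = len(kept2) - len(deduped)

    report = CleaningReport(
        n_input=n_input,
        n_removed_casual_absent=n_casual_absent,
        n_removed_non_european=n_non_european,
        n_removed_duplicates=n_duplicates,
        n_output=len(deduped),
    )
    return deduped, report


def build_occurrence_matrix(records: Sequence[SpeciesRecord]) -> OccurrenceMatrix:
    """Country × species presence matrix from cleaned records."""
    if not records:
        raise ValueError("cannot build an occurrence matrix from zero records")
    countries = sorted({r.country for r in records})
    species = sorted({r.species_name for r in records})
    ci = {c: i for i, c in enumerate(countries)}
    sj = {s: j for j, s in enumerate(species)}
    presence = np.zeros((len(countries), len(species)), dtype=bool)
    for r in records:
        presence[ci[r.country], sj[r.species_name]] = True
    return OccurrenceMatrix(countries=countries, species=species, presence=presence)


def annual_first_records(
    records: Sequence[SpeciesRecord], country: str
) -> AnnualSeries:
    """Zero-filled annual series of first records for one country.

    The series spans the first to the last observed first-record year; years
    without reports inside that window count zero — an active recording
    window with no reports is a genuine zero, and the trend test needs a
    regular series.
    """
    years = [
        r.first_record_year
        for r in records
        if r.country == country and r.first_record_year is not None
    ]
    if not years:
        raise ValueError(f"no dated records for country {country!r}")
    lo, hi = min(years), max(years)
    axis = np.arange(lo, hi + 1)
    counts = np.zeros(len(axis), dtype=int)
    for y in years:
        counts[y - lo] += 1
    return AnnualSeries(country=country, years=axis, counts=counts)


def composition_summary(
    records: Sequence[SpeciesRecord], level: str = "phylum"
) -> pd.DataFrame:
    """Distinct species per taxon, pooled across countries.

    Returns a frame with columns ``taxon``, ``n_species``, ``percent``,
    sorted by descending count.  Records lacking the requested taxonomy are
    bucketed as ``Unassigned``.  Percentages sum to 100.
    """
    if level not in {"phylum", "class"}:
        raise ValueError("level must be 'phylum' or 'class'")
    if not records:
        raise ValueError("no records to summarize")
    attr = "phylum" if level == "phylum" else "taxon_class"
    pairs = {(getattr(r, attr) or "Unassigned", r.species_name) for r in records}
    frame = (
        pd.DataFrame(sorted(pairs), columns=["taxon", "species"])
        .groupby("taxon", as_index=False)["species"]
        .nunique()
        .rename(columns={"species": "n_species"})
    )
    frame["percent"] = 100.0 * frame["n_species"] / frame["n_species"].sum()
    return frame.sort_values(
        ["n_species", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)


CATEGORY_LABELS: dict[str, str] = {
    "A": "research",
    "B": "economy",
    "C": "environment_culture",
    "D": "land_use",
}


@dataclass
class PredictorTable:
    """Country × predictor matrix with a driver-category label per column.

    Categories follow the four driver classes: A research, B economy,
    C environment & culture, D land use.
    """

    data: pd.DataFrame  # index: country, columns: predictors
    categories: dict[str, str] = field(default_factory=dict)  # predictor -> A-D

    def __post_init__(self) -> None:
        unknown = set(self.categories.values()) - set(CATEGORY_LABELS)
        if unknown:
            raise ValueError(f"unknown predictor categories: {sorted(unknown)}")
        missing = [c for c in self.data.columns if c not in self.categories]
        if missing:
            raise ValueError(f"predictors without a category: {missing}")

    @property
    def countries(self) -> list[str]:
        return list(self.data.index)

    @property
    def predictors(self) -> list[str]:
        return list(self.data.columns)

    def block(self, category: str) -> pd.DataFrame:
        """Sub-table of the predictors in one category (code or label)."""
        reverse = {v: k for k, v in CATEGORY_LABELS.items()}
        code = reverse.get(category, category)
        cols = [c for c in self.data.columns if self.categories[c] == code]
        return self.data[cols]

    def blocks(self) -> dict[str, pd.DataFrame]:
        """All four category blocks keyed by their long labels."""
        return {
            label: self.block(code)
            for code, label in CATEGORY_LABELS.items()
            if not self.block(code).empty
        }

    def drop(self, names: Iterable[str]) -> "PredictorTable":
        names = set(names)
        keep = [c for c in self.data.columns if c not in names]
        return PredictorTable(
            data=self.data[keep].copy(),
            categories={c: self.categories[c] for c in keep},
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "country"
        # category carried in a second header-like row via a companion column set
        out.to_csv(path)
        meta = Path(path).with_suffix(".categories.json")
        meta.write_text(json.dumps(self.categories, indent=2) + "\n")


def read_predictor_table(
    path: str | Path,
    *,
    categories: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> PredictorTable:
    """Read a country × predictor CSV (first column = country).

    Column categories come from ``categories`` or, failing that, from a
    ``<path>.categories.json`` companion file written by
    :meth:`PredictorTable.to_csv`.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if categories is None:
        meta = Path(path).with_suffix(".categories.json")
        if not meta.exists():
            raise SchemaError(
                f"no predictor categories given and {meta} does not exist"
            )
        categories = json.loads(meta.read_text())
    bad = frame.columns[~np.isfinite(frame.to_numpy(dtype=float)).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite predictor values in column(s): {list(bad)}")
    return PredictorTable(data=frame.astype(float), categories=dict(categories))


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the default CSV headers (round-trip)."""
    rows = [
        {
            DEFAULT_COLUMNS["species_name"]: r.species_name,
            DEFAULT_COLUMNS["phylum"]: r.phylum or "",
            DEFAULT_COLUMNS["taxon_class"]: r.taxon_class or "",
            DEFAULT_COLUMNS["country"]: r.country,
            DEFAULT_COLUMNS["first_record_year"]: (
                "" if r.first_record_year is None else r.first_record_year
            ),
            DEFAULT_COLUMNS["degree_of_establishment"]: r.degree_of_establishment
            or "",
            DEFAULT_COLUMNS["occurrence_status"]: r.occurrence_status or "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))


def write_cleaned_records(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
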