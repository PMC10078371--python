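"""Record tables, taxonomy harmonization and season-week assignment.

All downstream stages consume plain :class:`pandas.DataFrame` tables with
documented column sets:

``visits``
    raw field table ``plant, insect, date, count`` (one row per observation
    bout of a plant-insect pair, ``count`` visit events).
``pollen``
    per-individual pollen loads ``individual, insect, date, plant_genus,
    grains`` (grains of one plant genus washed off one captured insect).
``svd``
    single-visit deposition trials ``genus, family, grains, is_control``
    (conspecific grains deposited on a virgin stigma during one visit;
    control rows are unvisited flowers).
``taxonomy``
    harmonization map ``raw, canonical, rank, family``.

Parsed visit tables are converted to *interaction records* with columns
``plant_taxon, insect_taxon, year, week, count, evidence`` where ``week`` is
a season-week index shared across years (see :func:`assign_week`) and
``evidence`` is ``"visit"`` or ``"pollen"``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "INTERACTION_COLUMNS",
    "ParseReport",
    "SchemaError",
    "ParseError",
    "HarmonizationError",
    "TaxonomyMap",
    "read_records",
    "write_records",
    "harmonize",
    "assign_week",
    "season_week",
    "visits_to_interactions",
    "pollen_assign_weeks",
]

#: file-schema name -> ordered column names
SCHEMAS: dict[str, list[str]] = {
    "visits": ["plant", "insect", "date", "count"],
    "pollen": ["individual", "insect", "date", "plant_genus", "grains"],
    "svd": ["genus", "family", "grains", "is_control"],
    "taxonomy": ["raw", "canonical", "rank", "family"],
}

INTERACTION_COLUMNS = ["plant_taxon", "insect_taxon", "year", "week", "count", "evidence"]

_RANKS = {"species", "genus", "family"}


class SchemaError(ValueError):
    """A required column is missing or the schema name is unknown."""


class ParseError(ValueError):
    """A cell cannot be coerced to its declared type (reported with row number)."""


class HarmonizationError(ValueError):
    """One or more raw taxon names have no taxonomy-map entry."""


@dataclass
class ParseReport:
    """Outcome of one :func:`read_records` call."""

    path: str
    schema: str
    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def summary(self) -> str:
        return (
            f"read {self.path} [{self.schema}]: {self.n_rows} rows, "
            f"{self.n_accepted} accepted, {self.n_rejected} rejected"
        )


@dataclass(frozen=True)
class TaxonEntry:
    canonical: str
    rank: str
    family: str


@dataclass
class TaxonomyMap:
    """Mapping from raw taxon names to canonical names with rank and family.

    Canonical names are required to be self-mapping, so harmonization is
    idempotent by construction.
    """

    entries: dict[str, TaxonEntry]

    def __post_init__(self) -> None:
        for raw, entry in list(self.entries.items()):
            if entry.rank not in _RANKS:
                raise ValueError(f"unknown rank {entry.rank!r} for {raw!r}")
            # canonical names must map to themselves
            if entry.canonical not in self.entries:
                self.entries[entry.canonical] = TaxonEntry(
                    entry.canonical, entry.rank, entry.family
                )

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def canonical(self, name: str) -> str:
        try:
            return self.entries[name].canonical
        except KeyError:
            raise HarmonizationError(f"unmapped taxon name: {name!r}") from None

    def family(self, name: str) -> str:
        return self.entries[self.canonical(name)].family

    def genus_of(self, name: str) -> str:
        """Genus-level name for ``name`` (first epithet of a species binomial)."""
        entry = self.entries[self.canonical(name)]
        if entry.rank == "species":
            return entry.canonical.split()[0]
        return entry.canonical

    def unmapped(self, names) -> list[str]:
        return sorted({n for n in names if n not in self.entries})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyMap":
        entries = {
            str(r.raw): TaxonEntry(str(r.canonical), str(r.rank), str(r.family))
            for r in df.itertuples()
        }
        return cls(entries)

    @classmethod
    def identity(cls, names, rank: str = "genus", family: str | None = None) -> "TaxonomyMap":
        """Self-mapping taxonomy for already-canonical name lists."""
        return cls({n: TaxonEntry(n, rank, family or n) for n in names})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"raw": raw, "canonical": e.canonical, "rank": e.rank, "family": e.family}
            for raw, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=SCHEMAS["taxonomy"])


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_records(path, schema: str, delimiter: str | None = None):
    """Read a delimited table of the given schema.

    Returns ``(table, report)``. Rows violating the schema's invariants
    (non-positive visit counts, missing dates, control trials carrying a
    taxon name) are dropped and listed in the report with their 1-based data
    row number; a cell that cannot be coerced at all raises :class:`ParseError`.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    delimiter = delimiter or _sniff_delimiter(str(path))
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    report = ParseReport(path=str(path), schema=schema, n_rows=len(df))
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    df = df[cols].copy()
    if df.empty:
        report.warnings.append(f"{path}: empty {schema} table")
        out = _empty_typed(schema)
        return out, report

    keep = np.ones(len(df), dtype=bool)

    def _reject(mask: np.ndarray, reason: str) -> None:
        for idx in np.nonzero(mask & keep)[0]:
            report.rejected.append((int(idx) + 1, reason))
        keep[mask] = False

    def _int_col(name: str) -> np.ndarray:
        raw = df[name].str.strip()
        ok = raw.str.fullmatch(r"[+-]?\d+")
        bad = np.nonzero(~ok.to_numpy())[0]
        if bad.size:
            raise ParseError(
                f"{path}: row {bad[0] + 1}: cannot parse {name}={raw.iloc[bad[0]]!r} as integer"
            )
        return raw.astype(np.int64).to_numpy()

    if schema in ("visits", "pollen"):
        dates = pd.to_datetime(df["date"].str.strip(), errors="coerce", format="ISO8601")
        _reject(dates.isna().to_numpy(), "missing or unparseable date")
        df["date"] = dates

    if schema == "visits":
        counts = _int_col("count")
        df["count"] = counts
        _reject(counts < 1, "count must be >= 1")
    elif schema == "pollen":
        grains = _int_col("grains")
        df["grains"] = grains
        _reject(grains < 0, "grains must be >= 0")
    elif schema == "svd":
        grains = _int_col("grains")
        df["grains"] = grains
        _reject(grains < 0, "grains must be >= 0")
        flags = df["is_control"].str.strip().str.lower()
        ok = flags.isin(["true", "false", "0", "1"])
        bad = np.nonzero(~ok.to_numpy())[0]
        if bad.size:
            raise ParseError(
                f"{path}: row {bad[0] + 1}: cannot parse is_control="
                f"{df['is_control'].iloc[bad[0]]!r} as boolean"
            )
        is_control = flags.isin(["true", "1"]).to_numpy()
        df["is_control"] = is_control
        has_taxon = (df["genus"].str.strip() != "") | (df["family"].str.strip() != "")
        _reject(is_control & has_taxon.to_numpy(), "control rows must not name a taxon")
    elif schema == "taxonomy":
        bad_rank = ~df["rank"].str.strip().isin(_RANKS)
        _reject(bad_rank.to_numpy(), f"rank must be one of {sorted(_RANKS)}")

    out = df.loc[keep].reset_index(drop=True)
    if schema == "pollen":
        dup = out.duplicated(subset=["individual", "plant_genus"], keep=False)
        if dup.any():
            pairs = out.loc[dup, ["individual", "plant_genus"]].drop_duplicates()
            raise ParseError(
                f"{path}: duplicate (individual, plant_genus) rows "
                f"(likely data corruption): {pairs.to_records(index=False).tolist()}"
            )
    report.n_accepted = len(out)
    return out, report


def _empty_typed(schema: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=SCHEMAS[schema])
    if schema in ("visits", "pollen"):
        df["date"] = pd.to_datetime(df["date"])
    for col in ("count", "grains"):
        if col in df.columns:
            df[col] = df[col].astype(np.int64)
    if schema == "svd":
        df["is_control"] = df["is_control"].astype(bool)
    return df


def write_records(df: pd.DataFrame, path, schema: str, delimiter: str = ",") -> None:
    """Write a table in one of the documented schemas (round-trips with
    :func:`read_records`)."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    out = df[SCHEMAS[schema]].copy()
    if "date" in out.columns and len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# season weeks

def assign_week(date, season_origin) -> int:
    """Season-week index of ``date`` relative to a fixed calendar origin.

    ``floor((date - season_origin) / 7 days)``; the same origin (by calendar
    date) is used for every year of a study so week indices align across
    years. Dates more than 366 days before the origin are refused.
    """
    date = _as_date(date)
    origin = _as_date(season_origin)
    delta = (date - origin).days
    if delta < -366:
        raise ValueError(f"date {date} precedes season origin {origin} by more than a year")
    return delta // 7


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


def season_week(dates: pd.Series, origin_month: int = 6, origin_day: int = 1) -> pd.Series:
    """Vectorized :func:`assign_week` using the same month/day origin in each
    observation's own year (default June 1)."""
    dates = pd.to_datetime(dates)
    origins = pd.to_datetime(
        {"year": dates.dt.year, "month": origin_month, "day": origin_day}
    )
    return ((dates - origins).dt.days // 7).astype(np.int64)


def visits_to_interactions(
    visits: pd.DataFrame, origin_month: int = 6, origin_day: int = 1
) -> pd.DataFrame:
    """Convert a parsed visits table to interaction records (evidence='visit')."""
    if visits.empty:
        return pd.DataFrame(columns=INTERACTION_COLUMNS)
    out = pd.DataFrame(
        {
            "plant_taxon": visits["plant"],
            "insect_taxon": visits["insect"],
            "year": pd.to_datetime(visits["date"]).dt.year.astype(np.int64),
            "week": season_week(visits["date"], origin_month, origin_day),
            "count": visits["count"].astype(np.int64),
            "evidence": "visit",
        }
    )
    return out


def pollen_assign_weeks(
    pollen: pd.DataFrame, origin_month: int = 6, origin_day: int = 1
) -> pd.DataFrame:
    """Attach capture year/week columns to a parsed pollen-load table.

    Pollen-inferred links are dated by the week the carrying insect was
    captured (pollen residence time on the body is assumed short).
    """
    out = pollen.copy()
    if out.empty:
        out["year"] = pd.Series(dtype=np.int64)
        out["week"] = pd.Series(dtype=np.int64)
        return out
    out["year"] = pd.to_datetime(out["date"]).dt.year.astype(np.int64)
    out["week"] = season_week(out["date"], origin_month, origin_day)
    return out


# ---------------------------------------------------------------------------
# harmonization

def harmonize(
    records: pd.DataFrame,
    taxmap: TaxonomyMap,
    exclude_insects: frozenset | set | tuple = (),
) -> pd.DataFrame:
    """Canonicalize taxon names in an interaction-record table and merge
    duplicates created by renaming.

    Visit records that become identical on (plant, insect, year, week,
    evidence) merge by summing counts; pollen-evidence records keep count 1
    (a pollen link is a presence, not a frequency). Non-insect visitors
    (e.g. spiders, mites) named in ``exclude_insects`` are dropped after
    canonicalization. Unmapped names raise, listing every offender.
    """
    if records.empty:
        return records.copy()
    unmapped = taxmap.unmapped(
        pd.concat([records["plant_taxon"], records["insect_taxon"]]).unique()
    )
    if unmapped:
        raise HarmonizationError(f"unmapped taxon names: {unmapped}")
    out = records.copy()
    canon = {raw: e.canonical for raw, e in taxmap.entries.items()}
    out["plant_taxon"] = out["plant_taxon"].map(canon)
    out["insect_taxon"] = out["insect_taxon"].map(canon)
    excluded = {canon.get(n, n) for n in exclude_insects}
    if excluded:
        out = out[~out["insect_taxon"].isin(excluded)]
    keys = ["plant_taxon", "insect_taxon", "year", "week", "evidence"]
    merged = out.groupby(keys, as_index=False, sort=True)["count"].sum()
    is_pollen = merged["evidence"] == "pollen"
    merged.loc[is_pollen, "count"] = 1
    return merged[INTERACTION_COLUMNS].reset_index(drop=True)
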