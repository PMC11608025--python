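"""Reading, validation and curation of species catalogs and annual catch tables.

The two inputs of every analysis are

* a **species catalog** — one row per taxon with its trophic level (TL) and
  migratory class (tuna / oceanic_migratory / seasonal_migratory /
  indigenous), mirroring the curated species lists compiled from national
  fisheries yearbooks and FishBase trophic estimates; and
* a **catch table** — long-format annual landings, one row per
  (year, sector, species), with the catch mass stored internally in tonnes.

Both are held as plain :class:`pandas.DataFrame` objects: the catalog indexed
by a normalized ``species_id`` (case-folded, whitespace-collapsed scientific
name or family tag), the catch table with columns
``year, sector, species_id, catch``.

Curation follows the conventions of catch-based indicator studies: taxa with
unreliable trophic assignments (anchovies and larval fish, squid, bivalves,
lobsters, crabs) are dropped via the catalog's ``excluded_taxon`` flag, and
the analysis is restricted to the top-N species by total landed mass pooled
over all years and both sectors (N = 100 by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: Recognised statistical sectors: artisanal fisheries within 12 nm
#: ("coastal") and industrial fisheries in the 12-200 nm EEZ band ("offshore").
SECTORS = ("coastal", "offshore")

#: The four migratory classes driving scenario membership.
MIGRATORY_CLASSES = ("tuna", "oceanic_migratory", "seasonal_migratory", "indigenous")

CATALOG_COLUMNS = (
    "species_id",
    "scientific_name",
    "family",
    "common_name",
    "trophic_level",
    "migratory_class",
    "excluded_taxon",
)

CATCH_COLUMNS = ("year", "sector", "species_id", "catch")

_WS = re.compile(r"\s+")


def normalize_species_id(name: str) -> str:
    """Normalize a scientific name or family tag into a catalog key:
    trimmed, internal whitespace collapsed, case-folded."""
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass
class CurationConfig:
    """Settings for the curation pass applied after validation.

    Parameters
    ----------
    top_n
        Number of species retained, ranked by total catch pooled over all
        years and both sectors. Default 100, the convention of the yearbook
        analyses this package reproduces.
    excluded_taxa
        Extra species_id / family tags to drop in addition to the catalog's
        ``excluded_taxon`` flags.
    input_unit
        Unit of the catch column in input files; yearbook extracts report kg.
    """

    top_n: int = 100
    excluded_taxa: tuple[str, ...] = ()
    input_unit: str = "kg"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")
        if self.input_unit not in ("kg", "tonnes"):
            raise ValueError(f"input_unit must be 'kg' or 'tonnes', got {self.input_unit!r}")


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().casefold()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise FormatError(f"cannot interpret {x!r} as a boolean excluded_taxon flag")


def catalog_from_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw catalog frame and return it indexed by species_id.

    Raises
    ------
    FormatError
        if a required column is missing.
    ValidationError
        on duplicate species_id, trophic level outside [1, 5], or an unknown
        migratory class.
    """
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"species catalog is missing required column(s): {missing}")

    out = df.loc[:, list(CATALOG_COLUMNS)].copy()
    out["species_id"] = out["species_id"].map(normalize_species_id)
    for col in ("scientific_name", "family", "common_name"):
        out[col] = out[col].astype(str).str.strip()

    out["trophic_level"] = pd.to_numeric(out["trophic_level"], errors="coerce")
    bad_tl = out[out["trophic_level"].isna()]
    if len(bad_tl):
        raise ValidationError(
            "malformed trophic_level for: " + ", ".join(bad_tl["species_id"])
        )
    outside = out[(out["trophic_level"] < 1.0) | (out["trophic_level"] > 5.0)]
    if len(outside):
        raise ValidationError(
            "trophic_level outside [1, 5] for: "
            + ", ".join(f"{r.species_id} ({r.trophic_level})" for r in outside.itertuples())
        )

    out["migratory_class"] = out["migratory_class"].astype(str).str.strip().str.casefold()
    unknown = out[~out["migratory_class"].isin(MIGRATORY_CLASSES)]
    if len(unknown):
        raise ValidationError(
            "unknown migratory_class for: "
            + ", ".join(f"{r.species_id} ({r.migratory_class})" for r in unknown.itertuples())
        )

    out["excluded_taxon"] = out["excluded_taxon"].map(_parse_bool)

    dupes = out["species_id"][out["species_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate species_id in catalog: {sorted(dupes)}")

    return out.set_index("species_id", drop=False)


def read_species_catalog(path) -> pd.DataFrame:
    """Read and validate a species catalog CSV (UTF-8, header required)."""
    df = pd.read_csv(path, dtype=str)
    return catalog_from_dataframe(df)


# ---------------------------------------------------------------------------
# catch table
# ---------------------------------------------------------------------------


def catch_from_dataframe(df: pd.DataFrame, unit: str = "kg") -> pd.DataFrame:
    """Validate a long-format catch frame; convert catch to tonnes.

    kg inputs are divided by 1000 on read; internal storage is always tonnes.
    """
    if unit not in ("kg", "tonnes"):
        raise ValueError(f"unit must be 'kg' or 'tonnes', got {unit!r}")
    missing = [c for c in CATCH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"catch table is missing required column(s): {missing}")

    out = df.loc[:, list(CATCH_COLUMNS)].copy()
    out["year"] = pd.to_numeric(out["year"], errors="coerce")
    if out["year"].isna().any():
        raise FormatError("non-numeric year in catch table")
    out["year"] = out["year"].astype(int)

    out["sector"] = out["sector"].astype(str).str.strip().str.casefold()
    bad = sorted(set(out["sector"]) - set(SECTORS))
    if bad:
        raise FormatError(f"unknown sector label(s): {bad}; expected one of {SECTORS}")

    out["species_id"] = out["species_id"].map(normalize_species_id)

    out["catch"] = pd.to_numeric(out["catch"], errors="coerce").astype(float)
    if out["catch"].isna().any():
        raise FormatError("non-numeric catch in catch table")
    if (out["catch"] < 0).any():
        neg = out[out["catch"] < 0]
        raise ValidationError(
            f"negative catch for {len(neg)} row(s), e.g. "
            f"{tuple(neg.iloc[0][['year', 'sector', 'species_id']])}"
        )
    if unit == "kg":
        out["catch"] = out["catch"] / 1000.0

    key = ["year", "sector", "species_id"]
    dup = out[out.duplicated(key, keep=False)]
    if len(dup):
        cells = dup[key].drop_duplicates().itertuples(index=False)
        raise ValidationError(
            "duplicate (year, sector, species) cell(s): "
            + "; ".join(str(tuple(c)) for c in cells)
        )
    return out.reset_index(drop=True)


def read_catch_table(path, unit: str = "kg") -> pd.DataFrame:
    """Read a long-format annual catch CSV and convert it to tonnes."""
    return catch_from_dataframe(pd.read_csv(path), unit=unit)


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------


def validate_against_catalog(
    table: pd.DataFrame, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop catch records whose species is absent from the catalog.

    Returns the filtered table and a report frame
    (``species_id, dropped_tonnes``) listing every unmatched name with the
    total mass removed. Mass is conserved: kept + reported dropped = input.
    """
    known = table["species_id"].isin(catalog.index)
    dropped = table[~known]
    report = (
        dropped.groupby("species_id")["catch"]
        .sum()
        .rename("dropped_tonnes")
        .reset_index()
        .sort_values("species_id", ignore_index=True)
    )
    return table[known].reset_index(drop=True), report


def apply_taxon_exclusions(
    table: pd.DataFrame, catalog: pd.DataFrame, config: CurationConfig | None = None
) -> pd.DataFrame:
    """Remove curation-excluded taxa (anchovy/larval-fish, squid, bivalves,
    lobsters, crabs — whatever the catalog flags) plus any extra tags in
    ``config.excluded_taxa``."""
    config = config or CurationConfig()
    flagged = set(catalog.index[catalog["excluded_taxon"]])
    flagged |= {normalize_species_id(s) for s in config.excluded_taxa}
    return table[~table["species_id"].isin(flagged)].reset_index(drop=True)


def select_top_species(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Keep the ``n`` species with the largest catch pooled over all years
    and both sectors; ties broken by ascending species_id. Idempotent."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    totals = table.groupby("species_id")["catch"].sum()
    ranked = totals.reset_index().sort_values(
        ["catch", "species_id"], ascending=[False, True]
    )
    keep = set(ranked["species_id"].head(n))
    return table[table["species_id"].isin(keep)].reset_index(drop=True)


def curate(
    table: pd.DataFrame, catalog: pd.DataFrame, config: CurationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full curation pass: catalog matching, taxon exclusions, top-N cut.

    Returns (curated table, dropped-species report)."""
    config = config or CurationConfig()
    matched, report = validate_against_catalog(table, catalog)
    cleaned = apply_taxon_exclusions(matched, catalog, config)
    return select_top_species(cleaned, config.top_n), report


# ---------------------------------------------------------------------------
# simple series
# ---------------------------------------------------------------------------


def total_catch_series(table: pd.DataFrame, sector: str) -> pd.Series:
    """Per-year total catch (tonnes) for one sector. Years with no records
    are omitted, not zero-filled."""
    if sector not in SECTORS:
        raise ValueError(f"unknown sector {sector!r}; expected one of {SECTORS}")
    sub = table[table["sector"] == sector]
    return sub.groupby("year")["catch"].sum().sort_index().rename(sector)


def sector_share_series(coastal: pd.Series, offshore: pd.Series) -> pd.DataFrame:
    """Annual percentage split of total catch between the two sectors.

    Returns a frame indexed by year with columns ``coastal_pct``,
    ``offshore_pct`` (summing to 100 wherever defined) and ``single_sector``
    flagging years present in only one input series. Years where both totals
    are zero get missing shares.
    """
    if len(coastal) == 0 and len(offshore) == 0:
        raise ValueError("at least one sector series must be non-empty")
    years = coastal.index.union(offshore.index)
    c = coastal.reindex(years)
    o = offshore.reindex(years)
    single = c.isna() | o.isna()
    c = c.fillna(0.0)
    o = o.fillna(0.0)
    tot = c + o
    with np.errstate(invalid="ignore", divide="ignore"):
        cp = np.where(tot > 0, 100.0 * c / tot, np.nan)
        op = np.where(tot > 0, 100.0 * o / tot, np.nan)
    return pd.DataFrame(
        {"coastal_pct": cp, "offshore_pct": op, "single_sector": single.to_numpy()},
        index=years,
    )
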