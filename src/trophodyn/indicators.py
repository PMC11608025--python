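"""Catch-based trophic indicators: MTL, FiB and per-species CTL.

For year *j* with landings ``Y_ij`` of species *i* (trophic level ``TL_i``):

* **Mean trophic level**  ``MTL_j = Σ_i TL_i·Y_ij / Σ_i Y_ij`` — the
  catch-weighted mean trophic level of the year's landings. A sustained
  decline is the classical fishing-down-the-food-web signal; a rise can
  indicate intensified targeting of high-TL stocks.

* **Fishing-in-Balance**  ``FiB_j = log10(Y_j·(1/TE)^MTL_j)
  − log10(Y_0·(1/TE)^MTL_0)`` with transfer efficiency TE = 0.10 and a fixed
  baseline year (1970 by default). FiB stays constant when a one-level MTL
  drop is energetically compensated by a ten-fold catch increase; negative
  values suggest catches below ecosystem-consistent expectations.

* **Contribution to trophic level**  ``CTL_i = TL_i·Y_ij / Σ_i TL_i·Y_ij
  × 100%`` — each species' share of the TL-weighted catch, used to single
  out the species driving MTL/FiB dynamics.

All three are invariant under a global rescaling of catches; the TL term in
FiB is the year's MTL of the (scenario-filtered) catch, so the index is
evaluable from annual totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .io import SECTORS

__all__ = [
    "IndicatorSeries",
    "FiBParams",
    "CTLTable",
    "compute_mtl",
    "compute_fib",
    "compute_ctl",
    "average_ctl",
    "rank_ctl",
    "catch_share_series",
]


@dataclass
class IndicatorSeries:
    """A year-indexed indicator for one sector × scenario slice."""

    indicator: str  # "MTL" or "FiB"
    sector: str
    scenario: str
    values: pd.Series  # index: year; NaN-free (missing years omitted)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FiBParams:
    """FiB settings: trophic transfer efficiency (conventionally 10%) and the
    baseline year pinned to zero. Logarithms are base 10."""

    transfer_efficiency: float = 0.10
    baseline_year: int = 1970

    def __post_init__(self) -> None:
        if not 0.0 < self.transfer_efficiency < 1.0:
            raise ConfigError(
                f"transfer_efficiency must be in (0, 1), got {self.transfer_efficiency}"
            )


@dataclass
class CTLTable:
    """Annual per-species CTL percentages (years × species). Rows sum to
    100% for every year with positive catch; zero-catch years are all-NaN."""

    annual: pd.DataFrame


def _sector_slice(table: pd.DataFrame, sector: str | None) -> pd.DataFrame:
    if sector is None:
        return table
    if sector not in SECTORS:
        raise ValueError(f"unknown sector {sector!r}; expected one of {SECTORS}")
    return table[table["sector"] == sector]


def _with_tl(table: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Attach each record's trophic level; error naming species without one."""
    tl = table["species_id"].map(catalog["trophic_level"])
    if tl.isna().any():
        missing = sorted(set(table.loc[tl.isna(), "species_id"]))
        raise ValidationError(f"species without a catalog trophic level: {missing}")
    out = table.copy()
    out["tl"] = tl.to_numpy()
    return out


def compute_mtl(
    table: pd.DataFrame,
    catalog: pd.DataFrame,
    sector: str,
    scenario: str = "scenario_all",
) -> IndicatorSeries:
    """Catch-weighted mean trophic level per year for one sector.

    Years with zero or absent catch are omitted (missing, not zero)."""
    sub = _with_tl(_sector_slice(table, sector), catalog)
    grouped = sub.groupby("year")
    tot = grouped["catch"].sum()
    weighted = grouped.apply(lambda g: (g["tl"] * g["catch"]).sum(), include_groups=False)
    mtl = (weighted[tot > 0] / tot[tot > 0]).sort_index()
    return IndicatorSeries("MTL", sector, scenario, mtl.rename("MTL"))


def compute_fib(
    table: pd.DataFrame,
    catalog: pd.DataFrame,
    sector: str,
    params: FiBParams | None = None,
    scenario: str = "scenario_all",
) -> IndicatorSeries:
    """Fishing-in-Balance index per year for one sector.

    Raises :class:`ConfigError` if the baseline year is absent or has zero
    catch; zero-catch evaluated years are omitted. The baseline year maps to
    exactly 0.
    """
    params = params or FiBParams()
    sub = _sector_slice(table, sector)
    tot = sub.groupby("year")["catch"].sum()
    tot = tot[tot > 0]
    if params.baseline_year not in tot.index:
        raise ConfigError(
            f"FiB baseline year {params.baseline_year} absent or zero-catch "
            f"for sector {sector!r}"
        )
    mtl = compute_mtl(table, catalog, sector, scenario).values
    inv_te = 1.0 / params.transfer_efficiency
    level = np.log10(tot) + mtl.loc[tot.index] * np.log10(inv_te)
    fib = (level - level.loc[params.baseline_year]).sort_index()
    fib.loc[params.baseline_year] = 0.0  # exact by definition
    return IndicatorSeries("FiB", sector, scenario, fib.rename("FiB"))


def compute_ctl(
    table: pd.DataFrame,
    catalog: pd.DataFrame,
    sector: str | None = None,
) -> CTLTable:
    """Annual per-species CTL percentages.

    ``sector=None`` pools coastal and offshore landings (the convention for
    period-average CTL tables); otherwise one sector is used. Species absent
    in a year contribute 0%; a year with zero TL-weighted catch is all-NaN.
    """
    sub = _with_tl(_sector_slice(table, sector), catalog)
    sub = sub.assign(product=sub["tl"] * sub["catch"])
    wide = (
        sub.pivot_table(index="year", columns="species_id", values="product", aggfunc="sum")
        .fillna(0.0)
        .sort_index()
    )
    denom = wide.sum(axis=1)
    annual = wide.div(denom.where(denom > 0), axis=0) * 100.0
    return CTLTable(annual=annual)


def average_ctl(
    ctl: CTLTable,
    year_range: tuple[int, int] | None = None,
    absent_as_zero: bool = True,
) -> pd.Series:
    """Period-average CTL per species over an inclusive year range.

    Absence years count as 0% by default (``absent_as_zero=False`` averages
    over presence years only). Zero-catch (all-NaN) years are dropped.
    """
    annual = ctl.annual
    if year_range is None:
        year_range = (int(annual.index.min()), int(annual.index.max()))
    lo, hi = year_range
    if lo > hi:
        raise ValueError(f"empty year range {year_range}")
    if lo < annual.index.min() or hi > annual.index.max():
        raise ValueError(
            f"year range {year_range} outside available years "
            f"[{annual.index.min()}, {annual.index.max()}]"
        )
    window = annual.loc[lo:hi].dropna(how="all")
    if absent_as_zero:
        return window.mean(axis=0).rename("avg_ctl_percent")
    masked = window.where(window > 0)
    return masked.mean(axis=0).fillna(0.0).rename("avg_ctl_percent")


def rank_ctl(averages: pd.Series, top_k: int) -> pd.DataFrame:
    """Top-k species by period-average CTL, descending, ties alphabetical.

    Returns a frame with columns ``avg_ctl_percent`` and the running
    ``cumulative_percent``."""
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if len(averages) == 0:
        raise ValueError("averages must be non-empty")
    df = averages.rename("avg_ctl_percent").reset_index()
    df.columns = ["species_id", "avg_ctl_percent"]
    df = df.sort_values(
        ["avg_ctl_percent", "species_id"], ascending=[False, True], ignore_index=True
    ).head(top_k)
    df["cumulative_percent"] = df["avg_ctl_percent"].cumsum()
    return df.set_index("species_id")


def catch_share_series(
    table: pd.DataFrame,
    sector: str,
    species_subset=None,
) -> pd.DataFrame:
    """Annual catch share (%) of each species in the (scenario-filtered)
    sector total. Columns restricted to ``species_subset`` when given; the
    denominator is always the full filtered annual total. Zero-catch years
    are missing."""
    sub = _sector_slice(table, sector)
    wide = (
        sub.pivot_table(index="year", columns="species_id", values="catch", aggfunc="sum")
        .fillna(0.0)
        .sort_index()
    )
    denom = wide.sum(axis=1)
    shares = wide.div(denom.where(denom > 0), axis=0) * 100.0
    if species_subset is not None:
        missing = [s for s in species_subset if s not in shares.columns]
        if missing:
            raise ValueError(f"species not in the filtered table: {missing}")
        shares = shares.loc[:, list(species_subset)]
    return shares
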