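"""Cumulative species-exclusion scenarios.

Four scenarios progressively strip migratory assemblages from the landings:

* ``scenario_all`` — every curated species;
* ``scenario_1``  — minus the five tuna taxa (highly migratory, high value);
* ``scenario_2``  — additionally minus oceanic migratory species (billfish,
  pelagic sharks, dolphinfish, flying fish, saury, sunfish);
* ``scenario_3``  — additionally minus seasonally migratory species, leaving
  the indigenous assemblage of Taiwan's shelf waters.

Exclusion sets are cumulative by construction (scenario_1 ⊂ scenario_2 ⊂
scenario_3). The packaged species lists are the operational definition; the
catalog's ``migratory_class`` column acts as a cross-check, and a mismatch
triggers a warning with the list winning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .exceptions import ValidationError
from .io import SECTORS, normalize_species_id

SCENARIO_NAMES = ("scenario_all", "scenario_1", "scenario_2", "scenario_3")


@dataclass(frozen=True)
class ScenarioDefinition:
    """A named exclusion rule set: migratory classes and/or explicit species."""

    name: str
    excluded_classes: tuple[str, ...] = ()
    extra_excluded_species: tuple[str, ...] = ()


@dataclass
class ScenarioResult:
    """Outcome of resolving one scenario against a catch table."""

    name: str
    retained_species: frozenset
    #: period-pooled retained catch as % of the unfiltered table, per sector
    retained_fraction_by_sector: dict


def builtin_scenarios() -> dict[str, ScenarioDefinition]:
    """The four packaged scenario definitions, keyed by name."""
    text = resources.files("trophodyn").joinpath("data/scenarios.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name in SCENARIO_NAMES:
        spec = raw[name]
        out[name] = ScenarioDefinition(
            name=name,
            excluded_classes=tuple(spec["excluded_classes"]),
            extra_excluded_species=tuple(
                normalize_species_id(s) for s in spec["excluded_species"]
            ),
        )
    return out


def _excluded_ids(defn: ScenarioDefinition, catalog: pd.DataFrame) -> set:
    by_class = set(
        catalog.index[catalog["migratory_class"].isin(defn.excluded_classes)]
    )
    explicit = {normalize_species_id(s) for s in defn.extra_excluded_species}
    # cross-check: a listed species present in the catalog under a class the
    # scenario does not exclude is suspicious; the explicit list wins.
    if defn.excluded_classes:
        mismatched = [
            s
            for s in explicit & set(catalog.index)
            if catalog.loc[s, "migratory_class"] not in defn.excluded_classes
        ]
        if mismatched:
            warnings.warn(
                f"{defn.name}: explicitly excluded species with a non-excluded "
                f"migratory_class (list wins): {sorted(mismatched)}",
                stacklevel=2,
            )
    return by_class | explicit


def resolve_scenario(
    defn: ScenarioDefinition, catalog: pd.DataFrame, table: pd.DataFrame
) -> tuple[ScenarioResult, pd.DataFrame]:
    """Apply one scenario to a curated catch table.

    Removes records matching an excluded class OR an explicitly listed
    species, and reports the retained catch percentage per sector relative to
    the unfiltered input, pooled over the whole period.
    """
    excluded = _excluded_ids(defn, catalog)
    filtered = table[~table["species_id"].isin(excluded)].reset_index(drop=True)

    retained_ids = set(filtered["species_id"])
    no_class = [
        s for s in retained_ids
        if s in catalog.index and pd.isna(catalog.loc[s, "migratory_class"])
    ]
    if no_class:
        raise ValidationError(f"retained species without migratory_class: {sorted(no_class)}")

    fractions = {}
    for sector in SECTORS:
        base_mass = table.loc[table["sector"] == sector, "catch"].sum()
        if base_mass > 0:
            fractions[sector] = retained_fraction(filtered, table, sector)
    return (
        ScenarioResult(
            name=defn.name,
            retained_species=frozenset(retained_ids),
            retained_fraction_by_sector=fractions,
        ),
        filtered,
    )


def retained_fraction(
    filtered: pd.DataFrame, baseline: pd.DataFrame, sector: str
) -> float:
    """Period-pooled retained catch, % of baseline mass, for one sector."""
    if sector not in SECTORS:
        raise ValueError(f"unknown sector {sector!r}; expected one of {SECTORS}")
    base = baseline.loc[baseline["sector"] == sector, "catch"].sum()
    if base <= 0:
        raise ValidationError(f"baseline mass is zero for sector {sector!r}")
    kept = filtered.loc[filtered["sector"] == sector, "catch"].sum()
    return 100.0 * kept / base
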