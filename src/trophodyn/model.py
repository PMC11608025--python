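"""Model/results interface over the full indicator pipeline.

:class:`TrophicDynamics` bundles a catch table, a species catalog and the
analysis settings (curation, scenarios, FiB parameters, trend window);
``fit()`` runs curation → scenario resolution → MTL/FiB → per-decade trends
→ CTL ranking and returns a :class:`TrophicDynamicsResults` carrying every
table an indicator study reports: retained catch percentages per scenario,
year-indexed MTL and FiB series per scenario × sector, the OLS trend summary
(per-decade change, R², p), and period-average CTL rankings.

Typical use::

    model = TrophicDynamics.from_csv("catch.csv", "catalog.csv", unit="kg")
    res = model.fit()
    print(res.summary())
    res.save("out/")
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from . import io as tio
from .exceptions import ConfigError
from .indicators import (
    FiBParams,
    IndicatorSeries,
    average_ctl,
    compute_ctl,
    compute_fib,
    compute_mtl,
    rank_ctl,
)
from .io import SECTORS, CurationConfig
from .scenarios import SCENARIO_NAMES, builtin_scenarios, resolve_scenario
from .trends import summarize_trends


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class TrophicDynamics:
    """Catch-based trophic-indicator model for one fishery system.

    Parameters
    ----------
    catch, catalog
        Validated frames as produced by :mod:`trophodyn.io`.
    curation
        Top-N cut and taxon exclusions applied before any scenario.
    scenarios
        Mapping name -> ScenarioDefinition; defaults to the four packaged
        cumulative scenarios.
    fib_params
        Transfer efficiency and baseline year for FiB.
    sectors
        Sectors to analyse (default coastal + offshore).
    trend_window
        Optional inclusive (first, last) year restriction for trend fits.
    ctl_scenarios, ctl_top_k
        Scenarios for which pooled-sector CTL rankings are produced.
    """

    def __init__(
        self,
        catch: pd.DataFrame,
        catalog: pd.DataFrame,
        *,
        curation: CurationConfig | None = None,
        scenarios: dict | None = None,
        fib_params: FiBParams | None = None,
        sectors: tuple[str, ...] = SECTORS,
        trend_window: tuple[int, int] | None = None,
        ctl_scenarios: tuple[str, ...] = ("scenario_2", "scenario_3"),
        ctl_top_k: int = 6,
    ) -> None:
        self.catch = catch
        self.catalog = catalog
        self.curation = curation or CurationConfig()
        self.scenarios = scenarios or builtin_scenarios()
        self.fib_params = fib_params or FiBParams()
        self.sectors = tuple(sectors)
        self.trend_window = trend_window
        self.ctl_scenarios = tuple(ctl_scenarios)
        self.ctl_top_k = ctl_top_k
        self.source_paths: dict = {}

        unknown = set(self.ctl_scenarios) - set(self.scenarios)
        if unknown:
            raise ConfigError(f"ctl_scenarios not among scenarios: {sorted(unknown)}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(cls, catch_path, catalog_path, unit: str = "kg", **kwargs):
        """Build a model from a catch CSV and a catalog CSV."""
        catalog = tio.read_species_catalog(catalog_path)
        catch = tio.read_catch_table(catch_path, unit=unit)
        model = cls(catch, catalog, **kwargs)
        model.source_paths = {
            "catch": str(catch_path),
            "catalog": str(catalog_path),
            "unit": unit,
        }
        return model

    @classmethod
    def from_dataframes(cls, catch_df, catalog_df, unit: str = "tonnes", **kwargs):
        """Build a model from raw in-memory frames (validated on the way in)."""
        return cls(
            tio.catch_from_dataframe(catch_df, unit=unit),
            tio.catalog_from_dataframe(catalog_df),
            **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "TrophicDynamicsResults":
        curated, dropped = tio.curate(self.catch, self.catalog, self.curation)

        retained_rows = []
        scenario_tables = {}
        series: list[IndicatorSeries] = []
        for name in self.scenarios:
            result, filtered = resolve_scenario(self.scenarios[name], self.catalog, curated)
            scenario_tables[name] = filtered
            for sector in self.sectors:
                frac = result.retained_fraction_by_sector.get(sector)
                retained_rows.append(
                    {"scenario": name, "sector": sector, "retained_percent": frac}
                )
                series.append(compute_mtl(filtered, self.catalog, sector, scenario=name))
                series.append(
                    compute_fib(filtered, self.catalog, sector, self.fib_params, scenario=name)
                )

        if self.trend_window is not None:
            lo, hi = self.trend_window
            windowed = [
                IndicatorSeries(s.indicator, s.sector, s.scenario, s.values.loc[lo:hi])
                for s in series
            ]
        else:
            windowed = series
        trend_table = summarize_trends(windowed)

        ctl_averages = {}
        ctl_rankings = {}
        for name in self.ctl_scenarios:
            ctl = compute_ctl(scenario_tables[name], self.catalog, sector=None)
            avg = average_ctl(ctl)
            ctl_averages[name] = avg
            ctl_rankings[name] = rank_ctl(avg, self.ctl_top_k)

        return TrophicDynamicsResults(
            model=self,
            curated=curated,
            dropped_report=dropped,
            retained=pd.DataFrame(retained_rows),
            series=series,
            trend_table=trend_table,
            ctl_averages=ctl_averages,
            ctl_rankings=ctl_rankings,
        )


@dataclass
class TrophicDynamicsResults:
    """Fitted pipeline outputs; see :meth:`summary` for the headline view."""

    model: TrophicDynamics
    curated: pd.DataFrame
    dropped_report: pd.DataFrame
    retained: pd.DataFrame  # scenario × sector retained %
    series: list  # IndicatorSeries for every scenario × sector × indicator
    trend_table: pd.DataFrame
    ctl_averages: dict  # scenario -> Series
    ctl_rankings: dict  # scenario -> DataFrame

    def get_series(self, indicator: str, scenario: str, sector: str) -> IndicatorSeries:
        for s in self.series:
            if (s.indicator, s.scenario, s.sector) == (indicator, scenario, sector):
                return s
        raise KeyError(f"no series ({indicator}, {scenario}, {sector})")

    def series_frame(self) -> pd.DataFrame:
        """All indicator series as one long frame."""
        frames = []
        for s in self.series:
            df = s.values.rename("value").reset_index()
            df.columns = ["year", "value"]
            df.insert(0, "indicator", s.indicator)
            df.insert(1, "scenario", s.scenario)
            df.insert(2, "sector", s.sector)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Plain-text report: retained catch, trend table, CTL leaders.

        Indicator statistics are displayed at 2 decimals; underlying values
        stay full precision.
        """
        lines = ["Trophic dynamics results", "=" * 60]
        lines.append("\nRetained catch per scenario (% of curated mass, period-pooled):")
        ret = self.retained.pivot(index="scenario", columns="sector", values="retained_percent")
        ret = ret.reindex([n for n in SCENARIO_NAMES if n in ret.index])
        lines.append(ret.round(1).to_string())

        lines.append("\nLinear trends (per-decade change, R², p):")
        tt = self.trend_table.copy()
        for col in ("per_decade_change", "r_squared"):
            tt[col] = tt[col].round(2)
        lines.append(
            tt[
                ["indicator", "scenario", "sector", "per_decade_change", "r_squared", "p_display"]
            ].to_string(index=False)
        )

        for name, ranking in self.ctl_rankings.items():
            lines.append(f"\nTop CTL species, {name} (sectors pooled, period average %):")
            lines.append(ranking.round(2).to_string())
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def manifest(self) -> dict:
        m = self.model
        manifest = {
            "package": "trophodyn",
            "parameters": {
                "top_n": m.curation.top_n,
                "excluded_taxa": list(m.curation.excluded_taxa),
                "input_unit": m.curation.input_unit,
                "transfer_efficiency": m.fib_params.transfer_efficiency,
                "baseline_year": m.fib_params.baseline_year,
                "sectors": list(m.sectors),
                "scenarios": list(m.scenarios),
                "trend_window": list(m.trend_window) if m.trend_window else None,
                "ctl_scenarios": list(m.ctl_scenarios),
                "ctl_top_k": m.ctl_top_k,
            },
            "inputs": dict(m.source_paths),
        }
        for key in ("catch", "catalog"):
            path = m.source_paths.get(key)
            if path:
                try:
                    manifest["inputs"][f"{key}_sha256"] = _sha256(path)
                except OSError:
                    pass
        return manifest

    def save(self, outdir) -> None:
        """Write all output tables plus a run manifest to ``outdir``.

        Everything is computed before the first byte is written, so a failed
        fit never leaves partial outputs behind.
        """
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.retained.to_csv(out / "retained_fractions.csv", index=False)
        self.series_frame().to_csv(out / "indicator_series.csv", index=False)
        self.trend_table.to_csv(out / "trend_summary.csv", index=False)
        self.dropped_report.to_csv(out / "dropped_species.csv", index=False)
        for name, avg in self.ctl_averages.items():
            tldf = avg.rename("avg_ctl_percent").reset_index()
            tldf.columns = ["species_id", "avg_ctl_percent"]
            tldf["tl"] = tldf["species_id"].map(self.model.catalog["trophic_level"])
            tldf.to_csv(out / f"ctl_averages_{name}.csv", index=False)
            self.ctl_rankings[name].to_csv(out / f"ctl_ranking_{name}.csv")
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=2, sort_keys=True))
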