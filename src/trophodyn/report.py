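"""End-to-end pipeline orchestration and external-series comparison.

`run_pipeline` drives the whole analysis from a structured config (YAML or
dict): read and validate inputs, curate, resolve scenarios, compute MTL/FiB
and trends, rank CTL, and write the output tables plus a manifest that
suffices to reproduce the run. `compare_series` scores one of our indicator
series against an externally produced year/value series (e.g. a Sea Around
Us export read from a two-column CSV) on the year intersection only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, InsufficientDataError
from .indicators import FiBParams, IndicatorSeries
from .io import SECTORS, CurationConfig
from .model import TrophicDynamics, TrophicDynamicsResults


@dataclass
class RunConfig:
    """Declarative settings for one pipeline run."""

    catch_path: str
    catalog_path: str
    out_dir: str
    unit: str = "kg"
    top_n: int = 100
    excluded_taxa: tuple[str, ...] = ()
    transfer_efficiency: float = 0.10
    baseline_year: int = 1970
    sectors: tuple[str, ...] = SECTORS
    trend_window: tuple[int, int] | None = None
    ctl_scenarios: tuple[str, ...] = ("scenario_2", "scenario_3")
    ctl_top_k: int = 6

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"run config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run-config key(s): {sorted(unknown)}")
        for key in ("excluded_taxa", "sectors", "ctl_scenarios", "trend_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> TrophicDynamicsResults:
    """Run the full analysis described by ``config`` and write its outputs."""
    for label, p in (("catch", config.catch_path), ("catalog", config.catalog_path)):
        if not Path(p).exists():
            raise ConfigError(f"{label} file does not exist: {p}")
    model = TrophicDynamics.from_csv(
        config.catch_path,
        config.catalog_path,
        unit=config.unit,
        curation=CurationConfig(
            top_n=config.top_n,
            excluded_taxa=tuple(config.excluded_taxa),
            input_unit=config.unit,
        ),
        fib_params=FiBParams(
            transfer_efficiency=config.transfer_efficiency,
            baseline_year=config.baseline_year,
        ),
        sectors=tuple(config.sectors),
        trend_window=config.trend_window,
        ctl_scenarios=tuple(config.ctl_scenarios),
        ctl_top_k=config.ctl_top_k,
    )
    results = model.fit()
    results.save(config.out_dir)
    return results


@dataclass(frozen=True)
class SeriesComparison:
    """Overlap statistics between two year-indexed series."""

    n_common_years: int
    mean_difference: float  # mean(a - b) over common years
    correlation: float  # Pearson r over common years


def compare_series(a, b) -> SeriesComparison:
    """Compare an indicator series with an external year/value series.

    Statistics use the year intersection only — no interpolation. Requires
    at least three common years.
    """
    sa = a.values if isinstance(a, IndicatorSeries) else a
    sb = b.values if isinstance(b, IndicatorSeries) else b
    common = sa.dropna().index.intersection(sb.dropna().index)
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >= 3 common years to compare, got {len(common)}"
        )
    x = sa.loc[common].to_numpy(dtype=float)
    y = sb.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        corr = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else float("nan")
    else:
        corr = float(np.corrcoef(x, y)[0, 1])
    return SeriesComparison(
        n_common_years=len(common),
        mean_difference=float(np.mean(x - y)),
        correlation=corr,
    )


def read_external_series(path) -> pd.Series:
    """Read a two-column (year, value) CSV into a year-indexed series."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ConfigError(f"external series {path} needs two columns (year, value)")
    years = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if years.isna().any():
        raise ConfigError(f"non-numeric year in external series {path}")
    return pd.Series(values.to_numpy(), index=years.astype(int).to_numpy()).sort_index()
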