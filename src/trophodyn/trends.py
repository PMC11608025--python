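"""Linear trends of indicator series, summarised per decade.

Each indicator series (MTL or FiB vs calendar year) is fitted by ordinary
least squares; the headline statistic is the per-decade change (10 × slope)
together with R² and the two-sided t-test p-value of the slope (n − 2 df).
Missing years are skipped, never interpolated. No autocorrelation correction
is applied — the numbers are plain linear-trend summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .indicators import IndicatorSeries

__all__ = ["TrendResult", "fit_linear_trend", "summarize_trends", "format_p"]


@dataclass(frozen=True)
class TrendResult:
    """OLS summary of one indicator series (units: indicator per year)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_years: int

    @property
    def per_decade_change(self) -> float:
        return 10.0 * self.slope


def fit_linear_trend(series) -> TrendResult:
    """OLS of indicator value on calendar year.

    Accepts an :class:`IndicatorSeries` or a year-indexed pandas Series.
    Requires >= 3 non-missing points and non-constant years. A constant-value
    series gets slope 0, R² 0 and p 1 (the zero-SS_tot convention).
    """
    values = series.values if isinstance(series, IndicatorSeries) else series
    clean = values.dropna()
    if len(clean) < 3:
        raise InsufficientDataError(
            f"trend fit needs >= 3 year/value pairs, got {len(clean)}"
        )
    x = clean.index.to_numpy(dtype=float)
    y = clean.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InsufficientDataError("all observations share one year; slope undefined")
    if np.ptp(y) == 0:
        return TrendResult(0.0, float(y[0]), 0.0, 1.0, len(y))
    fit = stats.linregress(x, y)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n_years=len(y),
    )


def format_p(p: float) -> str:
    """Display convention for trend p-values: below 0.01 prints '<0.01'."""
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def summarize_trends(series_list: list[IndicatorSeries]) -> pd.DataFrame:
    """Fit every series and tabulate one row per (indicator, scenario,
    sector) with per-decade change, R², p and its display form."""
    rows = []
    for s in series_list:
        fit = fit_linear_trend(s)
        rows.append(
            {
                "indicator": s.indicator,
                "scenario": s.scenario,
                "sector": s.sector,
                "per_decade_change": fit.per_decade_change,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "p_display": format_p(fit.p_value),
                "n_years": fit.n_years,
            }
        )
    return pd.DataFrame(rows)
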