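"""Time-lag / time-series design-matrix construction.

The feature matrix for a target day *t* combines:

* every weather variable at offsets ``0 .. ts_window−1`` days before *t*
  (the event may depend on a window of adjacent days, not a single one);
* soil moisture at each modelled depth *d* at offsets
  ``lag(d) .. lag(d)+ts_window−1`` — strictly past values, shifted by the
  percolation delay found by the lag analysis;
* response: irrigation water input (mm) on day *t*.

Column names are self-describing: ``t_mean_d1`` is the daily mean temperature
one day before the target day; ``sm30_lag1_d0`` is the 30 cm moisture at its
base lag of 1 day (the trailing ``_d{k}`` counts extra days of the window on
top of the base lag).  Calendar days whose lagged columns would reach before
the series start are dropped, as is any row with a missing cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import WEATHER_COLUMNS
from .lags import LagSpec

__all__ = ["TLTSDesign", "FeatureMatrix", "build_tlts_matrix", "DEFAULT_DESIGN"]


@dataclass(frozen=True)
class TLTSDesign:
    """Recipe for turning a daily table into a lagged feature matrix."""

    weather_vars: tuple[str, ...] = tuple(WEATHER_COLUMNS)
    soil_lags: LagSpec = field(default_factory=lambda: LagSpec({30: 1, 60: 2, 90: 2}))
    ts_window: int = 2
    response: str = "irrigation_mm"

    def __post_init__(self) -> None:
        if self.ts_window < 1:
            raise ValueError(f"ts_window must be >= 1, got {self.ts_window}")

    @property
    def max_total_lag(self) -> int:
        """Deepest look-back any column needs (days before the target day)."""
        soil = max(
            (lag + self.ts_window - 1 for lag in self.soil_lags.lags.values()),
            default=0,
        )
        return max(self.ts_window - 1, soil)

    def column_names(self) -> list[str]:
        cols = [f"{v}_d{o}" for v in self.weather_vars for o in range(self.ts_window)]
        cols += [
            f"sm{d}_lag{lag}_d{o}"
            for d, lag in sorted(self.soil_lags.lags.items())
            for o in range(self.ts_window)
        ]
        return cols


@dataclass(frozen=True)
class FeatureMatrix:
    """Design matrix with aligned response and row dates."""

    X: pd.DataFrame       # rows = usable days, named lagged columns
    y: pd.Series          # response (raw units, mm/day)
    dates: pd.DatetimeIndex

    @property
    def n_rows(self) -> int:
        return len(self.X)


def build_tlts_matrix(daily: pd.DataFrame, design: TLTSDesign) -> FeatureMatrix:
    """Assemble the lagged/windowed feature matrix from a daily table.

    Raises if no complete row survives (series too short or too sparse).
    """
    missing = [v for v in design.weather_vars if v not in daily.columns]
    missing += [
        f"sm{d}" for d in design.soil_lags.lags if f"sm{d}" not in daily.columns
    ]
    if design.response not in daily.columns:
        missing.append(design.response)
    if missing:
        raise ValueError(f"daily series lacks column(s): {missing}")

    pieces: dict[str, pd.Series] = {}
    for v in design.weather_vars:
        for o in range(design.ts_window):
            pieces[f"{v}_d{o}"] = daily[v].shift(o)
    for d, lag in sorted(design.soil_lags.lags.items()):
        for o in range(design.ts_window):
            pieces[f"sm{d}_lag{lag}_d{o}"] = daily[f"sm{d}"].shift(lag + o)
    X = pd.DataFrame(pieces, index=daily.index)
    y = daily[design.response]

    # drop the warm-up rows, then any row with a missing predictor or response
    X = X.iloc[design.max_total_lag :]
    y = y.iloc[design.max_total_lag :]
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    if X.empty:
        raise ValueError("no usable rows after lagging and missing-data removal")
    return FeatureMatrix(X=X, y=y, dates=pd.DatetimeIndex(X.index))


#: the final published configuration: moisture at 30 cm lagged 1 day, 60 and
#: 90 cm lagged 2 days, a 2-day time-series window, weather at lag 0.
DEFAULT_DESIGN = TLTSDesign()
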