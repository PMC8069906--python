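"""Application phase: daily irrigation forecasting and savings accounting.

At prediction time the model answers "how much water does the profile need to
sit at its optimum?" by the **field-capacity substitution**: the feature row
is built exactly as in training, except every soil-moisture column is
replaced by the field capacity of its depth.  Weather columns at future
offsets come from a forecast table, at past offsets from observed records.
Forecasts are produced for horizons T0 (interrogation day) through T3, raw
model output is clipped at zero, and the system retrains adaptively as new
daily records accumulate.

Savings are judged against the conventional fixed schedule (one dose per
day, rainy days excluded) in both water depth and pumping energy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TLTSDesign
from .model import IrrigationPLS, IrrigationPLSResults, PipelineMetrics
from .soil import ConversionConstants, SoilProfile, DEFAULT_CONSTANTS, mm_to_kwh

__all__ = [
    "ForecastInput",
    "IrrigationForecast",
    "predict_irrigation",
    "ConventionalSchedule",
    "conventional_irrigation",
    "SavingsReport",
    "savings_report",
    "recommend_series",
    "AdaptiveState",
    "adaptive_update",
]

DEFAULT_HORIZONS = (0, 1, 2, 3)


@dataclass(frozen=True)
class ForecastInput:
    """Inputs for one interrogation of the model.

    ``forecast`` is a weather table indexed by ``offset_days`` (0 = the
    interrogation day itself) with the same weather columns used in training;
    ``recent`` holds observed daily records covering any lagged weather
    column still anchored in the past.
    """

    date: pd.Timestamp
    forecast: pd.DataFrame
    recent: pd.DataFrame

    def weather_at(self, day_offset: int, var: str, use_observed_t0: bool = False) -> float:
        """Weather value ``day_offset`` days from the interrogation date."""
        date = pd.Timestamp(self.date) + pd.Timedelta(days=day_offset)
        if day_offset < 0 or (day_offset == 0 and use_observed_t0
                              and date in self.recent.index):
            if date not in self.recent.index:
                raise ValueError(f"no observed record for {date.date()} ({var})")
            return float(self.recent.loc[date, var])
        if day_offset not in self.forecast.index:
            raise ValueError(f"missing forecast row for offset {day_offset}")
        return float(self.forecast.loc[day_offset, var])


@dataclass(frozen=True)
class IrrigationForecast:
    """Recommended irrigation per horizon, with the unclipped model output."""

    date: pd.Timestamp
    table: pd.DataFrame     # index offset, columns raw_mm / recommended_mm
    inputs_hash: str

    @property
    def recommended(self) -> pd.Series:
        return self.table["recommended_mm"]


def _hash_inputs(finput: ForecastInput, horizons) -> str:
    payload = json.dumps(
        {
            "date": str(pd.Timestamp(finput.date).date()),
            "horizons": list(horizons),
            "forecast": finput.forecast.round(9).to_csv(),
            "recent": finput.recent.round(9).to_csv(),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def predict_irrigation(
    results: IrrigationPLSResults,
    profile: SoilProfile,
    finput: ForecastInput,
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    use_observed_t0: bool = False,
) -> IrrigationForecast:
    """Forecast irrigation needs at each horizon by field-capacity substitution.

    For horizon ``h`` the feature row mirrors a training row for day
    ``date + h``: each weather variable at window offset ``o`` is taken at
    day ``h − o`` (forecast table for today/future days, observed records for
    past days), while every soil-moisture column takes the field capacity of
    its depth.  The raw prediction is back-transformed to mm and clipped at 0.
    """
    design: TLTSDesign = results.design
    fc = profile.fc_by_depth()
    for depth in design.soil_lags.lags:
        if depth not in fc:
            raise ValueError(f"profile has no field capacity for {depth} cm")

    rows = []
    for h in horizons:
        row = {}
        for col in results.columns:
            if col.startswith("sm"):
                depth = int(col.split("_")[0][2:])
                row[col] = fc[depth]
            else:
                var, o = col.rsplit("_d", 1)
                row[col] = finput.weather_at(h - int(o), var, use_observed_t0)
        rows.append(row)
    X = pd.DataFrame(rows, index=pd.Index(list(horizons), name="offset"))
    raw = results.predict_rows(X)
    table = pd.DataFrame(
        {"raw_mm": raw, "recommended_mm": np.maximum(raw, 0.0)}, index=X.index
    )
    return IrrigationForecast(
        date=pd.Timestamp(finput.date),
        table=table,
        inputs_hash=_hash_inputs(finput, horizons),
    )


def recommend_series(
    results: IrrigationPLSResults,
    profile: SoilProfile,
    daily: pd.DataFrame,
) -> pd.Series:
    """Apply the model a posteriori over a whole observed season.

    For every usable day the feature row is built exactly as in training from
    the observed weather, with every soil-moisture column replaced by the
    field capacity of its depth; predictions are clipped at zero.  This is
    the daily recommendation the system would have issued, and the series
    compared against the conventional schedule in savings accounting.
    """
    from .design import build_tlts_matrix

    fm = build_tlts_matrix(daily, results.design)
    X = fm.X.copy()
    fc = profile.fc_by_depth()
    for col in X.columns:
        if col.startswith("sm"):
            X[col] = fc[int(col.split("_")[0][2:])]
    raw = results.predict_rows(X)
    return pd.Series(np.maximum(raw, 0.0), index=fm.dates, name="recommended_mm")


# ---------------------------------------------------------------------------
# conventional baseline and savings

@dataclass(frozen=True)
class ConventionalSchedule:
    """Fixed daily practice: one dose every day, rainy days excluded."""

    constants: ConversionConstants = DEFAULT_CONSTANTS
    rainy_day_threshold_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.rainy_day_threshold_mm < 0:
            raise ValueError("rainy-day threshold must be non-negative")


def conventional_irrigation(
    rain: pd.Series,
    schedule: ConventionalSchedule = ConventionalSchedule(),
) -> pd.Series:
    """Daily mm applied under the fixed schedule for a given rain series."""
    dose = schedule.constants.dose_mm
    out = pd.Series(
        np.where(rain.to_numpy() > schedule.rainy_day_threshold_mm, 0.0, dose),
        index=rain.index,
        name="conventional_mm",
    )
    return out


@dataclass(frozen=True)
class SavingsReport:
    """Water and energy comparison of proposed vs conventional irrigation."""

    start: pd.Timestamp
    end: pd.Timestamp
    conventional_total_mm: float
    proposed_total_mm: float
    saving_mm: float
    conventional_kwh: float
    proposed_kwh: float
    saving_kwh: float
    saving_percent: float   # NaN when the conventional total is zero

    def frame(self) -> pd.DataFrame:
        d = {
            "start": str(pd.Timestamp(self.start).date()),
            "end": str(pd.Timestamp(self.end).date()),
            "conventional_total_mm": self.conventional_total_mm,
            "proposed_total_mm": self.proposed_total_mm,
            "saving_mm": self.saving_mm,
            "conventional_kwh": self.conventional_kwh,
            "proposed_kwh": self.proposed_kwh,
            "saving_kwh": self.saving_kwh,
            "saving_percent": self.saving_percent,
        }
        return pd.DataFrame({"value": list(d.values())}, index=pd.Index(d.keys(), name="field"))


def savings_report(
    proposed: pd.Series,
    conventional: pd.Series,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> SavingsReport:
    """Totals, difference, percent saving and kWh twins over a common period."""
    if len(proposed) != len(conventional) or not proposed.index.equals(conventional.index):
        raise ValueError("proposed and conventional series must be aligned")
    conv = float(conventional.sum())
    prop = float(proposed.sum())
    saving = conv - prop
    percent = 100.0 * saving / conv if conv > 0 else float("nan")
    return SavingsReport(
        start=proposed.index[0],
        end=proposed.index[-1],
        conventional_total_mm=conv,
        proposed_total_mm=prop,
        saving_mm=saving,
        conventional_kwh=mm_to_kwh(conv, constants),
        proposed_kwh=mm_to_kwh(prop, constants),
        saving_kwh=mm_to_kwh(conv, constants) - mm_to_kwh(prop, constants),
        saving_percent=percent,
    )


# ---------------------------------------------------------------------------
# adaptive retraining

@dataclass(frozen=True)
class AdaptiveState:
    """Self-learning loop state: history, current fit, archived fits.

    By default the model accumulates the full record history; a sliding
    window (`window_days`) drops the oldest records before each refit.
    """

    records: pd.DataFrame
    design: TLTSDesign
    n_components: int = 8
    ms_fraction: float = 0.8
    cv_scheme: str | None = "loo"
    window_days: int | None = None
    results: IrrigationPLSResults | None = None
    history: tuple[PipelineMetrics, ...] = ()

    def training_records(self) -> pd.DataFrame:
        if self.window_days is None:
            return self.records
        return self.records.iloc[-self.window_days :]

    @classmethod
    def initialize(cls, records: pd.DataFrame, design: TLTSDesign, **kwargs) -> "AdaptiveState":
        state = cls(records=records, design=design, **kwargs)
        return replace(state, results=state._refit())

    def _refit(self) -> IrrigationPLSResults:
        return IrrigationPLS(
            self.training_records(),
            design=self.design,
            n_components=self.n_components,
            ms_fraction=self.ms_fraction,
            cv_scheme=self.cv_scheme,
        ).fit()


def adaptive_update(state: AdaptiveState, new_records: pd.DataFrame) -> AdaptiveState:
    """Append new daily records and refit; no-op for empty input.

    New record dates must strictly extend the stored history; the previous
    fit's metrics are archived in the state's history.
    """
    if new_records.empty:
        return state
    last = state.records.index.max()
    if new_records.index.min() <= last:
        raise ValueError(
            f"new records must start after {last.date()}; got {new_records.index.min().date()}"
        )
    records = pd.concat([state.records, new_records])
    archived = state.history
    if state.results is not None:
        archived = archived + (state.results.metrics,)
    new_state = replace(state, records=records, history=archived)
    return replace(new_state, results=new_state._refit())
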