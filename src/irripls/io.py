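"""Daily-record schema, CSV round-trip, 30-minute aggregation, climate summary.

Everything downstream consumes one tidy daily table (a :class:`pandas.DataFrame`
indexed by calendar date) with a fixed column vocabulary:

====================  =========================================================
column                meaning
====================  =========================================================
``rh_mean/min/max``   air relative humidity, %
``t_mean/min/max``    air temperature, °C
``dew_mean``          dew-point temperature, °C
``wind_dir``          wind direction, degrees (daily mean, as-is)
``wind_mean``         mean wind speed, km/h
``wind_gust``         daily maximum gust speed, km/h
``rain_mm``           rainfall total, mm/day
``solar_mean``        solar radiation, W/m²
``sm30/sm60/sm90``    volumetric soil moisture at 30/60/90 cm, %
``irrigation_mm``     irrigation water input, mm/day
====================  =========================================================

Dates are calendar days in the station's local time; no time-zone arithmetic
is performed.  Missing cells are NaN and a record with any missing model
variable is excluded from training rows by the design-matrix builder.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DAILY_COLUMNS",
    "WEATHER_COLUMNS",
    "SOIL_COLUMNS",
    "read_daily_csv",
    "write_daily_csv",
    "aggregate_daily",
    "climate_summary",
    "read_soil_profile_csv",
    "write_soil_profile_csv",
    "MONTHLY_CLIMATE_NORMALS",
]

WEATHER_COLUMNS = [
    "rh_mean", "rh_min", "rh_max",
    "t_mean", "t_min", "t_max",
    "dew_mean", "wind_dir", "wind_mean", "wind_gust",
    "rain_mm", "solar_mean",
]
SOIL_COLUMNS = ["sm30", "sm60", "sm90"]
DAILY_COLUMNS = WEATHER_COLUMNS + SOIL_COLUMNS + ["irrigation_mm"]

#: expected 30-min observations per day and the completeness threshold
INTERVALS_PER_DAY = 48
MIN_COMPLETE_INTERVALS = 40


def _validate_daily(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicated date(s) in daily series: {list(dupes)[:5]}")
    if not df.index.is_monotonic_increasing:
        raise ValueError("dates must be strictly increasing")
    for col in ("rain_mm", "irrigation_mm"):
        if col in df and (df[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col}")
    for col in SOIL_COLUMNS:
        if col in df:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"{col} outside [0, 100]")
    return df


def read_daily_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    require: list[str] | None = None,
) -> pd.DataFrame:
    """Read a daily-record CSV into the canonical schema.

    Parameters
    ----------
    path : path to a comma-separated, UTF-8, '.'-decimal file with a ``date``
        column in ISO-8601 form.
    column_map : optional mapping from foreign header names to canonical
        column names, applied before validation.
    require : canonical columns that must be present (defaults to none beyond
        ``date``); a missing required column raises an error naming it.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "date" not in df.columns:
        raise ValueError("daily CSV must have a 'date' column")
    for col in require or []:
        if col not in df.columns:
            raise ValueError(f"required column missing from {path}: {col!r}")
    unknown = [c for c in df.columns if c not in DAILY_COLUMNS + ["date", "complete"]]
    if unknown:
        raise ValueError(f"unknown column(s) in {path}: {unknown}")
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df = df.set_index("date")
    return _validate_daily(df)


def write_daily_csv(daily: pd.DataFrame, path: str | Path) -> None:
    """Write a daily series so that a read round-trips the values exactly."""
    out = daily.copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path)


def aggregate_daily(
    observations: pd.DataFrame,
    min_intervals: int = MIN_COMPLETE_INTERVALS,
) -> pd.DataFrame:
    """Collapse 30-minute station observations into daily weather records.

    ``observations`` must carry a sorted ``timestamp`` column plus any of:
    ``air_humidity``, ``air_temp``, ``dew_point``, ``wind_dir``,
    ``wind_speed_mean``, ``wind_speed_gust``, ``rain``, ``solar_rad``.
    Humidity and temperature yield daily mean/min/max; dew point, wind
    direction, mean wind speed and solar radiation yield daily means; gusts
    yield the daily maximum; rain is summed.  Days with fewer than
    ``min_intervals`` observations are kept but flagged ``complete=False``.
    """
    if observations.empty:
        return pd.DataFrame(columns=WEATHER_COLUMNS + ["complete"])
    ts = pd.to_datetime(observations["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("observations must be sorted by timestamp")
    obs = observations.copy()
    obs["_day"] = ts.dt.normalize()
    g = obs.groupby("_day")

    out = pd.DataFrame(index=g.size().index)
    out.index.name = "date"

    def put(col: str, src: str, how: str) -> None:
        if src in obs.columns:
            out[col] = getattr(g[src], how)()

    put("rh_mean", "air_humidity", "mean")
    put("rh_min", "air_humidity", "min")
    put("rh_max", "air_humidity", "max")
    put("t_mean", "air_temp", "mean")
    put("t_min", "air_temp", "min")
    put("t_max", "air_temp", "max")
    put("dew_mean", "dew_point", "mean")
    put("wind_dir", "wind_dir", "mean")
    put("wind_mean", "wind_speed_mean", "mean")
    put("wind_gust", "wind_speed_gust", "max")
    put("rain_mm", "rain", "sum")
    put("solar_mean", "solar_rad", "mean")
    out["complete"] = g.size() >= min_intervals
    return out


def climate_summary(monthly: pd.DataFrame) -> dict[str, float]:
    """Summarise a 12-month climate-normals table.

    ``monthly`` needs columns ``avg_t``, ``min_t``, ``max_t``, ``rain``
    (one row per month).  Returns annual rainfall (sum, mm), mean annual
    temperature (reported at 1 decimal, °C), the month-to-month rainfall
    range (mm) and mean-temperature range (°C).
    """
    if len(monthly) != 12:
        raise ValueError(f"expected 12 monthly rows, got {len(monthly)}")
    return {
        "annual_rain": float(monthly["rain"].sum()),
        "mean_t": float(round(monthly["avg_t"].mean(), 1)),
        "rain_range": float(monthly["rain"].max() - monthly["rain"].min()),
        "t_range": float(monthly["avg_t"].max() - monthly["avg_t"].min()),
    }


_SOIL_CSV_COLUMNS = [
    "depth_code", "texture", "om", "fc", "wp", "awc", "density", "limestone",
]


def read_soil_profile_csv(path: str | Path):
    """Read a soil-profile CSV (one row per depth, lab-report headings)."""
    from .soil import SoilLayer, SoilProfile

    df = pd.read_csv(path)
    missing = [c for c in ("depth_cm", "fc", "wp") if c not in df.columns]
    if missing:
        raise ValueError(f"soil profile CSV missing column(s): {missing}")
    layers = []
    for _, row in df.iterrows():
        layers.append(
            SoilLayer(
                depth_cm=int(row["depth_cm"]),
                texture=str(row.get("texture", "")),
                om=float(row.get("om", 0.0)),
                fc=float(row["fc"]),
                wp=float(row["wp"]),
                awc=float(row["awc"]) if "awc" in df.columns else None,
                density=float(row["density"]) if "density" in df.columns else None,
            )
        )
    return SoilProfile.from_layers(layers)


def write_soil_profile_csv(profile, path: str | Path) -> None:
    rows = [
        {
            "depth_cm": l.depth_cm, "texture": l.texture, "om": l.om,
            "fc": l.fc, "wp": l.wp, "awc": l.awc, "density": l.density,
        }
        for l in profile.layers
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


#: 30-year monthly climate normals for the temperate alpine orchard site the
#: simulator's climatology is shaped on (oceanic temperate, Cfb): monthly
#: average/min/max temperature (°C) and rainfall (mm).
MONTHLY_CLIMATE_NORMALS = pd.DataFrame(
    {
        "avg_t": [-0.6, 1.9, 6.2, 10.8, 14.7, 18.3, 20.7, 19.9, 16.9, 10.5, 5.1, 0.8],
        "min_t": [-4.1, -2.3, 1.4, 5.4, 9.3, 12.6, 14.6, 14.1, 11.5, 6.0, 1.5, -2.2],
        "max_t": [2.9, 6.2, 11.1, 16.2, 20.1, 24.1, 26.8, 25.7, 22.3, 15.0, 8.8, 3.9],
        "rain": [40, 42, 53, 69, 82, 92, 84, 96, 79, 85, 89, 51],
    },
    index=pd.Index(range(1, 13), name="month"),
)
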