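# irripls

Adaptive time-lag/time-series PLS modelling of daily irrigation water input,
for precision-irrigation decision support in orchards instrumented with a
weather station and multi-depth soil-moisture sensors.

## The problem

A parcel irrigated on a fixed schedule (here: one 5.25 mm dose per day,
rainy days excluded, 900 kWh of pumping energy per dose) wastes water and
energy whenever the soil profile already holds what the crop needs. With
daily weather aggregates and volumetric soil moisture at 30, 60 and 90 cm,
one can instead *learn* the parcel's water behaviour and ask the inverse
question each morning: how much water does the profile need today — and
over the next three days — to sit in its optimum band (between the
available water capacity AWC = FC − WP and the field capacity FC)?

## The method

1. **Lag analysis.** Surface water input (rain + irrigation) reaches a
   buried sensor with a depth-dependent delay. For each depth the
   cross-correlation `r(m) = corr(input_t, moisture_{t+m})`, m = 0..5 days,
   with a per-lag two-tailed t-test, selects the response lag: the
   significant lag ≥ 1 with maximal |r| (fallback for unresponsive depths).
2. **TimeLag/TimeSeries design.** Predictors are the weather variables over
   a window of `w` adjacent days and the soil moistures shifted by their
   lags (window on top); the response is the day's irrigation (mm).
3. **Chemometric calibration.** Autoscaling, an 80/20 SPXY split (sample-set
   partitioning on joint x–y distances), PLS1 by NIPALS with 8 latent
   vectors, leave-one-out cross-validation, and the standard metric suite —
   RMSEC, RMSECV, SEP, bias, RPD and r for model and test sets.
4. **Field-capacity substitution.** At prediction time every soil-moisture
   column is replaced by the FC of its depth, so the model returns the water
   input consistent with a profile at its optimum: the daily recommendation,
   clipped at zero, for horizons T0–T3 (forecast weather for future offsets,
   observations for past ones). The model retrains itself as new daily
   records accumulate.
5. **Savings accounting.** Recommendations vs the conventional schedule,
   in mm and kWh (linear pump conversion, 5.25 mm ≡ 900 kWh).

Field datasets of this kind are rarely public, so the package ships a
synthetic generator (`irripls.simulate`) reproducing the assumed structure:
climatology-shaped weather, Bernoulli–gamma rainfall, a three-layer bucket
cascade with 1-day/2-day percolation delays to 30/60 cm and a decoupled
90 cm layer, and a linear precision-management irrigation rule. See
`docs/methods.md` for the model, the generator's assumptions and its limits.

## Worked example

```python
import pandas as pd
from irripls import (SimConfig, make_training_scenario, analyze_daily,
                     select_lags, train_pipeline, predict_irrigation,
                     ForecastInput, DEFAULT_SOIL_PROFILE)

sim = make_training_scenario(SimConfig(n_days=120, seed=3))   # one season
lags = select_lags(analyze_daily(sim.daily))
print(lags.lags)                  # {30: 1, 60: 2, 90: 2}
res = train_pipeline(sim.daily)
print(res.summary())
```

```
Irrigation water input — PLS (time-lag / time-series)
========================================================
No. of samples            117
Model set / test set      94 / 23
Preprocessing             autoscale
No. of LVs                8
Soil-moisture lags        30 cm: 1 d, 60 cm: 2 d, 90 cm: 2 d
TimeSeries window         2 d
--------------------------------------------------------
RMSEC        (mm)            0.389
RMSECV       (mm)            0.496
Bias (test)  (mm)           -0.005
SEP model    (mm)            0.391
SEP test     (mm)            0.333
RPD model                    3.030
RPD test                     2.778
r model (80%)                0.943
r test                       0.947
========================================================
```

The lag analysis found the 30 cm moisture responding one day after surface
water input (r = 0.67) and the 60 cm moisture two days after (r = 0.63),
with no coherent response at 90 cm — so those depths enter the model at
lags 1, 2 and 2 (fallback). The calibration errors (RMSEC ≈ 0.39 mm against
a ~5.8 mm/day mean input) and correlations near 0.94 say the rule generating
irrigation in this scenario is well captured.

Forecasting with a 4-day weather table and the profile pinned at field
capacity:

```python
fi = ForecastInput(date=sim.daily.index[-1], forecast=forecast_rows,
                   recent=sim.daily)
print(predict_irrigation(res, DEFAULT_SOIL_PROFILE, fi).table.round(2))
```

```
        raw_mm  recommended_mm
offset
0         2.88            2.88
1         2.76            2.76
2         2.76            2.76
3         2.76            2.76
```

A profile already at field capacity needs well under the conventional
5.25 mm dose. Applied a posteriori over the whole season
(`recommend_series`) and compared with the fixed schedule
(`conventional_irrigation`, `savings_report`), this run recommends 336 mm
against the schedule's 404 mm — a saving of 68 mm (≈ 11,700 kWh, 16.9 %).
A single season's percentage is noisy (see `docs/methods.md` on the
extrapolation behaviour of FC substitution); averaged over many simulated
seasons it settles around 20 %.

The same workflow is scriptable from a shell:

```sh
irripls full-run --seed 7 --n-days 120 --out runs/demo
irripls train --daily runs/demo/daily.csv --lags runs/demo/lags.json --out runs/demo
```

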