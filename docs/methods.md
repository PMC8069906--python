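# Methods

## Problem and model

`irripls` estimates the daily irrigation water input of an orchard parcel
from routinely available signals — weather-station aggregates and volumetric
soil moisture at 30, 60 and 90 cm — and inverts that estimate at prediction
time to answer the operational question: *how much water does the profile
need today and over the next three days to sit at its optimum?*

The statistical core is a univariate partial least squares (PLS1) regression

    y_t = f(weather_{t..t-(w-1)}, sm_d,{t-ℓ(d)..t-ℓ(d)-(w-1)}) + ε_t

where `y_t` is irrigation (mm/day), `w` is the TimeSeries window (adjacent
days included as separate predictors), and `ℓ(d)` is the per-depth TimeLag:
the number of days surface water needs to percolate to the sensor at depth
`d`. Lags are not assumed but *selected* from the data by cross-correlating
the surface water input (rain + irrigation) with each depth's moisture
series.

### Lag selection

For lags m = 0..5, r(m) is the Pearson correlation of input `x[t]` with
moisture `y[t+m]` over the n−m overlapping pairs (no padding or circular
wrap-around; overlap shrinks with lag). Each lag carries a two-tailed
p-value from the exact t statistic `t = r·sqrt((n−2)/(1−r²))` with
`n_overlap − 2` degrees of freedom. Per depth the modelling lag is the
lag ≥ 1 with the largest |r| among those with p < α (default α = 0.05, ties
toward the smaller lag — the more parsimonious causal delay). A depth with
no significant lag receives a configurable fallback (default 2 days):
deep layers may respond incoherently yet still enter the model at a nominal
delay. Only non-negative lags are scanned, since cause precedes effect, and
soil-moisture predictors must be strictly past values (lag ≥ 1) so the model
is usable for forecasting.

### Calibration pipeline

1. **Design matrix.** Every weather variable at offsets `0..w−1` days before
   the target day; soil moisture at `ℓ(d)..ℓ(d)+w−1`; rows that would reach
   before the series start, or contain any missing cell, are dropped
   (conservative missing-data policy; no interpolation by default).
2. **Autoscale.** Column-wise standardisation to zero mean and unit sample
   standard deviation (ddof = 1), for X and y; predictions are
   back-transformed to mm. A constant column is an error, not a silent drop.
3. **SPXY split.** The analysis set is partitioned 80/20 into model and test
   sets by sample-set partitioning on joint x–y distances:
   `d(i,j) = dx/max dx + dy/max dy`, seeded with the most distant pair, grown
   by max–min selection. Distances are measured in the autoscaled joint
   space of the full analysis set; the model's own scaling is then
   re-estimated on the model set only, so the test set never leaks into
   calibration. The procedure is deterministic; ties break to the lowest
   row index, making it permutation-covariant.
4. **NIPALS PLS1.** Latent vectors are extracted sequentially — weight =
   normalised covariance direction of the X and y residuals, score, rank-one
   X deflation — and folded into a single regression vector
   `b = W(PᵀW)⁻¹q`. Eight latent vectors by default. With the full LV count
   the solution equals least squares (verified against the normal equations
   in the tests); with fewer it is the usual shrunken compromise suited to
   collinear weather blocks.
5. **Validation.** Leave-one-out cross-validation of the model set
   (scaling re-estimated inside every fold) gives RMSECV per LV count; a
   contiguous-blocks scheme is available because rows are temporally
   ordered. The metric suite is the standard chemometric one: RMSEC, SEP
   (bias-corrected, divisor n−1), bias = mean(pred − obs), Pearson r, and
   RPD = sd(reference)/RMSE, reported separately for model and test sets.
   The single `bias` field reports the external (test-set) bias. These
   satisfy the identity `SEP² = n/(n−1)·(RMSE² − bias²)`, which the tests
   assert.

### Application phase: field-capacity substitution

At prediction time every soil-moisture column is replaced by the **field
capacity** of its depth, so the fitted mapping returns the water input
consistent with a profile sitting at its optimum — the recommendation.
Weather columns at future offsets come from a forecast table (a static CSV
snapshot, for reproducibility), at past offsets from observed records;
horizons T0–T3 are produced per interrogation. Raw output is clipped at
zero (negative irrigation is meaningless). Applied a posteriori over a whole
observed season, the same substitution yields the daily recommendation
series that is compared with the conventional schedule — one 5.25 mm dose
per day, skipped when rain exceeds 1.0 mm (configurable; the practice is
stated only as "rainy days excluded") — in mm and, through the fixed linear
pump conversion 5.25 mm ≡ 900 kWh, in energy. The savings report exposes
all raw totals so any percentage can be recomputed from them.

The model is *adaptive*: as new daily records arrive the full pipeline is
refit on the extended history (full accumulation by default; a sliding
window is available), with previous metrics archived.

## Synthetic data generator

Field records of this kind are rarely deposited, so the package ships a
generator reproducing the statistical structure the pipeline assumes. Its
defaults are the study conditions; they were chosen once, from the design
below, and are what the tests and the acceptance experiments run on.

* **Weather.** Daily mean/min/max temperature follows 30-year monthly
  normals of a temperate alpine orchard site (annual mean 10.4 °C, annual
  rain 862 mm) interpolated periodically over the day-of-year, plus a
  1.5 °C day-to-day anomaly. Rain is a Bernoulli wet-day process
  (p = 0.3) with gamma wet-day depths (shape 2, scale 3 mm — mean 6 mm);
  humidity, dew point, wind and solar radiation are simple covarying draws.
  Wind direction is uniform degrees (the model consumes it as-is; a circular
  encoding is a documented caveat, not implemented, matching the design
  matrix's treatment).
* **Soil.** A three-layer bucket cascade on the default sandy-loam profile
  (FC 17.1/21.6/16.0 %, WP 6.3/11.8/4.1 % at 30/60/90 cm; 3 mm of water per
  volumetric % per 30 cm layer). A fraction of each day's surface input
  arrives in each layer after its percolation delay — defaults 0.55 after
  1 day at 30 cm, 0.25 after 2 days at 60 cm, 0 to 90 cm, remainder lost
  below the profile — then storage decays by a per-layer ET/drainage
  fraction (0.30, 0.45, 0.10 per day) and is capped at saturation
  (FC + 5 %), overflow cascading downward. The split-fraction arrival was
  chosen over an overflow-only cascade because threshold overflow makes the
  deep response a rare nonlinear event and smears the lag-2 correlation
  peak; likewise the 60 cm decay must be fast, or the moisture level
  correlates almost equally with inputs two and three days back and lag
  selection becomes ambiguous. With these defaults the configured delays
  are recovered by the lag analysis in ≥ 95 % of seeds (measured: 99/100).
  Water is conserved when the arrival fractions sum to one and ET is zero,
  which the tests assert. The 90 cm layer is driven mostly by an
  independent slow AR(1) wander (ρ = 0.95) to mimic a decoupled deep layer
  with stochastic influences.
* **Irrigation (training scenario).** A smooth precision-management rule:
  `irr_t = max(0, dose + 0.6·(target − sm30_{t−1}) + 0.12·(T_t − 20) −
  0.2·rain_t + jitter)` with dose 5.25 mm, jitter sd 0.4 mm, and a target of
  13.5 % — the middle of the 30 cm optimum band (AWC 10.8 % to FC 17.1 %),
  where the management doctrine says the profile should sit. The rule is deliberately *affine* in the model's feature columns
  (a binary rainy-day on/off schedule is a step function of rain that no
  linear model can fit exactly), so a noise-free run is exactly learnable —
  the pipeline's correctness floor. The fixed on/off schedule is still
  implemented separately as the savings baseline.
* **Noise.** Additive Gaussian observation noise (sd 0.25 %) on moisture,
  applied last; a global `noise_scale` multiplies observation noise, rule
  jitter and the 90 cm wander, so `noise_scale = 0` is a fully noise-free
  scenario with hidden truth exposed for parameter recovery. Sensor drift
  is not modelled.

What passing on this generator shows — and what it does not: the pipeline
provably recovers lag structure, generative coefficients (for predictors
that are not heavily collinear; the temperature effect spreads across its
correlated siblings and only its sign is identified) and management savings
*when the data-generating process matches the model family*. Real series
add sensor drift, irrigation-record errors, non-additive soil physics and
weather-forecast error, none of which the generator emulates.

## Numerical choices and degenerate inputs

* Sample statistics use ddof = 1 throughout (autoscale, RPD reference sd).
* |r| = 1 returns p = 0 as the t-statistic limit; constant overlap at any
  lag is an error ("zero variance at lag m"), not a NaN.
* NIPALS stops early if the residual covariance norm falls below 1e−14 and
  returns the LVs extracted so far; `n_lv` must satisfy
  `n_lv ≤ min(n−1, p)`.
* SPXY requires positive spread in both spaces; RMSE = 0 flags RPD as
  infinite rather than raising.
* A model-set fraction that rounds to the full sample count yields an empty
  test set and NaN test metrics rather than an error.
* CSV round-trips use full float repr, so write→read is exact; dates are
  ISO-8601 calendar days with no time-zone arithmetic.
* Soil lab-report density values are stored verbatim but never used in
  computation (the printed magnitudes are physically implausible).

## Problem sizes

Simulated seasons are 120 days (≈ one irrigation season), giving 117
analysis samples after the 3-day lag warm-up; the lag-recovery experiment
uses 100 seasons; oracle-equivalence checks use 50 random 20×6 problems.
These sizes make every experiment exact enough to be decisive while the
whole suite and the acceptance script each run in seconds.

## Known limitations

* PLS coefficient magnitudes are not identified under strong collinearity;
  interpret the raw-space coefficient vector as a predictive direction, not
  per-variable physics.
* Field-capacity substitution is an *extrapolation*: at prediction time the
  soil-moisture columns are pinned to values (their FCs) jointly far outside
  the training cloud, so whatever share of the signal the fit allocated to
  collinear-but-irrelevant moisture columns (60/90 cm here) is misapplied.
  On the synthetic scenario this makes a single season's saving percentage
  scatter widely around the generative truth (standard deviation of tens of
  percentage points across seeds) even though calibration metrics are
  excellent; the acceptance experiment therefore averages the savings
  accounting over many simulated seasons. Any field deployment of
  FC substitution inherits this hazard.
* The SPXY split concentrates extreme samples in the model set, so test-set
  r can fluctuate well below model-set r on small seasons; RMSECV is the
  more stable internal figure.
* Centibar-tension sensors require an external calibration to volumetric %
  before use; the package consumes % throughout.
* The conventional-schedule baseline depends on the rainy-day threshold,
  which the practice it models leaves unspecified; it is a parameter, and
  all raw totals are reported so the comparison can be redone under any
  reading.
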