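# Methods

This note documents the models, numerical choices and limitations of
`phenocast`, an automated species-level plant phenology forecasting
toolkit: process-based thermal-forcing models fit to onset
observations, combined by cross-validated stacking, driven by
statistically downscaled seasonal temperature forecasts, and verified
against subsequently observed events.

## Time axis

All daily series live on an *extended day axis*: day 1 = 1 January of
the target year, day 0 = 31 December of the prior year, 1 November of
the prior year = day −60 (non-leap counting). This makes accumulation
across the year boundary — chill in November, forcing through June —
ordinary integer arithmetic. A predicted "day of year" is the extended
index when it is ≥ 1; events before 1 January are reported at their
negative index. On disk, netCDF time is encoded as
`days since 31 Dec <reference_year − 1>` so stored values equal the
extended index.

Observed temperature series begin 1 November of the prior year by
default. A 30 November start is also supported
(`observed_start: 30nov`); the earlier default gives the alternating
model a full chill season.

## Phenology model family

All four families are driven solely by the 24-h daily mean temperature
`T_i` and predict the first day an accumulated requirement is met.

- **thermal_time** — growing degree days: daily unit
  `max(0, T_i − T_base)` accumulated from start day `t1`; the event
  occurs when the sum reaches `F*`. Parameters: `t1` (day), `T_base`
  (°C), `F*` (degree-days), all fit unless fixed.
- **alternating** — chill/forcing trade-off: degree days above 5 °C
  accumulate from `t1` while days with `T_i` < `chill_threshold`
  (default 5 °C, the literature standard) are counted as chill days
  `NCD`; the requirement on day *d* is `a + b·exp(c·NCD_d)` (with
  `c ≤ 0` more chill lowers the requirement). The 5 °C GDD base for
  the forcing sum is fixed, matching the classical formulation.
- **uniforc** — sigmoidal forcing response
  `1 / (1 + exp(b_sig·(T_i − c_sig)))` accumulated from `t1` to `F*`.
  The fitter bounds enforce `b_sig < 0` so forcing increases with
  temperature; `c_sig` (°C) locates the half-response.
- **linear** — a regression baseline:
  `day = round(beta0 + beta1 · mean(T over [window_start, window_end]))`,
  window fixed (default 1 Jan–1 Mar) and coefficients fit by ordinary
  least squares.

These four forms are the canonical suite of the process-model
literature for temperate spring phenology. Other suites (e.g. with a
sequential two-phase chill model, or photoperiod or moisture drivers)
are deliberately out of scope; the package's `FamilySpec` mechanism
accepts alternative bounds or fully prescribed members.

Missing temperature days: gaps of ≤ 3 consecutive days inside a
series are filled by linear interpolation; longer gaps inside a
model's active window make that cell's prediction *missing* rather
than silently zero-filling forcing, which would bias events late.

Grid prediction is vectorized (one cumulative sum over a
cells × days matrix) and is tested cell-for-cell against a per-cell
loop of the scalar predictor.

## Fitting and stacking

Onset events are derived from raw yes/no/unsure status records: a
"yes" counts only if the same plant/phenophase has a "no" within the
prior 30 days; plants with conflicting same-day statuses or more than
one yes-series within 12 months are dropped entirely for that
phenophase; "unsure" is ignored. Species × phenophase groups need at
least 30 onsets (inclusive) to be fit.

Single models are fit by minimizing the RMSE between predicted and
observed onset days using seeded differential evolution (tolerance
1e-4, no polishing — the objective is stepwise in the integer event
day, so gradient polish adds nothing). Observations a candidate
predicts no event for are charged a large finite penalty (1000 days).
Default bounds per family are wide enough for temperate spring events;
they are part of `FamilySpec` and can be narrowed.

The ensemble weights are learned by stacking: observations are
randomly partitioned into k = 100 folds (leave-one-out when the group
is smaller, with a warning; folds are assigned per observation, not
per plant or site), each family is fit on each training fold and
predicted on the held-out fold, and weights on the simplex
(non-negative, summing to one) minimize the RMSE of the weighted
out-of-fold prediction. The quadratic program is solved by SLSQP from
both the uniform point and the best single member's vertex, keeping
the better solution, so the stacked out-of-fold RMSE can never exceed
the best member's; the exact-tie case of identical member predictions
resolves to the uniform point. After weighting, every member is refit
on the full data set; weights are not re-estimated after the refit.

Ensemble prediction is the weighted mean of member event days, rounded
to the nearest day. Members predicting no event are dropped and the
remaining weights renormalized; if less than half the total weight
responds the ensemble withholds the forecast — one pathological member
cannot delete a forecast, but low-confidence dates are not invented.

A latitude-only ordinary-least-squares baseline
(`day = beta0 + beta1·latitude`) is fit per group for expressing
forecasts as anomalies against the spatially corrected long-term
average.

## Downscaling

Coarse (≈0.25°) 6-h temperature forecasts are first collapsed to daily
means (each day the mean of its four 6-h values; a trailing partial
day is dropped), then interpolated to the fine grid by inverse
distance weighting over the k = 4 nearest coarse centers with power
p = 2; a fine point coinciding with a coarse center takes that
center's value exactly, and points outside the coarse grid's bounding
box fall back to the nearest center.

For each fine cell and calendar month, an *asynchronous regression*
maps coarse to fine: both archive samples restricted to that month are
sorted, paired by empirical quantile (the longer sample's quantile
function interpolated to the shorter's length), and fine is regressed
on coarse by ordinary least squares. Pairing by rank rather than
timestamp is what makes a free-running climate model usable as a
predictor: only the distributions need to correspond. A single linear
segment (two parameters) is stored per cell per month; monthly
samples need ≥ 30 values and non-degenerate coarse variance, otherwise
the cell/month is flagged missing rather than fabricated. Months are
taken in the forecast's own calendar with no timezone adjustment.

## Forecasting and uncertainty

For each issue date, observed temperatures (up to the day before the
forecast's first day) are spliced with each downscaled member
(forecast values win on overlap days) into five continuous daily
member cubes. The phenology ensemble runs over each member; per cell
the point estimate is the member mean rounded to the day, the
uncertainty is the sample (n−1) standard deviation across members, and
the 95% prediction interval is the normal approximation
point ± 1.96·sd, clipped to the series span. With five members a
min/max range is not a 95% interval, hence the normal approximation.
Cells where fewer than 60% of members (3 of 5 nominal) predict an
event are missing; cells summarized over a strict subset are flagged
partial. The anomaly is the point estimate minus the latitude
baseline, negative meaning earlier than average. All grids are
cropped to the species range mask before publication.

The member spread is the only uncertainty source carried: the process
models are deterministic, so the advertised SD reflects uncertainty in
the temperature forecast, not parameter or structural uncertainty.

## Verification

Events are matched to the nearest grid cell (ties to the lower index);
events landing on masked-out cells are dropped with a logged count.
Each issue date's row scores, by default, the events that had not yet
occurred on that date (genuine forecasts; `mode="all"` scores every
matched event instead): RMSE, mean signed error (positive = predicted
later than observed), and the mean advertised SD. Signed-error
distributions and their mean absolute error are available per issue
date. On every row `rmse ≥ MAE ≥ |mean error|` by construction.

## Pipeline

The `fit`, `build-downscaling`, `forecast` and `verify` commands are
idempotent single-shot runners configured by YAML; scheduling is an
operations choice left outside the code. Fitted ensembles are stored
as deterministic, diff-friendly JSON documents (sorted keys, full
float precision, `schema_version` from day one) plus a metadata
index, so a model store can live under version control. Forecast
products are written one compressed netCDF per
species × phenophase × issue date. A forecast run writes everything
to a staging directory and renames it into the publish directory only
when every product succeeded; an interrupted run leaves the previous
publication byte-identical. Members whose time series do not reach
the minimum horizon (default 270 days — nine months — past the issue
date) are discarded in favour of a configured fallback forecast.

## Synthetic data

The generator emulates the pipeline's real inputs with a fully
parametric truth: temperature is
`T(d) = mean − lapse·(lat − lat0) + amplitude·sin(2π(d − phase)/365) + N(0, noise_sd)`
with defaults mean 10 °C, amplitude 12 °C (winter ≈ −2 °C, summer
≈ 22 °C), lapse 0.8 °C per degree latitude, daily weather noise
2 °C — a plausible temperate-US spring. Onsets are the true model's
prediction per site plus rounded N(0, 2 d) observation error; status
records are built to pass the 30-day filter, with optional injected
violations for filter tests. Coarse/fine archive pairs share known
per-cell/month affine maps (slopes 0.7–1.3, intercepts ±3 °C), so the
downscaling fit has an exact recoverable truth; 6-h values add a
zero-mean diurnal harmonic so daily aggregation is exact. Climate
members add a smooth perturbation whose SD grows linearly with lead
time (default 0.5 °C per 30 days). Every generator draws from its own
stream keyed by (seed, purpose), so adding generators never perturbs
existing fixtures.

What the generator does *not* emulate: spatially correlated weather
fronts, elevation, missing-data patterns of real gridded products,
observer biases in status data, or non-temperature drivers. Passing
tests therefore demonstrate correctness of the machinery and
statistical identifiability under the stated model, not skill on real
observations.

With every noise source at zero the full pipeline is exactly
identifiable: verification RMSE is 0 at all issue dates. When
cross-validation assigns a small weight to a structurally different
member, the rounded weighted mean can shift individual cells by one
day, so near-zero (≲0.2 d) rather than exactly zero RMSE can occur at
some generator seeds; this is a genuine property of ensemble
averaging with integer event days, not a numerical defect.

## Problem sizes used in tests and the acceptance script

Parameter recovery uses 100 sites on an 8×8 grid (70/30 train/test);
stacking uses the same observations with leave-one-out folds;
downscaling exactness uses a 3×3 fine grid over a 2-year archive; the
end-to-end runs use 12×12–20×20 grids, 2 species, 5 members and 3
issue dates with 5-fold stacking and a reduced optimizer budget.
These sizes were chosen so the whole suite completes in a few minutes
while every code path (including the vectorized/loop oracle pairs)
is exercised at full fidelity.

## Known limitations

- Parameter trade-offs: with `t1`, `T_base` and `F*` all free, many
  parameter sets fit equally well (a classical identifiability issue);
  recovery tests therefore fix the nuisance parameters.
- The downscaling stores a single linear segment per month, not the
  piecewise tails of the full asynchronous-regression method; extreme
  tails are extrapolated linearly.
- The 95% interval is a normal approximation from five members.
- CV folds are assigned per observation; plants observed repeatedly
  could leak information across folds in real data.
- No within-season data assimilation: new observations do not update
  a season's forecasts.
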