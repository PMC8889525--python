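# Methods

## The forecasting problem

Daily inpatient bed demand `Y_t` — census plus boarded patients — is a
strongly seasonal, autocorrelated count series.  The package forecasts
`Y_{t+h}` for h = 1 or 2 days from information available at the origin
`t`, for a whole-hospital adult census; no decomposition of the aggregate
demand (into census vs boarding, or by level of care) is attempted.

## The K-SVR engine

**Model.**  Training days are partitioned by K-means; by default the
clustered quantity is the scalar target demand itself, so clusters are
*demand levels* (a `feature_vector` representation, clustering the
z-scored predictor rows, is available for experimentation).  A multi-class
SVM (RBF kernel) learns features → cluster; an ε-SVR (RBF kernel) per
cluster learns features → demand on that cluster's rows only.  At
prediction time a day is always routed through the classifier — never
through stored training labels — so the deployment path equals the test
path.  Forecasts are real-valued, floored at zero, never rounded unless
the caller asks.

The predictor set (demand lags 1–3, seasonal lag 7, the lag-1×lag-2
interaction, covariates at the origin) is treated as a *feature
specification* for kernel regression rather than as a literal linear
model: with an RBF kernel the linear coefficients one would write in a
regression equation are absorbed into the learned function.  Present-day
(`t+h`-day) demand is never a predictor — every predictor indexes at or
before the forecast origin, so leakage is structurally impossible.

**Hyperparameters.**  Features are z-scored on training rows; SVR targets
are z-scored within each cluster (zero spread falls back to unit scale).
Grids: SVR C ∈ {0.1, 1, 10, 100}, ε ∈ {0.01, 0.1, 1} in
standardized-target units, RBF γ ∈ {0.1, 1, 10}/d for d features; the SVM
shares the C and γ grids.  Selection is by K-fold cross-validation
(default tenfold; folds shrink with a logged warning when a cluster is
smaller), minimizing misclassification for the SVM and mean absolute
error for each SVR.  Ties break deterministically toward the smallest C,
then ε, then γ.  Final models refit on all their rows.  A cluster with
fewer than 2 rows aborts training: a local model on so few points would
only memorize them.

**Choosing K.**  The within-group sum-of-squares (wss) curve is computed
for K = 1..10, each best-of-10 random restarts; K+1 is additionally
warm-started from the best K solution plus the farthest point, which
makes the curve provably non-increasing (independent restarts alone need
not be).  The elbow rule returns the smallest K whose relative wss drop
to K+1 falls below `min_relative_drop` (default 0.10 — an elbow criterion
is inherently a judgment call; the default encodes "marginal gain under
10%").  On smooth unimodal demand the optimal 1-D wss decays like 1/K²
and never drops below 10% per step within K ≤ 10, so no elbow is found:
the maximum tested K is returned with a `NoElbowWarning`.  On multimodal
(regime) demand and on near-degenerate data (few distinct demand levels)
the rule triggers properly.  A zero wss contributes a zero further drop,
so the first exact-fit K is selected on degenerate data.

**Multi-step forecasts.**  2-day-ahead forecasting defaults to *direct*
mode (a model trained at horizon 2, with lags laid out relative to the
2-day origin); *recursive* mode (a horizon-1 model fed its own forecasts,
covariates held at their last observed values) is available.  Both are
legitimate readings of multi-step kernel forecasting; direct mode avoids
compounding routing errors and is used in the evaluation harness.

## Calendar handling

In all-days mode a lag step is a calendar day.  In weekdays-only mode
Saturday/Sunday rows are removed and every lag is re-indexed over
business-day positions: a Monday forecast at horizon 1 uses Friday as
lag 1 (effectively a 3-day-ahead prediction), and at horizon 2 uses
Thursday (4 days).  The seasonal lag is interpreted positionally (7
business days ≈ 1.4 weeks) by default; a `seasonal_as_same_weekday`
switch uses 5 positions (same weekday, previous week) instead, because
the intended meaning of a "lag 7" in a weekday-only calendar is genuinely
ambiguous.  Dates are the primary key at every module boundary, which
prevents off-by-one errors between the two calendars.

## Evaluation protocol

Chronological 70/30 split; models are trained on the first 70% only.
Four Monday-start test weeks (7 days, or 5 in weekday-only mode) are
placed evenly spaced and non-adjacent in the held-out span; weeks must be
pairwise disjoint and disjoint from training, and the report aborts
rather than silently trims if a model cannot forecast every day.  When
model *variants* (calendar modes, horizons) are compared, they are scored
on the *same* test weeks (`select_shared_test_weeks`), otherwise the
different 70% boundaries of the two calendars produce different weeks and
week-to-week variability swamps the variant effect.

Measures per (model, week), averaged across weeks:

* MAPE = mean(|Yr − Yf| / Yr) × 100;
* MAE and RMSE in beds/day (RMSE ≥ MAE always, by Jensen);
* **error variance** = the sample variance (N−1 denominator) of the daily
  relative errors |Yr − Yf| / Yr.  This quantity has no universal
  definition; the relative-error reading is used here because it is the
  natural variability companion to MAPE and produces the 1e-5..1e-3
  magnitudes typical of percent-level forecasts, whereas a beds² reading
  would sit orders of magnitude higher.  The cross-week "Average" column
  averages the per-week metric values (it does not pool days).

The ARIMA comparator is fitted by maximum likelihood on the training
span; its order is AIC-selected over p, q ∈ 0..3, d ∈ 0..1 (non-seasonal
by default; a weekly seasonal term is available).  Per-day test forecasts
re-filter the *fixed* fitted parameters over the history up to each
forecast origin, so ARIMA and K-SVR see exactly the same information set.

## Synthetic census generator

Real hospital census data is business-sensitive and rarely shareable, so
all tests and examples run on synthetic series emulating a ~350-bed
tertiary hospital:

* base level 340 beds with an additive weekday profile
  (+5, +12, +15, +12, 0, −22, −25 for Mon..Sun): mid-week high from the
  elective surgical schedule, weekend trough;
* AR(2) noise, coefficients (0.5, 0.2), innovation sd 8 beds — enough
  memory to make lags 1–3 informative and the weekly lag visible in the
  ACF;
* `weekend_noise_scale` = 0.5: weekend innovations at half strength.
  Weekend census moves little and predictably — no elective surgery and
  low admission/discharge turnover — and a homoskedastic series misses
  this, which matters for any comparison of with- vs without-weekend
  models (an all-days model is scored on weekend days; their volatility
  must reflect the real weekend quiescence);
* covariates (medicine, surgical, midnight censuses) as noisy linear maps
  of demand, giving the strong demand–covariate correlations the feature
  set expects;
* optional regimes: persistent level shifts with geometric sojourns
  *and their own weekday-profile gain*.  The bundled `regime_switching`
  preset alternates a baseline with a +60-bed surge (expected 60-day
  sojourns) whose weekly swing is amplified ×2.5 — a surge driven by
  elective volume deepens the weekly cycle.  The gain term matters: a
  pure level shift leaves the process linear-Gaussian, where a correctly
  specified ARIMA is essentially optimal and cluster-local regression has
  nothing to exploit; distinct per-regime dynamics are precisely the
  structure the K-SVR architecture assumes.

Demand is rounded and floored at 0, and every series is bit-reproducible
from its seed.  What the generator does **not** emulate: patient-level
arrival/discharge processes, length-of-stay distributions, holidays, flu
season, capacity saturation, or calendar drift.  Passing tests therefore
show the engine recovers the structure it assumes when that structure is
present — not that it attains any particular accuracy on real hospital
data.

## Numerical choices and edge cases

* K-means: Lloyd's with `n_init` restarts, best by wss; fits are
  bit-reproducible given (seed, n_init); wss is verified against direct
  recomputation to 1e-9 in the tests.
* Grid-search determinism: grids are scanned in ascending order with
  strict-improvement updates, so ties resolve to the smallest values.
* MAPE and the error variance require strictly positive realized demand
  (they are undefined at zero); MAE/RMSE do not.
* Feature rows whose lags reach before the series start are dropped, not
  imputed.
* Loading rejects duplicate dates, calendar gaps, and negative or
  non-numeric values with the offending date or 1-based data-row number.
* Forecast sizes in the test-suite and acceptance script: three-year
  (1095-day) series for the plain preset, 1500 days for the regime
  preset, five seeds for the stochastic ordering checks — sizes at which
  the orderings of interest are detectable while the whole suite runs in
  minutes.

## Known limitations

* With no elbow in sight on smooth unimodal demand, auto-K runs to the
  top of the tested range and the extra clusters cost a little accuracy
  through misrouting; fix K (or widen `min_relative_drop`) when the
  demand histogram is known to be unimodal.
* The SVM routes on lagged features only (the calendar is deliberately
  not a predictor), so day-of-week phase must be inferred from the lag
  pattern; days following sharp profile jumps (Saturday, Monday) carry
  slightly higher error.
* The error-variance metric follows the relative-error interpretation
  described above; other groups may define it differently.
* 2-day weekday-only forecasts are effectively 4-day forecasts for
  Mondays and accuracy degrades accordingly — that is a property of the
  calendar, not a defect.
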