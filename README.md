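# bedcast

Short-term forecasting of daily **inpatient bed demand** — the hospital
census plus patients boarded in the ED, PACU or recovery suites awaiting an
inpatient bed.  Accurate 1–2-day-ahead demand forecasts let capacity teams
expedite discharges, decant elective surgery or adjust staffing *before* the
house fills, instead of reacting to overcrowding.  The package is written
for hospital-operations analysts and researchers in patient-flow modelling.

## The method

The engine is a **cluster-local support-vector regression** (K-SVR):

1. **Cluster** the historical daily demands `Y_t` into K groups of similar
   level with K-means; K is chosen from the within-group sum-of-squares
   curve by the elbow rule.
2. **Classify**: a multi-class RBF-kernel SVM learns to map a day's
   predictor vector to its demand cluster.
3. **Regress**: for each cluster an RBF-kernel ε-SVR is trained on that
   cluster's days only, so days following similar historical patterns get
   their own local model.

The predictors for a forecast of `Y_{t+h}` made at origin `t` follow

```
Ŷ_{t+h} = f( Y_t, Y_{t-1}, Y_{t-2},  Y_{t-6},  Y_t·Y_{t-1},  M_t, U_t, C_t )
              └── lags Dt.1..Dt.3 ──┘ └ Dt.7 ┘  └─ Dt.1.2 ─┘  └ covariates ┘
```

with demand lags `l = 3`, seasonal lag `s = 7` (the weekly census cycle,
selected from ACF/PACF diagnostics), a lag-1×lag-2 interaction, and three
covariate censuses (medicine `Mt`, surgical `Ut`, midnight `Cen_Mid`) at the
origin.  Variants: horizons of 1 or 2 days, calendars with or without
weekends (the weekday-only variant re-indexes all lags over business days,
so a Monday forecast at horizon 1 uses Friday as `Dt.1`).  Multi-step
forecasts are either *direct* (a model trained at that horizon) or
*recursive* (forecasts fed back as lagged inputs).

Evaluation follows a test-week protocol: models train on the chronological
first 70% of the series and are scored on four non-overlapping Monday-start
weeks in the held-out span, with MAPE, MAE (beds/day), RMSE (beds/day) and
the variance of the daily relative errors reported per week, against an
AIC-selected ARIMA comparator.  Hospital census data is rarely shareable,
so a synthetic generator reproduces the structure the engine assumes:
weekly profile with a mid-week high and weekend trough, AR(2) noise with
quieter weekends, covariates that co-move with demand, and optional demand
regimes (e.g. a surgical surge) with their own weekly dynamics.

## Worked example

```python
import bedcast as bc

series = bc.generate(bc.preset("regime_switching", seed=1))
models = [
    bc.KSVRForecaster(horizon=1, k="auto", seed=1),
    bc.KSVRForecaster(horizon=1, k=3, seed=1),
    bc.ArimaComparator(),
]
report = bc.evaluate(models, series, horizon=1)
print(report.to_text())
```

prints (abridged)

```
1-day ahead, with weekend data
Metric          Model             Week 1      Week 2      Week 3      Week 4     Average
----------------------------------------------------------------------------------------
MAPE (%)        K-SVR               2.14        5.13        1.71        2.34        2.83
MAE (bed/day)   K-SVR               8.77       17.81        6.03        9.55       10.54
RMSE (bed/day)  K-SVR              10.79       19.54        6.71       11.14       12.05
MAPE (%)        K-SVR(3)            2.15        4.64        1.26        1.99        2.51
MAPE (%)        ARIMA               4.23        3.60        3.14        4.54        3.88
MAE (bed/day)   ARIMA              17.53       12.68       10.70       18.06       14.74
```

Read: across the four held-out weeks the cluster-local engine misses by
about 10.5 beds/day (2.83% of demand) on this surge-prone synthetic
series, clearly beating the single ARIMA (14.7 beds/day, 3.88%) — the
per-cluster regressors capture the different weekly dynamics of the
baseline and surge regimes that one global linear model averages away.
On this seed the 3-cluster variant edges out the elbow-selected one
(2.51%); across seeds the orderings hold on average, week-to-week
variability is real.

The `examples/` scripts walk through each capability (diagnostics,
training/forecasting, evaluation), and the same workflow is available from
a shell:

```sh
bedcast simulate --preset tertiary_350 --seed 1 --out census.csv
bedcast diagnose --input census.csv --out-dir diag/
bedcast train    --input census.csv --k auto --out model.joblib
bedcast forecast --model model.joblib --input census.csv \
                 --origin 2017-12-30 --horizon 3 --out forecast.csv
bedcast evaluate --input census.csv --horizon 1 --out-dir eval/
```

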