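"""High-level forecaster objects sharing a common fit/forecast contract.

Each forecaster is constructed with its settings, fitted on a training
census series, and then asked for step-``h`` forecasts anchored so that the
forecast for day ``d`` uses only information available at ``d - h``.  This
is the contract :func:`bedcast.evaluation.evaluate` drives.
"""

from __future__ import annotations

import logging
from typing import Protocol, Sequence, runtime_checkable

import pandas as pd

from .arima import ArimaForecaster, auto_arima, fit_arima
from .census import ALL_DAYS, CensusSeries
from .clustering import TARGET_VALUE, fit_kmeans, select_k_elbow, wss_curve
from .features import build_features
from .ksvr import (
    KSVRError,
    KSVRModel,
    SVMGrid,
    SVRGrid,
    forecast_horizon,
    predict_rows,
    train_ksvr,
)

logger = logging.getLogger(__name__)


@runtime_checkable
class Forecaster(Protocol):
    """Anything evaluate() can score."""

    name: str

    def fit(self, train: CensusSeries) -> None: ...

    def forecast_dates(
        self, series: CensusSeries, target_dates, horizon: int
    ) -> pd.Series: ...


class KSVRForecaster:
    """The full cluster-then-regress pipeline behind one object.

    ``k="auto"`` selects the cluster count from the within-group
    sum-of-squares curve by the elbow rule; an integer fixes it.  ``mode``
    chooses how multi-step forecasts are produced: ``"direct"`` trains the
    model at the requested horizon and builds each feature row in one shot;
    ``"recursive"`` trains at horizon 1 and feeds forecasts back.
    """

    def __init__(
        self,
        horizon: int = 1,
        calendar_mode: str = ALL_DAYS,
        k: int | str = "auto",
        k_max: int = 10,
        lags: Sequence[int] = (1, 2, 3),
        seasonal_lag: int = 7,
        covariate_lag: int = 1,
        covariates: Sequence[str] | None = None,
        seasonal_as_same_weekday: bool = False,
        representation: str = TARGET_VALUE,
        svm_grid: SVMGrid | None = None,
        svr_grid: SVRGrid | None = None,
        cv_folds: int = 10,
        n_init: int = 10,
        min_relative_drop: float = 0.10,
        mode: str = "direct",
        seed: int = 0,
        name: str | None = None,
    ) -> None:
        if mode not in ("direct", "recursive"):
            raise KSVRError(f"unknown mode {mode!r}")
        if k != "auto" and (not isinstance(k, int) or k < 1):
            raise KSVRError("k must be 'auto' or a positive integer")
        self.horizon = horizon
        self.calendar_mode = calendar_mode
        self.k = k
        self.k_max = k_max
        self.lags = tuple(lags)
        self.seasonal_lag = seasonal_lag
        self.covariate_lag = covariate_lag
        self.covariates = covariates
        self.seasonal_as_same_weekday = seasonal_as_same_weekday
        self.representation = representation
        self.svm_grid = svm_grid
        self.svr_grid = svr_grid
        self.cv_folds = cv_folds
        self.n_init = n_init
        self.min_relative_drop = min_relative_drop
        self.mode = mode
        self.seed = seed
        self.name = name or ("K-SVR" if k == "auto" else f"K-SVR({k})")
        self.model_: KSVRModel | None = None
        self.chosen_k_: int | None = None
        self.wss_curve_: list[float] | None = None

    def _build(self, series: CensusSeries, horizon: int):
        return build_features(
            series,
            lags=self.lags,
            seasonal_lag=self.seasonal_lag,
            horizon=horizon,
            covariate_lag=self.covariate_lag,
            covariates=self.covariates,
            seasonal_as_same_weekday=self.seasonal_as_same_weekday,
        )

    def fit(self, train: CensusSeries) -> None:
        if train.calendar_mode != self.calendar_mode:
            raise KSVRError(
                f"training series is {train.calendar_mode!r}, forecaster "
                f"expects {self.calendar_mode!r}"
            )
        train_h = 1 if self.mode == "recursive" else self.horizon
        table = self._build(train, train_h)
        if self.k == "auto":
            curve = wss_curve(
                table, range(1, self.k_max + 1),
                representation=self.representation,
                seed=self.seed, n_init=self.n_init,
            )
            self.wss_curve_ = curve
            k = select_k_elbow(curve, self.min_relative_drop)
            logger.info("%s: elbow selected K=%d", self.name, k)
        else:
            k = int(self.k)
        self.chosen_k_ = k
        clusters = fit_kmeans(
            table, k, representation=self.representation,
            seed=self.seed, n_init=self.n_init,
        )
        self.model_ = train_ksvr(
            table, clusters,
            svm_grid=self.svm_grid, svr_grid=self.svr_grid,
            cv_folds=self.cv_folds, seed=self.seed,
        )

    def _require_fitted(self) -> KSVRModel:
        if self.model_ is None:
            raise KSVRError("forecaster is not fitted")
        return self.model_

    def forecast_dates(
        self, series: CensusSeries, target_dates, horizon: int
    ) -> pd.Series:
        """Step-``horizon`` forecast for each target date.

        Feature rows are built from ``series`` but reference only dates at
        or before each target's forecast origin, so post-origin values
        cannot leak in.
        """
        model = self._require_fitted()
        dates = pd.DatetimeIndex(target_dates)
        if self.mode == "direct":
            if horizon != self.horizon:
                raise KSVRError(
                    f"direct forecaster trained at horizon {self.horizon}, "
                    f"asked for {horizon}"
                )
            table = self._build(series, horizon)
            missing = dates.difference(table.frame.index)
            if len(missing):
                raise KSVRError(
                    "no feature row for target date(s) "
                    f"{[str(d.date()) for d in missing]}"
                )
            rows = table.frame.loc[dates]
            return predict_rows(model, rows)["forecast"]
        out = []
        pos = series.dates.get_indexer(dates)
        if (pos < 0).any():
            raise KSVRError("target date(s) not in series")
        for p in pos:
            if p - horizon < 0:
                raise KSVRError("insufficient history for recursive forecast")
            origin = series.dates[p - horizon]
            fc = forecast_horizon(model, series, origin, horizon,
                                  mode="recursive")
            out.append(float(fc.iloc[-1]))
        return pd.Series(out, index=dates, name="forecast")


class ArimaComparator:
    """The classical comparator: a (seasonal) ARIMA on the demand series."""

    def __init__(
        self,
        order: tuple[int, int, int] | None = None,
        seasonal_period: int | None = None,
        name: str = "ARIMA",
    ) -> None:
        self.order = order
        self.seasonal_period = seasonal_period
        self.name = name
        self.forecaster_: ArimaForecaster | None = None

    def fit(self, train: CensusSeries) -> None:
        if self.order is not None:
            seas = (
                (1, 0, 1, self.seasonal_period) if self.seasonal_period else None
            )
            self.forecaster_ = fit_arima(train, self.order, seasonal_order=seas)
        else:
            self.forecaster_ = auto_arima(
                train, seasonal_period=self.seasonal_period
            )
        logger.info("%s: order %s", self.name, self.forecaster_.order)

    def forecast_dates(
        self, series: CensusSeries, target_dates, horizon: int
    ) -> pd.Series:
        if self.forecaster_ is None:
            raise ValueError("comparator is not fitted")
        return self.forecaster_.forecast_dates(series, target_dates, horizon)


class OracleForecaster:
    """Returns the realized demand; a perfect-forecast reference for tests."""

    def __init__(self, name: str = "oracle") -> None:
        self.name = name

    def fit(self, train: CensusSeries) -> None:  # nothing to learn
        pass

    def forecast_dates(
        self, series: CensusSeries, target_dates, horizon: int
    ) -> pd.Series:
        dates = pd.DatetimeIndex(target_dates)
        return series.demand.loc[dates].astype(float).rename("forecast")
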