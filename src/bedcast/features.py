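"""Predictor engineering for the bed-demand forecaster.

Each forecast of demand for a target date ``d`` at horizon ``h`` is made from
information available at the forecast origin ``d - h``:

* lagged demand ``Dt.k`` = demand ``k - 1`` steps before the origin (so
  ``Dt.1`` is the origin itself — the most recent usable observation),
* a seasonal lag ``Dt.s`` = demand ``s - 1`` steps before the origin
  (``s = 7`` captures the weekly cycle),
* the interaction ``Dt.1.2 = Dt.1 * Dt.2``,
* covariate censuses (medicine ``Mt``, surgical ``Ut``, midnight ``Cen_Mid``)
  at the origin ("yesterday" relative to a 1-day-ahead target).

In all-days mode a step is a calendar day; in weekdays-only mode it is a
position in the business-day sequence, so the Monday forecast at horizon 1
uses Friday as ``Dt.1`` and at horizon 2 uses Thursday.  Rows whose lags
reach before the series start are dropped, never imputed, and no predictor
may come from a date at or after the target's forecast origin's future —
leakage is structurally impossible because every predictor indexes at or
before the origin.

Lag and seasonal choices are guided by the autocorrelation (ACF) and partial
autocorrelation (PACF) diagnostics in :func:`correlogram`, and a greedy
forward pass (:func:`incremental_select`) scores candidate predictor sets by
cross-validated error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .census import (
    WEEKDAYS_ONLY,
    COVARIATE_FEATURE_NAMES,
    COVARIATE_ROLES,
    CensusSeries,
)

INTERACTION = "Dt.1.2"


class FeatureError(ValueError):
    """Raised for invalid predictor-construction requests."""


@dataclass(frozen=True)
class CorrelogramResult:
    """Sample ACF/PACF of a demand series for lags ``0..max_lag``.

    ``acf`` uses the biased sample autocovariance ratio; ``pacf`` the
    Durbin–Levinson recursion on it.  ``acf[0] == pacf[0] == 1``.
    """

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    n: int


@dataclass(frozen=True)
class FeatureTable:
    """Per-day target and predictors at a stated horizon and calendar mode.

    ``frame`` is indexed by target date; its first column is ``target`` and
    the rest are predictors in the order: demand lags, seasonal lag,
    interaction, covariates.
    """

    frame: pd.DataFrame
    horizon: int
    calendar_mode: str
    lags: tuple[int, ...]
    seasonal_lag: int
    covariate_lag: int

    @property
    def target_dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "target"]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["target"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        """Export for audit: target_date first column, then target, predictors."""
        out = self.frame.copy()
        out.insert(0, "target_date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)


def correlogram(series: CensusSeries, max_lag: int) -> CorrelogramResult:
    """ACF and PACF of the demand series for lags ``0..max_lag``.

    The correlogram is the lag-selection diagnostic: a spike in the PACF at
    short lags motivates the autoregressive lags, and the weekly peak in the
    ACF motivates the seasonal lag of 7.
    """
    y = series.demand.to_numpy(dtype=float)
    if max_lag < 1:
        raise FeatureError("max_lag must be >= 1")
    if len(y) <= max_lag + 1:
        raise FeatureError(
            f"series length {len(y)} too short for max_lag {max_lag}"
        )
    if np.ptp(y) == 0:
        raise FeatureError("constant series: autocorrelation undefined")
    acf_vals = _sm_acf(y, nlags=max_lag, adjusted=False, fft=False)
    pacf_vals = _sm_pacf(y, nlags=max_lag, method="ldb")
    return CorrelogramResult(
        lags=np.arange(max_lag + 1),
        acf=np.asarray(acf_vals),
        pacf=np.asarray(pacf_vals),
        n=len(y),
    )


def build_features(
    series: CensusSeries,
    lags: Sequence[int] = (1, 2, 3),
    seasonal_lag: int = 7,
    horizon: int = 1,
    covariate_lag: int = 1,
    covariates: Sequence[str] | None = None,
    seasonal_as_same_weekday: bool = False,
) -> FeatureTable:
    """Build the per-day predictor table for ``horizon``-step-ahead forecasts.

    Parameters
    ----------
    series:
        Input census series; its ``calendar_mode`` decides whether a step is
        a calendar day or a business-day position.
    lags:
        Demand lags ``k`` producing columns ``Dt.k`` = demand ``k - 1`` steps
        before the forecast origin.
    seasonal_lag:
        The seasonal step count ``s`` (column ``Dt.s``, demand ``s - 1``
        steps before the origin).  Must exceed ``max(lags)``.
    horizon:
        Steps ahead being forecast (``>= 1``).
    covariate_lag:
        Steps back from the origin at which covariates enter (1 = at the
        origin, regardless of horizon — "yesterday's" censuses).
    covariates:
        Covariate roles to include (default: all present in the series).
        Requesting an absent covariate raises.
    seasonal_as_same_weekday:
        Weekdays-only mode interprets the seasonal lag positionally by
        default (7 business-day positions back).  With this switch the
        seasonal lag becomes 5 positions — the same weekday one calendar
        week earlier.
    """
    lags = tuple(int(k) for k in lags)
    if not lags or min(lags) < 1:
        raise FeatureError("lags must be a nonempty list of positive ints")
    if seasonal_lag <= max(lags):
        raise FeatureError("seasonal_lag must exceed max(lags)")
    if horizon < 1:
        raise FeatureError("horizon must be >= 1")
    if covariate_lag < 1:
        raise FeatureError("covariate_lag must be >= 1")

    if covariates is None:
        cov_roles = list(series.covariates)
    else:
        cov_roles = list(covariates)
        for role in cov_roles:
            if role not in COVARIATE_ROLES:
                raise FeatureError(f"unknown covariate role {role!r}")
            if role not in series.frame.columns:
                raise FeatureError(
                    f"covariate {role!r} absent from series"
                )

    s_eff = seasonal_lag
    if seasonal_as_same_weekday:
        if series.calendar_mode != WEEKDAYS_ONLY:
            raise FeatureError(
                "seasonal_as_same_weekday applies only to weekdays_only series"
            )
        s_eff = 5

    demand = series.demand.to_numpy(dtype=float)
    n = len(demand)
    max_back = max(max(lags), s_eff, covariate_lag)  # steps back from origin
    p_min = horizon + max_back - 1  # first target position with full history
    if p_min >= n:
        raise FeatureError(
            f"series of length {n} yields no rows at horizon {horizon} "
            f"with max lag {max_back}"
        )
    pos = np.arange(p_min, n)
    origin = pos - horizon

    cols: dict[str, np.ndarray] = {"target": demand[pos]}
    for k in lags:
        cols[f"Dt.{k}"] = demand[origin - (k - 1)]
    seasonal_name = f"Dt.{s_eff}"
    cols[seasonal_name] = demand[origin - (s_eff - 1)]
    if 1 in lags and 2 in lags:
        cols[INTERACTION] = cols["Dt.1"] * cols["Dt.2"]
    for role in cov_roles:
        vals = series.frame[role].to_numpy(dtype=float)
        cols[COVARIATE_FEATURE_NAMES[role]] = vals[origin - (covariate_lag - 1)]

    frame = pd.DataFrame(cols, index=series.dates[pos])
    frame.index.name = "target_date"
    return FeatureTable(
        frame=frame,
        horizon=horizon,
        calendar_mode=series.calendar_mode,
        lags=lags,
        seasonal_lag=s_eff,
        covariate_lag=covariate_lag,
    )


def incremental_select(
    table: FeatureTable,
    candidates: Sequence[str],
    scorer: Callable[[Sequence[str]], float],
    tol: float = 1e-6,
) -> list[str]:
    """Greedy forward predictor selection.

    Starting from the empty model, repeatedly add the candidate that most
    reduces the scorer's cross-validated error; stop when the best marginal
    reduction is ``<= tol``.  Returns the predictors in addition order.
    ``scorer`` must accept any subset of ``candidates`` including the empty
    tuple (conventionally scored by an intercept-only model).
    """
    candidates = list(candidates)
    if not candidates:
        raise FeatureError("candidate list is empty")
    missing = [c for c in candidates if c not in table.frame.columns]
    if missing:
        raise FeatureError(f"candidates not in table: {missing}")

    selected: list[str] = []
    current = float(scorer(()))
    remaining = list(candidates)
    while remaining:
        trials = [(float(scorer(tuple(selected) + (c,))), c) for c in remaining]
        best_err, best_c = min(trials, key=lambda t: t[0])
        if current - best_err <= tol:
            break
        selected.append(best_c)
        remaining.remove(best_c)
        current = best_err
    return selected


def make_cv_scorer(
    table: FeatureTable,
    estimator_factory: Callable[[], object] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
):
    """Default scorer for :func:`incremental_select`: K-fold CV mean absolute error.

    The empty subset is scored by predicting the training-fold mean.  The
    default estimator is a linear regression; pass a factory returning any
    scikit-learn regressor to change it.
    """
    from sklearn.linear_model import LinearRegression
    from sklearn.model_selection import KFold

    y = table.y
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(y))

    def scorer(feature_subset: Sequence[str]) -> float:
        feats = list(feature_subset)
        errs = []
        for tr, te in splits:
            if not feats:
                pred = np.full(len(te), y[tr].mean())
            else:
                X = table.frame[feats].to_numpy(dtype=float)
                est = (estimator_factory or LinearRegression)()
                est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
            errs.append(np.mean(np.abs(y[te] - pred)))
        return float(np.mean(errs))

    return scorer
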