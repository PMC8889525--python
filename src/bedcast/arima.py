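"""ARIMA comparator for the bed-demand forecaster.

A classical (seasonal) ARIMA fitted by maximum likelihood on the training
span.  Orders may be given explicitly or chosen by an AIC-minimizing grid
(p, q in 0..3, d in 0..1; optionally a weekly seasonal term).  Multi-step
forecasts are recursive by construction of the state-space model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA as _SMARIMA
from statsmodels.tsa.stattools import adfuller

from .census import CensusSeries

logger = logging.getLogger(__name__)


class ArimaError(ValueError):
    """Raised when an ARIMA fit is invalid or fails to converge."""


@dataclass
class ArimaForecaster:
    """A fitted ARIMA wrapper exposing origin-anchored forecasts.

    ``forecast_dates`` re-filters the fitted parameters over the demand
    history up to each target's forecast origin, then projects ``horizon``
    steps — so a forecast for day ``d`` at horizon ``h`` uses exactly the
    data through ``d - h``, matching the evaluation protocol of the
    machine-learning models.
    """

    order: tuple[int, int, int]
    seasonal_order: tuple[int, int, int, int] | None
    results: object  # statsmodels ARIMAResults
    train_dates: pd.DatetimeIndex

    def forecast_horizon(self, series: CensusSeries, origin, horizon: int) -> pd.Series:
        """Forecast the ``horizon`` steps after ``origin`` (recursive)."""
        origin = pd.Timestamp(origin)
        hist = series.truncate_to(origin)
        y = hist.demand.to_numpy(dtype=float)
        res = self.results.apply(y)
        fc = np.clip(np.asarray(res.forecast(horizon)), 0.0, None)
        if series.calendar_mode == "all_days":
            idx = pd.date_range(origin, periods=horizon + 1, freq="D")[1:]
        else:
            idx = pd.bdate_range(origin, periods=horizon + 1)[1:]
        return pd.Series(fc, index=idx, name="forecast")

    def forecast_dates(self, series: CensusSeries, target_dates, horizon: int) -> pd.Series:
        """Step-``horizon`` forecast for each target date, each anchored at
        the data available ``horizon`` steps earlier."""
        out = []
        dates = series.dates
        for d in pd.DatetimeIndex(target_dates):
            pos = dates.get_indexer([d])[0]
            if pos < 0:
                raise ArimaError(f"target date {d.date()} not in series")
            origin_pos = pos - horizon
            if origin_pos < 0:
                raise ArimaError(f"no history before {d.date()} at horizon {horizon}")
            y = series.demand.to_numpy(dtype=float)[: origin_pos + 1]
            res = self.results.apply(y)
            out.append(float(np.clip(res.forecast(horizon)[-1], 0.0, None)))
        return pd.Series(out, index=pd.DatetimeIndex(target_dates), name="forecast")


def fit_arima(
    series: CensusSeries,
    order: tuple[int, int, int],
    seasonal_order: tuple[int, int, int, int] | None = None,
) -> ArimaForecaster:
    """Maximum-likelihood ARIMA fit on the demand series.

    Stationarity after ``d`` differences is checked with an augmented
    Dickey-Fuller test and reported as a warning only — short hospital
    series often fail the test without harming the comparator's role.
    """
    if any(o < 0 for o in order):
        raise ArimaError("order components must be >= 0")
    y = series.demand.to_numpy(dtype=float)
    p, d, q = order
    if p + q + d >= len(y):
        raise ArimaError(
            f"order {order} too large for a series of {len(y)} points"
        )
    if d <= 2 and len(y) > 20:
        yd = np.diff(y, n=d) if d else y
        try:
            pval = adfuller(yd, autolag="AIC")[1]
            if pval > 0.05:
                warnings.warn(
                    f"series may be non-stationary after {d} difference(s) "
                    f"(ADF p={pval:.3f})",
                    UserWarning,
                    stacklevel=2,
                )
        except Exception:  # pragma: no cover - diagnostic only
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = _SMARIMA(
            y,
            order=order,
            seasonal_order=seasonal_order or (0, 0, 0, 0),
        )
        try:
            results = model.fit()
        except Exception as exc:  # optimizer failures surface with context
            raise ArimaError(f"ARIMA{order} failed to converge: {exc}") from exc
    if not np.all(np.isfinite(results.params)):
        raise ArimaError(f"ARIMA{order} produced non-finite parameters")
    return ArimaForecaster(
        order=order,
        seasonal_order=seasonal_order,
        results=results,
        train_dates=series.dates,
    )


def auto_arima(
    series: CensusSeries,
    p_range: Sequence[int] = (0, 1, 2, 3),
    d_range: Sequence[int] = (0, 1),
    q_range: Sequence[int] = (0, 1, 2, 3),
    seasonal_period: int | None = None,
) -> ArimaForecaster:
    """AIC-minimizing order selection over a small grid.

    ``seasonal_period`` (e.g. 7 for a weekly cycle) adds a (1, 0, 1, m)
    seasonal term to each candidate; default is non-seasonal.  The chosen
    order is logged.
    """
    best: tuple[float, ArimaForecaster] | None = None
    for p, d, q in product(p_range, d_range, q_range):
        seas = (1, 0, 1, seasonal_period) if seasonal_period else None
        try:
            fc = fit_arima(series, (p, d, q), seasonal_order=seas)
        except ArimaError:
            continue
        aic = float(fc.results.aic)
        if np.isfinite(aic) and (best is None or aic < best[0]):
            best = (aic, fc)
    if best is None:
        raise ArimaError("no candidate ARIMA order converged")
    fc = best[1]
    logger.info("auto ARIMA selected order %s (AIC %.1f)", fc.order, best[0])
    return fc
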