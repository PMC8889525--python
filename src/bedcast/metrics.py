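"""Forecast performance measures.

All four measures compare a vector of realized daily bed demands ``Y_r``
with the corresponding forecasts ``Y_f``:

* MAPE — mean of ``|Y_r - Y_f| / Y_r``, reported in percent,
* MAE  — mean absolute error, in beds/day,
* RMSE — root mean squared error, in beds/day,
* error variance — sample variance (N-1 denominator) of the per-day
  relative errors ``|Y_r - Y_f| / Y_r`` (dimensionless); a variability
  companion to MAPE, small values meaning the percentage error is stable
  across days.
"""

from __future__ import annotations

import numpy as np


class MetricError(ValueError):
    """Raised for undefined metric requests (length mismatch, zero demand)."""


def _validate(real, forecast, require_positive: bool = False):
    r = np.asarray(real, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if r.shape != f.shape or r.ndim != 1:
        raise MetricError(
            f"real and forecast must be equal-length vectors, got "
            f"{r.shape} and {f.shape}"
        )
    if r.size == 0:
        raise MetricError("empty vectors")
    if require_positive and np.any(r <= 0):
        raise MetricError("real demand must be positive (relative error undefined)")
    return r, f


def mape(real, forecast) -> float:
    """Mean absolute percentage error, in percent."""
    r, f = _validate(real, forecast, require_positive=True)
    return float(np.mean(np.abs(r - f) / r) * 100.0)


def mae(real, forecast) -> float:
    """Mean absolute error, in beds per day."""
    r, f = _validate(real, forecast)
    return float(np.mean(np.abs(r - f)))


def rmse(real, forecast) -> float:
    """Root mean squared error, in beds per day."""
    r, f = _validate(real, forecast)
    return float(np.sqrt(np.mean((r - f) ** 2)))


def error_variance(real, forecast) -> float:
    """Sample variance of the per-day relative errors ``|Y_r - Y_f| / Y_r``."""
    r, f = _validate(real, forecast, require_positive=True)
    if r.size < 2:
        raise MetricError("error variance needs at least 2 points")
    rel = np.abs(r - f) / r
    return float(np.var(rel, ddof=1))
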