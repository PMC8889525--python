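import numpy as np
import pandas as pd
import pytest

from bedcast.census import ALL_DAYS, CensusSeries


def make_series(
    demand,
    start="2020-01-06",  # a Monday
    covariates: bool = False,
    calendar_mode: str = ALL_DAYS,
) -> CensusSeries:
    """Build a small validated census series from a demand vector."""
    demand = np.asarray(demand, dtype=np.int64)
    dates = pd.date_range(start, periods=len(demand), freq="D")
    data = {"demand": demand}
    if covariates:
        data["medicine_census"] = (demand * 0.45).astype(np.int64)
        data["surgical_census"] = (demand * 0.25).astype(np.int64)
        data["midnight_census"] = (demand * 0.95).astype(np.int64)
    frame = pd.DataFrame(data, index=dates)
    if calendar_mode != ALL_DAYS:
        frame = frame[frame.index.dayofweek < 5]
    return CensusSeries(frame, calendar_mode)


@pytest.fixture
def periodic_series() -> CensusSeries:
    """20 exact weekly cycles, distinct level per weekday, starting Monday."""
    week = [310, 320, 330, 325, 315, 295, 290]
    return make_series(week * 20)


@pytest.fixture
def noisy_series() -> CensusSeries:
    """A year of weekly-seasonal demand with reproducible noise."""
    rng = np.random.default_rng(42)
    week = np.array([5, 12, 15, 12, 0, -22, -25])
    n = 364
    demand = 340 + week[np.arange(n) % 7] + rng.normal(0, 8, n)
    return make_series(np.clip(np.round(demand), 0, None), covariates=True)
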