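"""Daily census series: domain type, CSV ingestion/validation, calendar views.

The engine's raw input is one row per calendar date with total inpatient bed
demand (census plus patients boarded elsewhere awaiting a bed) and up to three
covariate censuses: the medicine census, the surgical census and the total
12AM (midnight) census.  Dates are the primary key everywhere; positional
indices never cross module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

ALL_DAYS = "all_days"
WEEKDAYS_ONLY = "weekdays_only"

#: covariate roles, in canonical order; the demand column is always required
COVARIATE_ROLES = ("medicine_census", "surgical_census", "midnight_census")

#: role -> predictor-table column name (medicine, surgical, midnight census)
COVARIATE_FEATURE_NAMES = {
    "medicine_census": "Mt",
    "surgical_census": "Ut",
    "midnight_census": "Cen_Mid",
}


class CensusValidationError(ValueError):
    """Raised when a census table violates a calendar or value invariant."""


@dataclass(frozen=True)
class CensusSeries:
    """A validated daily bed-demand series.

    Parameters
    ----------
    frame:
        DataFrame indexed by a strictly increasing ``DatetimeIndex`` (one row
        per day), with an integer ``demand`` column and any subset of the
        optional integer covariate columns ``medicine_census``,
        ``surgical_census``, ``midnight_census``.
    calendar_mode:
        ``"all_days"`` (consecutive calendar days) or ``"weekdays_only"``
        (Saturdays/Sundays removed; gaps over weekends are expected).
    """

    frame: pd.DataFrame
    calendar_mode: str = ALL_DAYS

    def __post_init__(self) -> None:
        if self.calendar_mode not in (ALL_DAYS, WEEKDAYS_ONLY):
            raise CensusValidationError(
                f"unknown calendar_mode {self.calendar_mode!r}"
            )
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise CensusValidationError("index must be a DatetimeIndex")
        if len(idx) == 0:
            raise CensusValidationError("series is empty")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise CensusValidationError(f"duplicate date: {dup.date()}")
        if not idx.is_monotonic_increasing:
            raise CensusValidationError("dates must be strictly increasing")
        if "demand" not in self.frame.columns:
            raise CensusValidationError("missing required column 'demand'")
        unknown = set(self.frame.columns) - {"demand", *COVARIATE_ROLES}
        if unknown:
            raise CensusValidationError(f"unknown columns: {sorted(unknown)}")
        if self.calendar_mode == ALL_DAYS:
            gaps = pd.date_range(idx[0], idx[-1], freq="D").difference(idx)
            if len(gaps):
                shown = ", ".join(str(d.date()) for d in gaps[:5])
                raise CensusValidationError(
                    f"calendar gap: {len(gaps)} missing date(s): {shown}"
                )
        else:
            weekend = idx[idx.dayofweek >= 5]
            if len(weekend):
                raise CensusValidationError(
                    f"weekend date in weekdays_only series: {weekend[0].date()}"
                )
        for col in self.frame.columns:
            vals = self.frame[col]
            if not np.issubdtype(vals.dtype, np.number):
                raise CensusValidationError(f"column {col!r} is not numeric")
            arr = vals.to_numpy()
            if not np.all(np.isfinite(arr)):
                raise CensusValidationError(f"non-finite value in {col!r}")
            if (arr < 0).any():
                bad = idx[arr < 0][0]
                raise CensusValidationError(
                    f"negative {col} on {bad.date()}"
                )

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def demand(self) -> pd.Series:
        return self.frame["demand"]

    @property
    def covariates(self) -> tuple[str, ...]:
        """Covariate roles actually present in this series."""
        return tuple(c for c in COVARIATE_ROLES if c in self.frame.columns)

    def truncate_to(self, last_date) -> "CensusSeries":
        """Return the prefix of the series with dates <= ``last_date``."""
        sub = self.frame.loc[: pd.Timestamp(last_date)]
        if sub.empty:
            raise CensusValidationError(f"no dates on or before {last_date}")
        return CensusSeries(sub, self.calendar_mode)

    def write_csv(self, path: str | Path) -> None:
        """Write the series in the canonical CSV format (ISO dates, ints)."""
        out = self.frame.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)


def load_census(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> CensusSeries:
    """Load and validate a daily census CSV into all-days mode.

    The file must have a header row with a ``date`` column (ISO-8601) and a
    ``demand`` column; the three covariate columns are optional and recorded
    as absent (not zero-filled) when missing.  ``column_map`` maps the roles
    ``date``/``demand``/``medicine_census``/``surgical_census``/
    ``midnight_census`` to the file's actual header names.

    Raises :class:`CensusValidationError` naming the offending date for
    duplicates and gaps, or the 1-based data-row number for a negative or
    non-numeric census value.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]

    def header(role: str) -> str | None:
        name = column_map.get(role, role)
        return name if name in raw.columns else None

    date_col = header("date")
    demand_col = header("demand")
    if date_col is None or demand_col is None:
        raise CensusValidationError(
            f"CSV must contain date and demand columns (have {list(raw.columns)})"
        )

    data: dict[str, np.ndarray] = {}
    roles = [("demand", demand_col)] + [
        (r, h) for r in COVARIATE_ROLES if (h := header(r)) is not None
    ]
    for role, col in roles:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() | ~np.isfinite(parsed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CensusValidationError(
                f"non-numeric or missing {role} value {raw[col][bad].iloc[0]!r} "
                f"on row {row}"
            )
        neg = parsed < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 1
            raise CensusValidationError(
                f"negative {role} value {parsed[neg].iloc[0]} on row {row}"
            )
        data[role] = parsed.to_numpy()

    dates = pd.to_datetime(raw[date_col], format="%Y-%m-%d")
    frame = pd.DataFrame(data, index=pd.DatetimeIndex(dates.values))
    for col in frame.columns:  # bed counts are integers when they can be
        arr = frame[col].to_numpy()
        if np.all(arr == np.round(arr)):
            frame[col] = arr.astype(np.int64)
    return CensusSeries(frame, ALL_DAYS)


def restrict_to_weekdays(series: CensusSeries) -> CensusSeries:
    """Drop Saturday/Sunday rows, switching the series to weekdays-only mode.

    The weekday-only view re-indexes every downstream lag over business-day
    positions (Friday is the business day before Monday).  Re-restricting an
    already weekday-only series is a caller bug and raises.
    """
    if series.calendar_mode != ALL_DAYS:
        raise CensusValidationError(
            "series is already weekdays_only; restrict_to_weekdays expects all_days"
        )
    keep = series.frame.index.dayofweek < 5
    return CensusSeries(series.frame[keep], WEEKDAYS_ONLY)
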