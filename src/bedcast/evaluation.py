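"""Test-week evaluation protocol.

Models are trained on the chronological first 70% of the series and scored
on four non-overlapping, non-adjacent test weeks drawn from the remaining
30% — per-day forecasts at the stated horizon, with MAPE, MAE, RMSE and the
error variance reported per (model, week) plus a cross-week average.  The
training and testing spans never overlap; a test week that lacks a
forecastable day aborts the report rather than silently trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import ALL_DAYS, WEEKDAYS_ONLY, CensusSeries, restrict_to_weekdays
from .metrics import error_variance, mae, mape, rmse

METRIC_FUNCS = {
    "MAPE (%)": mape,
    "MAE (bed/day)": mae,
    "RMSE (bed/day)": rmse,
    "Error variance": error_variance,
}


class EvaluationError(ValueError):
    """Raised when the test-week protocol is violated."""


@dataclass(frozen=True)
class EvaluationReport:
    """Per-test-week forecasts and performance measures for each model.

    ``metrics`` is indexed by (metric, model) with columns ``Week 1..n`` and
    ``Average`` (the mean of the per-week metric values).  ``vectors`` maps
    ``(model, week_number)`` to the (real, forecast) pair used.
    """

    metrics: pd.DataFrame
    vectors: Mapping[tuple[str, int], tuple[pd.Series, pd.Series]]
    test_weeks: tuple[pd.DatetimeIndex, ...]
    horizon: int
    calendar_mode: str

    def to_csv(self, path: str | Path) -> None:
        out = self.metrics.reset_index()
        out.columns = ["Metric", "Model", *self.metrics.columns]
        out.to_csv(path, index=False)

    def to_text(self) -> str:
        """Aligned table: metric x model rows, week + average columns."""
        lines = [
            f"{self.horizon}-day ahead, "
            + ("with weekend data" if self.calendar_mode == ALL_DAYS
               else "without weekend data")
        ]
        df = self.metrics.copy()
        formatted = df.map(
            lambda v: f"{v:.2E}" if abs(v) < 0.01 else f"{v:.2f}"
        )
        header = f"{'Metric':<16}{'Model':<12}" + "".join(
            f"{c:>12}" for c in df.columns
        )
        lines.append(header)
        lines.append("-" * len(header))
        for (metric, model), row in formatted.iterrows():
            lines.append(
                f"{metric:<16}{model:<12}" + "".join(f"{v:>12}" for v in row)
            )
        return "\n".join(lines)


def select_test_weeks(
    series: CensusSeries,
    n_weeks: int = 4,
    train_frac: float = 0.7,
) -> list[pd.DatetimeIndex]:
    """Pick ``n_weeks`` evenly spaced, non-adjacent Monday-start weeks from
    the held-out final span of the series.

    A week is 7 consecutive calendar days in all-days mode and the 5
    business days Monday-Friday in weekdays-only mode.
    """
    week_len = 7 if series.calendar_mode == ALL_DAYS else 5
    n = len(series)
    train_n = int(np.ceil(train_frac * n))
    test_dates = series.dates[train_n:]
    candidates = []
    for i, d in enumerate(test_dates):
        if d.dayofweek == 0 and i + week_len <= len(test_dates):
            block = test_dates[i : i + week_len]
            if series.calendar_mode == ALL_DAYS:
                if (block[-1] - block[0]).days == week_len - 1:
                    candidates.append(block)
            else:
                if all(dd.dayofweek == j for j, dd in enumerate(block)):
                    candidates.append(block)
    # non-adjacent: keep at least one full week between chosen week starts
    if len(candidates) < n_weeks:
        raise EvaluationError(
            f"test span has only {len(candidates)} candidate weeks, "
            f"need {n_weeks}"
        )
    picks: list[pd.DatetimeIndex] = []
    for j in np.linspace(0, len(candidates) - 1, n_weeks).round().astype(int):
        picks.append(candidates[j])
    starts = [w[0] for w in picks]
    if len(set(starts)) < n_weeks or any(
        (b - a).days < 14 for a, b in zip(starts, starts[1:])
    ):
        raise EvaluationError(
            "test span too short to place non-adjacent test weeks"
        )
    return picks


def select_shared_test_weeks(
    series: CensusSeries,
    n_weeks: int = 4,
    train_frac: float = 0.7,
) -> list[pd.Timestamp]:
    """Monday start dates usable as test weeks in *both* calendar modes.

    Model variants are compared on the same test weeks, so the weeks must
    lie in the held-out span of the all-days series and of its
    weekday-restricted view, and leave a full 7 calendar days before the
    series end.  Returns ``n_weeks`` evenly spaced, non-adjacent starts.
    """
    if series.calendar_mode != ALL_DAYS:
        raise EvaluationError("shared test weeks start from an all_days series")
    wk = restrict_to_weekdays(series)
    boundary = max(
        series.dates[int(np.ceil(train_frac * len(series))) - 1],
        wk.dates[int(np.ceil(train_frac * len(wk))) - 1],
    )
    candidates = [
        d for d in series.dates
        if d.dayofweek == 0 and d > boundary
        and d + pd.Timedelta(days=6) <= series.dates[-1]
    ]
    if len(candidates) < n_weeks:
        raise EvaluationError(
            f"only {len(candidates)} candidate shared weeks, need {n_weeks}"
        )
    picks = [candidates[j] for j in
             np.linspace(0, len(candidates) - 1, n_weeks).round().astype(int)]
    if len(set(picks)) < n_weeks or any(
        (b - a).days < 14 for a, b in zip(picks, picks[1:])
    ):
        raise EvaluationError(
            "test span too short to place non-adjacent shared test weeks"
        )
    return picks


def evaluate(
    models: Sequence,
    series: CensusSeries,
    horizon: int = 1,
    calendar_mode: str = ALL_DAYS,
    test_weeks: Sequence | None = None,
    train_frac: float = 0.7,
    n_weeks: int = 4,
) -> EvaluationReport:
    """Run the test-week protocol for a list of fitted-from-scratch models.

    ``models`` are :class:`~bedcast.pipeline.Forecaster`-like objects; each
    is trained here on the first ``train_frac`` of the (possibly
    weekday-restricted) series and asked for per-day step-``horizon``
    forecasts over every test week.  ``test_weeks`` may be given as week
    start dates; by default four evenly spaced weeks are drawn from the
    held-out span.
    """
    if calendar_mode == WEEKDAYS_ONLY and series.calendar_mode == ALL_DAYS:
        work = restrict_to_weekdays(series)
    elif calendar_mode == series.calendar_mode:
        work = series
    else:
        raise EvaluationError(
            f"cannot evaluate a {series.calendar_mode!r} series in "
            f"{calendar_mode!r} mode"
        )

    n = len(work)
    train_n = int(np.ceil(train_frac * n))
    train = CensusSeries(work.frame.iloc[:train_n], work.calendar_mode)
    train_end = train.dates[-1]
    week_len = 7 if calendar_mode == ALL_DAYS else 5

    if test_weeks is None:
        weeks = select_test_weeks(work, n_weeks=n_weeks, train_frac=train_frac)
    else:
        weeks = []
        for w in test_weeks:
            if isinstance(w, pd.DatetimeIndex):
                weeks.append(w)
                continue
            start = pd.Timestamp(w)
            pos = work.dates.get_indexer([start])[0]
            if pos < 0 or pos + week_len > n:
                raise EvaluationError(f"test week starting {start.date()} "
                                      "not fully inside the series")
            weeks.append(work.dates[pos : pos + week_len])

    seen: set[pd.Timestamp] = set()
    for w in weeks:
        if len(w) != week_len:
            raise EvaluationError(
                f"test week starting {w[0].date()} has {len(w)} days, "
                f"expected {week_len}"
            )
        if w[0] <= train_end:
            raise EvaluationError(
                f"test week starting {w[0].date()} overlaps the training "
                f"span (ends {train_end.date()})"
            )
        overlap = seen.intersection(w)
        if overlap:
            raise EvaluationError(
                f"test weeks overlap on {sorted(d.date() for d in overlap)}"
            )
        seen.update(w)

    vectors: dict[tuple[str, int], tuple[pd.Series, pd.Series]] = {}
    rows: dict[tuple[str, str], list[float]] = {}
    for model in models:
        model.fit(train)
        for wi, week in enumerate(weeks, start=1):
            forecast = model.forecast_dates(work, week, horizon)
            if forecast.isna().any() or len(forecast) != week_len:
                raise EvaluationError(
                    f"model {model.name!r} failed to forecast every day of "
                    f"week {wi}"
                )
            real = work.demand.loc[week].astype(float)
            vectors[(model.name, wi)] = (real, forecast)
            for metric, func in METRIC_FUNCS.items():
                rows.setdefault((metric, model.name), []).append(
                    func(real.to_numpy(), forecast.to_numpy())
                )

    cols = [f"Week {i}" for i in range(1, len(weeks) + 1)]
    metrics = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    metrics.index = pd.MultiIndex.from_tuples(
        metrics.index, names=["metric", "model"]
    )
    metrics["Average"] = metrics[cols].mean(axis=1)
    return EvaluationReport(
        metrics=metrics,
        vectors=vectors,
        test_weeks=tuple(pd.DatetimeIndex(w) for w in weeks),
        horizon=horizon,
        calendar_mode=calendar_mode,
    )
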