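"""Predictor construction, correlogram diagnostics and forward selection."""

import numpy as np
import pandas as pd
import pytest

from bedcast.census import CensusSeries, restrict_to_weekdays
from bedcast.features import (
    FeatureError,
    build_features,
    correlogram,
    incremental_select,
    make_cv_scorer,
)
from .conftest import make_series


class TestCorrelogram:
    def test_weekly_sinusoid_peaks_at_lag_7(self):
        t = np.arange(700)
        demand = np.round(300 + 50 * np.sin(2 * np.pi * t / 7)).astype(int)
        cg = correlogram(make_series(demand), max_lag=14)
        assert cg.acf[0] == pytest.approx(1.0)
        assert np.argmax(cg.acf[1:15]) + 1 in (7, 14)
        assert cg.acf[14] == pytest.approx(cg.acf[7], abs=0.05)

    def test_ar1_pacf_matches_closed_form(self):
        # PACF of an AR(1) is phi at lag 1 and 0 beyond
        rng = np.random.default_rng(7)
        n = 5000
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = 0.8 * x[i - 1] + rng.normal()
        series = make_series(np.round(300 + 10 * x).clip(0))
        cg = correlogram(series, max_lag=10)
        assert cg.pacf[1] == pytest.approx(0.8, abs=0.05)
        assert np.all(np.abs(cg.pacf[2:]) < 0.05)

    def test_white_noise_acf_within_null_band(self):
        rng = np.random.default_rng(11)
        series = make_series(np.round(300 + 10 * rng.normal(size=5000)))
        cg = correlogram(series, max_lag=20)
        assert np.all(np.abs(cg.acf[1:]) < 3 / np.sqrt(cg.n))

    def test_magnitudes_bounded_by_one(self, noisy_series):
        cg = correlogram(noisy_series, max_lag=21)
        assert np.all(np.abs(cg.acf) <= 1 + 1e-9)
        assert np.all(np.abs(cg.pacf) <= 1 + 1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(FeatureError, match="constant"):
            correlogram(make_series([300] * 50), max_lag=5)

    def test_max_lag_too_large_rejected(self):
        with pytest.raises(FeatureError):
            correlogram(make_series(np.arange(10) + 300), max_lag=9)


class TestBuildFeatures:
    def test_hand_indexed_toy_vector(self):
        # Mon..Mon, demand 10..80
        series = make_series([10, 20, 30, 40, 50, 60, 70, 80])
        table = build_features(series, lags=[1, 2, 3], seasonal_lag=7,
                               horizon=1)
        assert len(table) == 1
        row = table.frame.iloc[0]
        assert row["target"] == 80
        assert row["Dt.1"] == 70
        assert row["Dt.2"] == 60
        assert row["Dt.3"] == 50
        assert row["Dt.7"] == 10
        assert row["Dt.1.2"] == 4200

    def test_weekday_monday_horizon1_uses_friday(self, periodic_series):
        wk = restrict_to_weekdays(periodic_series)
        table = build_features(wk, horizon=1)
        mondays = table.frame[table.frame.index.dayofweek == 0]
        for monday, row in mondays.iterrows():
            friday = monday - pd.Timedelta(days=3)
            assert row["Dt.1"] == wk.demand.loc[friday]

    def test_weekday_monday_horizon2_uses_thursday(self, periodic_series):
        wk = restrict_to_weekdays(periodic_series)
        table = build_features(wk, horizon=2)
        mondays = table.frame[table.frame.index.dayofweek == 0]
        assert len(mondays)
        for monday, row in mondays.iterrows():
            thursday = monday - pd.Timedelta(days=4)
            assert row["Dt.1"] == wk.demand.loc[thursday]

    def test_horizon_shift_identity(self, noisy_series):
        t1 = build_features(noisy_series, horizon=1)
        t2 = build_features(noisy_series, horizon=2)
        shared = t1.frame.index.intersection(t2.frame.index)
        assert len(shared) > 300
        np.testing.assert_array_equal(
            t2.frame.loc[shared, "Dt.1"], t1.frame.loc[shared, "Dt.2"]
        )

    def test_interaction_is_exact_product(self, noisy_series):
        table = build_features(noisy_series)
        np.testing.assert_array_equal(
            table.frame["Dt.1.2"],
            table.frame["Dt.1"] * table.frame["Dt.2"],
        )

    def test_no_leakage_from_post_origin_values(self, noisy_series):
        table = build_features(noisy_series, horizon=1)
        target = table.frame.index[50]
        origin = target - pd.Timedelta(days=1)
        tampered = noisy_series.frame.copy()
        after = tampered.index > origin
        rng = np.random.default_rng(0)
        tampered.loc[after, "demand"] = rng.integers(0, 1000, int(after.sum()))
        t2 = build_features(CensusSeries(tampered), horizon=1)
        pd.testing.assert_series_equal(
            table.frame.loc[target].drop("target"),
            t2.frame.loc[target].drop("target"),
        )

    def test_short_lags_drop_rows_never_impute(self):
        series = make_series(np.arange(10) + 300)
        table = build_features(series, lags=[1, 2, 3], seasonal_lag=7,
                               horizon=1)
        # first 7 positions lack the seasonal lag: 10 - 7 = 3 rows survive
        assert len(table) == 3
        assert not table.frame.isna().any().any()

    def test_covariates_enter_at_the_origin(self, noisy_series):
        table = build_features(noisy_series, horizon=1)
        target = table.frame.index[10]
        origin = target - pd.Timedelta(days=1)
        assert table.frame.loc[target, "Mt"] == (
            noisy_series.frame.loc[origin, "medicine_census"]
        )

    def test_absent_covariate_is_an_error(self):
        series = make_series(np.arange(20) + 300)  # no covariates
        with pytest.raises(FeatureError, match="medicine_census"):
            build_features(series, covariates=["medicine_census"])

    def test_too_short_series_is_an_error(self):
        with pytest.raises(FeatureError, match="no rows"):
            build_features(make_series([300] * 7), horizon=1)

    def test_csv_export_round_trip(self, tmp_path, noisy_series):
        table = build_features(noisy_series)
        out = tmp_path / "features.csv"
        table.to_csv(out)
        back = pd.read_csv(out)
        assert list(back.columns)[:2] == ["target_date", "target"]
        assert len(back) == len(table)


class TestIncrementalSelect:
    @staticmethod
    def _table_with(noise_col=False):
        rng = np.random.default_rng(3)
        demand = np.round(300 + 30 * rng.standard_normal(200)).clip(0)
        series = make_series(demand)
        table = build_features(series, horizon=1)
        if noise_col:
            frame = table.frame.copy()
            frame["noise"] = rng.standard_normal(len(frame))
            table = type(table)(frame, table.horizon, table.calendar_mode,
                                table.lags, table.seasonal_lag,
                                table.covariate_lag)
        return table

    def test_exact_linear_target_selects_only_its_predictor(self):
        table = self._table_with(noise_col=True)
        frame = table.frame.copy()
        frame["target"] = 2.0 * frame["Dt.1"] + 5.0
        table = type(table)(frame, table.horizon, table.calendar_mode,
                            table.lags, table.seasonal_lag,
                            table.covariate_lag)
        scorer = make_cv_scorer(table, seed=0)
        selected = incremental_select(table, ["Dt.1", "noise"], scorer)
        assert selected == ["Dt.1"]

    def test_two_term_target_selects_both_in_oracle_order(self):
        table = self._table_with()
        frame = table.frame.copy()
        frame["target"] = frame["Dt.1"] + frame["Dt.7"]
        table = type(table)(frame, table.horizon, table.calendar_mode,
                            table.lags, table.seasonal_lag,
                            table.covariate_lag)
        scorer = make_cv_scorer(table, seed=0)
        selected = incremental_select(table, ["Dt.1", "Dt.7"], scorer)
        # brute-force oracle over all four subsets
        errs = {sub: scorer(sub) for sub in
                [(), ("Dt.1",), ("Dt.7",), ("Dt.1", "Dt.7")]}
        first = min([("Dt.1",), ("Dt.7",)], key=errs.get)[0]
        assert selected == [first, {"Dt.1": "Dt.7", "Dt.7": "Dt.1"}[first]]
        assert errs[("Dt.1", "Dt.7")] < min(errs[("Dt.1",)], errs[("Dt.7",)])

    def test_infinite_tolerance_selects_nothing(self, noisy_series):
        table = build_features(noisy_series)
        scorer = make_cv_scorer(table, seed=0)
        assert incremental_select(table, table.feature_names, scorer,
                                  tol=np.inf) == []

    def test_empty_candidates_is_an_error(self, noisy_series):
        table = build_features(noisy_series)
        with pytest.raises(FeatureError, match="empty"):
            incremental_select(table, [], lambda s: 0.0)
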