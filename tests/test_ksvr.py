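"""The two-stage forecaster: routing, local regression, multi-step forecasts."""

import numpy as np
import pandas as pd
import pytest

from bedcast.census import CensusSeries
from bedcast.clustering import fit_kmeans
from bedcast.features import build_features
from bedcast.ksvr import (
    KSVRError,
    SVRGrid,
    forecast_horizon,
    load_model,
    predict_one,
    predict_rows,
    save_model,
    train_ksvr,
    train_svr,
)
from .conftest import make_series


def two_regime_series(n_weeks=40, seed=1):
    """Alternating blocks of ~100-bed and ~400-bed demand (disjoint ranges)."""
    rng = np.random.default_rng(seed)
    blocks = []
    for i in range(n_weeks):
        level = 100 if i % 2 == 0 else 400
        blocks.append(level + rng.integers(-1, 2, 7))
    return make_series(np.concatenate(blocks))


@pytest.fixture(scope="module")
def separable_model():
    series = two_regime_series()
    table = build_features(series, horizon=1)
    clusters = fit_kmeans(table, K=2, seed=0)
    model = train_ksvr(table, clusters, cv_folds=5, seed=0)
    return series, table, clusters, model


class TestTrainKSVR:
    def test_k1_collapses_to_plain_svr(self, noisy_series):
        table = build_features(noisy_series)
        clusters = fit_kmeans(table, K=1, seed=0)
        ksvr = train_ksvr(table, clusters, cv_folds=5, seed=0)
        plain = train_svr(table, cv_folds=5, seed=0)
        a = predict_rows(ksvr, table.frame)["forecast"].to_numpy()
        b = plain.predict(table.X)
        np.testing.assert_array_equal(a, b)
        assert ksvr.regressors[0].best_params == plain.tuned.best_params

    def test_separable_clusters_are_learned(self, separable_model):
        _, table, clusters, model = separable_model
        routed = predict_rows(model, table.frame)
        # classifier routes every training row to its own cluster
        assert (routed["cluster"].to_numpy() == clusters.labels).all()
        for log in model.tuning_log["svr"].values():
            assert log["cv_mae"] < 2.0

    def test_fresh_high_regime_row_forecast(self, separable_model):
        _, table, _, model = separable_model
        high = table.frame[table.frame["target"] > 300].iloc[0].copy()
        high[:] = high[:] + 1  # nearby but unseen
        high["Dt.1.2"] = high["Dt.1"] * high["Dt.2"]
        pred = predict_one(model, high.drop("target"))
        assert 390 <= pred.forecast <= 410
        assert pred.cluster == int(
            predict_rows(model, table.frame[table.frame["target"] > 300])[
                "cluster"
            ].mode()[0]
        )

    def test_singleton_cluster_is_an_error(self):
        table = build_features(make_series(
            np.r_[[300] * 7, [300] * 10, [800]]), horizon=1)
        clusters = fit_kmeans(table, K=2, seed=0)
        with pytest.raises(KSVRError, match="cluster \\d"):
            train_ksvr(table, clusters, cv_folds=2, seed=0)

    def test_label_row_mismatch_is_an_error(self, noisy_series):
        table = build_features(noisy_series)
        clusters = fit_kmeans(table, K=2, seed=0)
        short = build_features(noisy_series.truncate_to(
            noisy_series.dates[100]))
        with pytest.raises(KSVRError, match="labels"):
            train_ksvr(short, clusters)

    def test_determinism(self, noisy_series):
        table = build_features(noisy_series)
        clusters = fit_kmeans(table, K=3, seed=2)
        m1 = train_ksvr(table, clusters, cv_folds=5, seed=2)
        m2 = train_ksvr(table, clusters, cv_folds=5, seed=2)
        np.testing.assert_array_equal(
            predict_rows(m1, table.frame)["forecast"],
            predict_rows(m2, table.frame)["forecast"],
        )
        assert m1.tuning_log == m2.tuning_log


class TestPredict:
    def test_missing_feature_column_is_an_error(self, separable_model):
        _, table, _, model = separable_model
        row = table.frame.iloc[0].drop(["target", "Dt.7"])
        with pytest.raises(KSVRError, match="Dt.7"):
            predict_one(model, row)

    def test_forecast_clipped_at_zero(self, separable_model):
        # absurd inputs cannot produce a negative bed count
        _, table, _, model = separable_model
        row = table.frame.iloc[0].drop("target") * 0.0
        assert predict_one(model, row).forecast >= 0.0


class TestForecastHorizon:
    def test_modes_coincide_at_horizon_1(self, separable_model):
        series, _, _, model = separable_model
        origin = series.dates[-10]
        rec = forecast_horizon(model, series, origin, 1, mode="recursive")
        direct = forecast_horizon(model, series, origin, 1, mode="direct")
        pd.testing.assert_series_equal(rec, direct)

    def test_direct_mode_horizon_mismatch_is_an_error(self, separable_model):
        series, _, _, model = separable_model
        with pytest.raises(KSVRError, match="direct"):
            forecast_horizon(model, series, series.dates[-5], 2, mode="direct")

    def test_no_leakage_after_origin(self, separable_model):
        series, _, _, model = separable_model
        origin = series.dates[-30]
        base = forecast_horizon(model, series, origin, 3)
        tampered = series.frame.copy()
        after = tampered.index > origin
        tampered.loc[after, "demand"] = 999
        t_series = CensusSeries(tampered)
        pd.testing.assert_series_equal(
            base, forecast_horizon(model, t_series, origin, 3)
        )

    def test_insufficient_history_is_an_error(self, separable_model):
        series, _, _, model = separable_model
        short = CensusSeries(series.frame.iloc[:3])
        with pytest.raises(KSVRError, match="insufficient history"):
            forecast_horizon(model, short, short.dates[-1], 1)

    def test_recursive_feeds_forecasts_back(self, separable_model):
        series, _, _, model = separable_model
        origin = series.dates[-10]
        fc = forecast_horizon(model, series, origin, 4, mode="recursive")
        assert len(fc) == 4
        assert (fc.index == pd.date_range(origin, periods=5, freq="D")[1:]).all()


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, separable_model):
        series, table, _, model = separable_model
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(
            predict_rows(model, table.frame)["forecast"],
            predict_rows(back, table.frame)["forecast"],
        )

    def test_load_rejects_foreign_archive(self, tmp_path):
        import joblib

        path = tmp_path / "junk.joblib"
        joblib.dump({"something": 1}, path)
        with pytest.raises(KSVRError, match="archive"):
            load_model(path)


class TestClusteringHelpsOnRegimeData:
    def test_local_regressors_beat_global_svr_in_expectation(self):
        """Two demand regimes with distinct lag dynamics: the cluster-local
        engine should average a lower held-out MAPE than one global SVR."""
        from bedcast.synthetic import preset, generate

        deltas = []
        for seed in range(1, 6):
            series = generate(preset("regime_switching", seed=seed))
            table = build_features(series, horizon=1)
            ntr = int(np.ceil(0.7 * len(table)))
            train = type(table)(table.frame.iloc[:ntr], table.horizon,
                                table.calendar_mode, table.lags,
                                table.seasonal_lag, table.covariate_lag)
            clusters = fit_kmeans(train, K=2, seed=seed)
            ksvr = train_ksvr(train, clusters, cv_folds=5, seed=seed)
            plain = train_svr(train, cv_folds=5, seed=seed)
            test = table.frame.iloc[ntr:]
            yte = test["target"].to_numpy()
            e_k = np.mean(np.abs(
                predict_rows(ksvr, test)["forecast"].to_numpy() - yte) / yte)
            e_g = np.mean(np.abs(plain.predict(
                test[list(plain.feature_names)].to_numpy()) - yte) / yte)
            deltas.append(e_g - e_k)
        assert np.mean(deltas) > 0
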