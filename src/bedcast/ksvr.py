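"""The K-SVR forecaster: an SVM routes each day to a demand cluster, and
that cluster's locally trained support-vector regressor produces the forecast.

Training: days are grouped by K-means on their demand level (see
:mod:`bedcast.clustering`); a multi-class RBF-kernel SVM is tuned by grid
search + cross-validation to predict the cluster from the predictor row; for
each cluster an RBF-kernel epsilon-SVR is tuned the same way on that
cluster's rows only.  Features are z-scored on the training rows; targets
are z-scored within each cluster and back-transformed at prediction time.

Prediction always routes through the classifier — never through stored
training labels — so the deployment path equals the test path.  The engine
works as a one-shot 1- or 2-day-ahead ("direct") predictor, or recursively
feeds forecasts back as lagged inputs for multi-day horizons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .census import (
    ALL_DAYS,
    COVARIATE_FEATURE_NAMES,
    CensusSeries,
)
from .clustering import ClusterModel
from .features import INTERACTION, FeatureTable

logger = logging.getLogger(__name__)

_PERSIST_FORMAT = "bedcast-ksvr"
_PERSIST_VERSION = 1


class KSVRError(ValueError):
    """Raised for invalid training or prediction requests."""


@dataclass(frozen=True)
class SVRGrid:
    """Hyperparameter grid for the local epsilon-SVRs.

    ``C`` and ``epsilon`` are in standardized-target units; ``gamma_scale``
    multiplies the 1/d default RBF width for d features.
    """

    C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    epsilon: tuple[float, ...] = (0.01, 0.1, 1.0)
    gamma_scale: tuple[float, ...] = (0.1, 1.0, 10.0)


@dataclass(frozen=True)
class SVMGrid:
    """Hyperparameter grid for the cluster-assignment SVM."""

    C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_scale: tuple[float, ...] = (0.1, 1.0, 10.0)


@dataclass(frozen=True)
class FeatureSpec:
    """What the model was trained on; prediction inputs must match."""

    lags: tuple[int, ...]
    seasonal_lag: int
    horizon: int
    calendar_mode: str
    covariate_lag: int
    feature_names: tuple[str, ...]


@dataclass(frozen=True)
class TunedSVR:
    """One local regressor plus its target standardization."""

    estimator: SVR
    y_mean: float
    y_std: float
    best_params: dict
    cv_mae: float

    def predict(self, Xs: np.ndarray) -> np.ndarray:
        return self.estimator.predict(Xs) * self.y_std + self.y_mean


@dataclass(frozen=True)
class KSVRModel:
    cluster_model: ClusterModel
    classifier: SVC | None  # None iff K == 1
    regressors: tuple[TunedSVR, ...]  # index c-1 is cluster c
    feature_spec: FeatureSpec
    scaler: StandardScaler
    tuning_log: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.cluster_model.K


@dataclass(frozen=True)
class Prediction:
    forecast: float
    cluster: int
    confidence: float  # classifier decision margin (inf when K == 1)


# --------------------------------------------------------------------------
# tuning helpers

def _kernel_gamma(scale: float, d: int) -> float:
    return scale / d


def _tune_svr(
    Xs: np.ndarray,
    y: np.ndarray,
    grid: SVRGrid,
    cv_folds: int,
    seed: int,
) -> TunedSVR:
    """Grid-search an epsilon-SVR by K-fold CV mean absolute error.

    Ties break deterministically toward the smallest C, then epsilon, then
    gamma (the grid is scanned in ascending order with strict improvement).
    The target is z-scored before fitting; a zero spread falls back to unit
    scale (constant target within a cluster).
    """
    n = len(y)
    y_mean = float(np.mean(y))
    y_std = float(np.std(y))
    if y_std <= 0:
        y_std = 1.0
    ys = (y - y_mean) / y_std
    d = Xs.shape[1]

    folds = min(cv_folds, n)
    if folds < cv_folds:
        logger.warning("cluster with %d rows: CV folds reduced to %d", n, folds)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))

    best: tuple[float, dict] | None = None
    for C in sorted(grid.C):
        for eps in sorted(grid.epsilon):
            for gs in sorted(grid.gamma_scale):
                gamma = _kernel_gamma(gs, d)
                errs = []
                for tr, te in splits:
                    est = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
                    est.fit(Xs[tr], ys[tr])
                    pred = est.predict(Xs[te]) * y_std + y_mean
                    errs.append(np.mean(np.abs(y[te] - pred)))
                mae = float(np.mean(errs))
                params = {"C": C, "epsilon": eps, "gamma": gamma}
                if best is None or mae < best[0]:
                    best = (mae, params)
    assert best is not None
    mae, params = best
    est = SVR(kernel="rbf", **params)
    est.fit(Xs, ys)
    return TunedSVR(estimator=est, y_mean=y_mean, y_std=y_std,
                    best_params=params, cv_mae=mae)


def _tune_svm(
    Xs: np.ndarray,
    labels: np.ndarray,
    grid: SVMGrid,
    cv_folds: int,
    seed: int,
) -> tuple[SVC, dict, float]:
    """Grid-search the cluster-assignment SVC by CV misclassification rate."""
    d = Xs.shape[1]
    _, counts = np.unique(labels, return_counts=True)
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        folds = 2
    if folds < cv_folds:
        logger.warning("smallest cluster has %d rows: SVM CV folds reduced to %d",
                       counts.min(), folds)
    kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs, labels))

    best: tuple[float, dict] | None = None
    for C in sorted(grid.C):
        for gs in sorted(grid.gamma_scale):
            gamma = _kernel_gamma(gs, d)
            errs = []
            for tr, te in splits:
                est = SVC(kernel="rbf", C=C, gamma=gamma)
                est.fit(Xs[tr], labels[tr])
                errs.append(np.mean(est.predict(Xs[te]) != labels[te]))
            err = float(np.mean(errs))
            params = {"C": C, "gamma": gamma}
            if best is None or err < best[0]:
                best = (err, params)
    assert best is not None
    err, params = best
    est = SVC(kernel="rbf", decision_function_shape="ovr", **params)
    est.fit(Xs, labels)
    return est, params, err


# --------------------------------------------------------------------------
# training

def train_ksvr(
    table: FeatureTable,
    cluster_model: ClusterModel,
    svm_grid: SVMGrid | None = None,
    svr_grid: SVRGrid | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> KSVRModel:
    """Train the two-stage forecaster on a feature table and its clustering.

    The cluster model must have been fitted on the same rows (one label per
    table row).  Any cluster with fewer than 2 rows aborts training — a
    local SVR on so few points would only memorize them.
    """
    svm_grid = svm_grid or SVMGrid()
    svr_grid = svr_grid or SVRGrid()
    if cv_folds < 2:
        raise KSVRError("cv_folds must be >= 2")
    labels = np.asarray(cluster_model.labels)
    if len(labels) != len(table):
        raise KSVRError(
            f"cluster model has {len(labels)} labels for {len(table)} rows"
        )

    X = table.X
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    y = table.y
    K = cluster_model.K

    # overfitting guard first: a local SVR on < 2 rows would only memorize
    cluster_rows = {c: np.flatnonzero(labels == c) for c in range(1, K + 1)}
    for c, idx in cluster_rows.items():
        if len(idx) < 2:
            raise KSVRError(
                f"cluster {c} has {len(idx)} row(s); local SVR needs >= 2"
            )

    tuning_log: dict = {"svr": {}, "svm": None}
    classifier = None
    if K > 1:
        classifier, svm_params, svm_err = _tune_svm(
            Xs, labels, svm_grid, cv_folds, seed
        )
        tuning_log["svm"] = {"params": svm_params, "cv_error_rate": svm_err}
        logger.info("SVM tuned: %s (CV error %.4f)", svm_params, svm_err)

    regressors = []
    for c in range(1, K + 1):
        idx = cluster_rows[c]
        tuned = _tune_svr(Xs[idx], y[idx], svr_grid, cv_folds, seed)
        regressors.append(tuned)
        tuning_log["svr"][c] = {
            "n": int(len(idx)),
            "params": tuned.best_params,
            "cv_mae": tuned.cv_mae,
        }
        logger.info("cluster %d SVR tuned on %d rows: %s (CV MAE %.3f)",
                    c, len(idx), tuned.best_params, tuned.cv_mae)

    spec = FeatureSpec(
        lags=table.lags,
        seasonal_lag=table.seasonal_lag,
        horizon=table.horizon,
        calendar_mode=table.calendar_mode,
        covariate_lag=table.covariate_lag,
        feature_names=tuple(table.feature_names),
    )
    return KSVRModel(
        cluster_model=cluster_model,
        classifier=classifier,
        regressors=tuple(regressors),
        feature_spec=spec,
        scaler=scaler,
        tuning_log=tuning_log,
    )


def train_svr(
    table: FeatureTable,
    svr_grid: SVRGrid | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> "GlobalSVR":
    """Train a single tuned SVR on all rows — the K=1 special case of the
    engine, provided as the natural global comparator."""
    svr_grid = svr_grid or SVRGrid()
    X = table.X
    scaler = StandardScaler().fit(X)
    tuned = _tune_svr(scaler.transform(X), table.y, svr_grid, cv_folds, seed)
    return GlobalSVR(scaler=scaler, tuned=tuned,
                     feature_names=tuple(table.feature_names))


@dataclass(frozen=True)
class GlobalSVR:
    scaler: StandardScaler
    tuned: TunedSVR
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = self.tuned.predict(self.scaler.transform(np.asarray(X, dtype=float)))
        return np.clip(out, 0.0, None)


# --------------------------------------------------------------------------
# prediction

def _rows_to_matrix(model: KSVRModel, rows: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.feature_spec.feature_names
               if c not in rows.columns]
    if missing:
        raise KSVRError(f"missing feature column(s): {missing}")
    return rows[list(model.feature_spec.feature_names)].to_numpy(dtype=float)


def predict_rows(model: KSVRModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Forecast a batch of feature rows; returns forecast/cluster/confidence."""
    X = _rows_to_matrix(model, rows)
    Xs = model.scaler.transform(X)
    n = len(Xs)
    if model.classifier is None:
        clusters = np.ones(n, dtype=int)
        margins = np.full(n, np.inf)
    else:
        clusters = model.classifier.predict(Xs).astype(int)
        scores = np.atleast_2d(model.classifier.decision_function(Xs))
        if scores.shape[1] == 1:  # binary: signed distance to the boundary
            margins = np.abs(scores[:, 0])
        else:
            part = np.sort(scores, axis=1)
            margins = part[:, -1] - part[:, -2]
    forecasts = np.empty(n)
    for c in np.unique(clusters):
        sel = clusters == c
        forecasts[sel] = model.regressors[c - 1].predict(Xs[sel])
    forecasts = np.clip(forecasts, 0.0, None)
    return pd.DataFrame(
        {"forecast": forecasts, "cluster": clusters, "confidence": margins},
        index=rows.index,
    )


def predict_one(model: KSVRModel, features: Mapping[str, float] | pd.Series) -> Prediction:
    """Forecast a single feature row.

    Returns the bed-demand forecast (real-valued, floored at 0), the cluster
    the SVM assigned, and the classifier's decision margin.
    """
    row = pd.DataFrame([dict(features)])
    out = predict_rows(model, row).iloc[0]
    return Prediction(forecast=float(out["forecast"]),
                      cluster=int(out["cluster"]),
                      confidence=float(out["confidence"]))


def _feature_row_from_history(
    model: KSVRModel,
    demand_hist: np.ndarray,
    covariate_values: Mapping[str, float],
) -> dict[str, float]:
    """Assemble one feature row whose forecast origin is the last element of
    ``demand_hist`` (positional indexing, matching build_features)."""
    spec = model.feature_spec
    row: dict[str, float] = {}
    for k in spec.lags:
        row[f"Dt.{k}"] = float(demand_hist[-k])
    row[f"Dt.{spec.seasonal_lag}"] = float(demand_hist[-spec.seasonal_lag])
    if INTERACTION in spec.feature_names:
        row[INTERACTION] = row["Dt.1"] * row["Dt.2"]
    for name in spec.feature_names:
        if name in covariate_values:
            row[name] = float(covariate_values[name])
    return row


def forecast_horizon(
    model: KSVRModel,
    series: CensusSeries,
    origin,
    horizon: int,
    mode: str = "recursive",
) -> pd.Series:
    """Forecast demand for the ``horizon`` steps after ``origin``.

    ``recursive`` mode requires a model trained at horizon 1: each step's
    forecast is fed back as the next step's ``Dt.1`` (other demand lags
    shift accordingly; covariates are held at their last observed values).
    ``direct`` mode requires ``model.feature_spec.horizon == horizon`` and
    returns the single step-``horizon`` forecast built in one shot.

    Only data up to ``origin`` is consulted; later rows of ``series`` cannot
    influence the output.
    """
    if mode not in ("recursive", "direct"):
        raise KSVRError(f"unknown mode {mode!r}")
    spec = model.feature_spec
    if series.calendar_mode != spec.calendar_mode:
        raise KSVRError(
            f"series calendar_mode {series.calendar_mode!r} != model's "
            f"{spec.calendar_mode!r}"
        )
    if horizon < 1:
        raise KSVRError("horizon must be >= 1")
    if mode == "direct" and spec.horizon != horizon:
        raise KSVRError(
            f"direct mode needs a model trained at horizon {horizon}, "
            f"got {spec.horizon}"
        )
    if mode == "recursive" and spec.horizon != 1:
        raise KSVRError("recursive mode needs a model trained at horizon 1")

    origin = pd.Timestamp(origin)
    if origin not in series.dates:
        raise KSVRError(f"origin {origin.date()} not in series")
    hist = series.truncate_to(origin)
    max_back = max(max(spec.lags), spec.seasonal_lag)
    if len(hist) < max_back:
        have = set(hist.dates)
        if spec.calendar_mode == ALL_DAYS:
            need = pd.date_range(end=origin, periods=max_back, freq="D")
        else:
            need = pd.bdate_range(end=origin, periods=max_back)
        missing = [str(d.date()) for d in need if d not in have]
        raise KSVRError(
            f"insufficient history before {origin.date()}: missing {missing}"
        )

    covariate_values = {
        COVARIATE_FEATURE_NAMES[role]: float(
            hist.frame[role].iloc[-spec.covariate_lag]
        )
        for role in hist.covariates
        if COVARIATE_FEATURE_NAMES[role] in spec.feature_names
    }
    missing_cov = [
        name for name in spec.feature_names
        if name in COVARIATE_FEATURE_NAMES.values()
        and name not in covariate_values
    ]
    if missing_cov:
        raise KSVRError(f"series lacks covariate(s) for feature(s) {missing_cov}")

    if spec.calendar_mode == ALL_DAYS:
        future = pd.date_range(origin, periods=horizon + 1, freq="D")[1:]
    else:
        future = pd.bdate_range(origin, periods=horizon + 1)[1:]

    demand_hist = hist.demand.to_numpy(dtype=float)
    if mode == "direct":
        # lag k of the step-h target reaches back h+k-1 steps from the target,
        # i.e. k-1 steps back from the origin: same indexing as recursive step 1
        row = _feature_row_from_history(model, demand_hist, covariate_values)
        pred = predict_one(model, row)
        return pd.Series([pred.forecast], index=future[-1:], name="forecast")

    values = list(demand_hist)
    out = []
    for _ in range(horizon):
        row = _feature_row_from_history(
            model, np.asarray(values), covariate_values
        )
        pred = predict_one(model, row)
        out.append(pred.forecast)
        values.append(pred.forecast)
    return pd.Series(out, index=future, name="forecast")


# --------------------------------------------------------------------------
# persistence

def save_model(model: KSVRModel, path: str | Path) -> None:
    """Persist a fitted model to a single self-describing archive."""
    joblib.dump(
        {"format": _PERSIST_FORMAT, "version": _PERSIST_VERSION, "model": model},
        path,
    )


def load_model(path: str | Path) -> KSVRModel:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != _PERSIST_FORMAT:
        raise KSVRError(f"{path} is not a saved forecaster archive")
    if blob.get("version") != _PERSIST_VERSION:
        raise KSVRError(f"unsupported archive version {blob.get('version')}")
    return blob["model"]
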