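"""K-means grouping of historical demand and elbow-based selection of K.

The forecaster engine first partitions the training days into K groups of
similar demand (by default clustering the scalar demand itself), then fits
one local regressor per group.  The number of clusters is chosen from the
within-group sum-of-squares (wss) curve: K grows until the marginal wss
reduction becomes small ("elbow").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .features import FeatureTable

TARGET_VALUE = "target_value"
FEATURE_VECTOR = "feature_vector"


class ClusterError(ValueError):
    """Raised for invalid clustering requests."""


class NoElbowWarning(UserWarning):
    """The wss curve never flattens below the threshold; max K returned."""


@dataclass(frozen=True)
class ClusterModel:
    """A fitted K-means grouping of the training days.

    ``labels`` are 1-based cluster ids, one per training row of the feature
    table the model was fitted on.  ``wss`` is the within-group sum of
    squares — the sum over clusters of squared distances of each member to
    its own center, in the clustered representation (scalar demand by
    default, or the z-scored predictor rows).
    """

    K: int
    centers: np.ndarray  # (K, d) in the clustered representation
    labels: np.ndarray  # (n,) values in 1..K
    wss: float
    representation: str
    seed: int
    n_init: int
    scale_mean: np.ndarray | None = None  # feature_vector mode z-scoring
    scale_std: np.ndarray | None = None


def _cluster_matrix(table: FeatureTable, representation: str):
    if representation == TARGET_VALUE:
        return table.y.reshape(-1, 1), None, None
    if representation == FEATURE_VECTOR:
        X = table.X
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return (X - mean) / std, mean, std
    raise ClusterError(f"unknown representation {representation!r}")


def _best_kmeans(X: np.ndarray, K: int, seed: int, n_init: int,
                 warm_centers: np.ndarray | None = None) -> KMeans:
    """Best-of-restarts Lloyd's; optionally also try a warm-start init."""
    fits = []
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatter on tiny data
        km.fit(X)
        fits.append(km)
        if warm_centers is not None:
            km_w = KMeans(n_clusters=K, init=warm_centers, n_init=1,
                          random_state=seed)
            km_w.fit(X)
            fits.append(km_w)
    return min(fits, key=lambda f: f.inertia_)


def fit_kmeans(
    table: FeatureTable,
    K: int,
    representation: str = TARGET_VALUE,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """Fit K-means with ``n_init`` random restarts, keeping the best wss.

    ``representation="target_value"`` clusters the scalar demand being
    forecast (the engine's default: groups of similar demand levels);
    ``"feature_vector"`` clusters the z-scored predictor rows instead.
    """
    n = len(table)
    if K < 1:
        raise ClusterError("K must be >= 1")
    if K > n:
        raise ClusterError(f"K={K} exceeds the {n} available rows")
    X, mean, std = _cluster_matrix(table, representation)
    km = _best_kmeans(X, K, seed, n_init)
    return ClusterModel(
        K=K,
        centers=km.cluster_centers_.copy(),
        labels=km.labels_.astype(int) + 1,
        wss=float(km.inertia_),
        representation=representation,
        seed=seed,
        n_init=n_init,
        scale_mean=mean,
        scale_std=std,
    )


def wss_curve(
    table: FeatureTable,
    K_range: Sequence[int],
    representation: str = TARGET_VALUE,
    seed: int = 0,
    n_init: int = 10,
) -> list[float]:
    """Within-group sum of squares for each K in ``K_range``.

    Each K is fit best-of-restarts; in addition, when the range is
    consecutive, K+1 is warm-started from the best K solution plus the point
    farthest from its assigned center, which guarantees the curve is
    monotone non-increasing (independent restarts alone need not be).
    """
    K_range = list(K_range)
    if any(k < 1 or k > len(table) for k in K_range):
        raise ClusterError("all K in range must satisfy 1 <= K <= n rows")
    X, _, _ = _cluster_matrix(table, representation)
    out: list[float] = []
    prev: KMeans | None = None
    for K in K_range:
        warm = None
        if prev is not None and K == prev.n_clusters + 1:
            dists = np.linalg.norm(
                X - prev.cluster_centers_[prev.labels_], axis=1
            )
            extra = X[int(np.argmax(dists))]
            warm = np.vstack([prev.cluster_centers_, extra])
        km = _best_kmeans(X, K, seed, n_init, warm_centers=warm)
        out.append(float(km.inertia_))
        prev = km
    return out


def select_k_elbow(wss: Sequence[float], min_relative_drop: float = 0.10) -> int:
    """Elbow rule on a wss curve from consecutive K starting at 1.

    Returns the smallest K such that the relative wss reduction from K to
    K+1 falls below ``min_relative_drop``.  A zero wss contributes a zero
    further drop (exact fit reached).  If every drop stays above the
    threshold, the largest tested K is returned with a
    :class:`NoElbowWarning`.
    """
    wss = [float(w) for w in wss]
    if len(wss) < 3:
        raise ClusterError("need the wss for at least 3 consecutive K values")
    if not 0 < min_relative_drop < 1:
        raise ClusterError("min_relative_drop must be in (0, 1)")
    for i in range(len(wss) - 1):
        drop = 0.0 if wss[i] == 0 else (wss[i] - wss[i + 1]) / wss[i]
        if drop < min_relative_drop:
            return i + 1  # K values start at 1
    warnings.warn(
        "wss curve shows no elbow at the tested K values; returning the max",
        NoElbowWarning,
        stacklevel=2,
    )
    return len(wss)


def recompute_wss(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Direct wss recomputation from (rows, labels, centers); audit helper."""
    diffs = X - centers[labels - 1]
    return float(np.sum(diffs * diffs))


def wss_curve_to_csv(K_range: Sequence[int], wss: Sequence[float],
                     path: str | Path) -> None:
    pd.DataFrame({"K": list(K_range), "wss": list(wss)}).to_csv(path, index=False)
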