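"""Feature-space scaling and silhouette-selected k-means clustering.

Clustering operates on the three independent variables (PTT, PIR, HR)
only, after z-score standardization; the number of clusters is chosen by
sweeping a k range and keeping the argmax of the mean silhouette score.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

#: Columns of the independent-variable space used for clustering.
FEATURE_SPACE = ("ptt_s", "pir_ratio", "hr_bpm")


@dataclass
class ScalingModel:
    """Per-feature z-score parameters (population standard deviation)."""

    center: np.ndarray
    scale: np.ndarray
    columns: tuple = FEATURE_SPACE

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scaling factors must be positive")


@dataclass
class ClusterModel:
    """A fitted k-means partition of the scaled feature space."""

    k: int
    centroids: np.ndarray  # (k, 3) in scaled space
    labels: np.ndarray
    inertia: float
    silhouette_by_k: dict
    seed: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        counts = np.bincount(self.labels, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("every cluster must be non-empty")


def _matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[list(FEATURE_SPACE)].to_numpy(dtype=float)
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    return x


def fit_scaler(features) -> ScalingModel:
    """Fit a z-score scaler on (PTT, PIR, HR); constant columns get scale 1."""
    x = _matrix(features)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    center = x.mean(axis=0)
    scale = x.std(axis=0)  # population SD
    const = scale == 0
    if const.any():
        warnings.warn("constant feature column(s); scale set to 1", stacklevel=2)
        scale = np.where(const, 1.0, scale)
    return ScalingModel(center=center, scale=scale)


def apply_scaler(scaler: ScalingModel, features) -> np.ndarray:
    return (_matrix(features) - scaler.center) / scaler.scale


def invert_scaler(scaler: ScalingModel, scaled: np.ndarray) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * scaler.scale + scaler.center


def kmeans_fit(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts."""
    points = np.asarray(points, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(np.unique(points, axis=0)):
        raise ValueError("k exceeds the number of distinct points")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        algorithm="lloyd",
        random_state=seed,
    ).fit(points)
    return km.cluster_centers_, km.labels_.astype(int), float(km.inertia_)


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score (b - a) / max(a, b); singletons contribute 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(silhouette_score(np.asarray(points, dtype=float), labels, metric="euclidean"))


def select_k(
    points: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """Sweep k in [k_min, k_max], keep the silhouette argmax (ties: smallest k)."""
    if k_min < 2 or k_max < k_min:
        raise ValueError("need 2 <= k_min <= k_max")
    points = np.asarray(points, dtype=float)
    fits = {}
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        centroids, labels, inertia = kmeans_fit(points, k, seed=seed, n_init=n_init)
        fits[k] = (centroids, labels, inertia)
        scores[k] = mean_silhouette(points, labels)
    best = max(scores, key=lambda k: (scores[k], -k))
    centroids, labels, inertia = fits[best]
    logger.info("silhouette sweep %d..%d selected k=%d (score %.3f)",
                k_min, k_max, best, scores[best])
    return ClusterModel(
        k=best, centroids=centroids, labels=labels, inertia=inertia,
        silhouette_by_k=scores, seed=seed,
    )


def fit_clusters(
    points: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterModel:
    """Fit k-means at a fixed k (silhouette recorded for that k only)."""
    centroids, labels, inertia = kmeans_fit(points, k, seed=seed, n_init=n_init)
    score = mean_silhouette(points, labels)
    return ClusterModel(
        k=k, centroids=centroids, labels=labels, inertia=inertia,
        silhouette_by_k={k: score}, seed=seed,
    )


def assign_cluster(model: ClusterModel, scaler: ScalingModel, features) -> np.ndarray:
    """Nearest-centroid index in scaled space for each row (ties: lowest)."""
    scaled = apply_scaler(scaler, features)
    d = cdist(scaled, model.centroids)
    return d.argmin(axis=1)


def save_cluster_model(model: ClusterModel, scaler: ScalingModel, path) -> Path:
    """Serialize model + scaler as JSON (labels included for provenance)."""
    payload = {
        "k": model.k,
        "centroids": model.centroids.tolist(),
        "inertia": model.inertia,
        "silhouette_by_k": {str(k): v for k, v in model.silhouette_by_k.items()},
        "seed": model.seed,
        "labels": model.labels.tolist(),
        "scaler": {
            "center": scaler.center.tolist(),
            "scale": scaler.scale.tolist(),
            "columns": list(scaler.columns),
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_cluster_model(path) -> tuple[ClusterModel, ScalingModel]:
    payload = json.loads(Path(path).read_text())
    scaler = ScalingModel(
        center=np.array(payload["scaler"]["center"]),
        scale=np.array(payload["scaler"]["scale"]),
        columns=tuple(payload["scaler"]["columns"]),
    )
    model = ClusterModel(
        k=payload["k"],
        centroids=np.array(payload["centroids"]),
        labels=np.array(payload["labels"], dtype=int),
        inertia=payload["inertia"],
        silhouette_by_k={int(k): v for k, v in payload["silhouette_by_k"].items()},
        seed=payload["seed"],
    )
    return model, scaler
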