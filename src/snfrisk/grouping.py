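"""K-means grouping of facilities on their factor scores.

Facilities are clustered with restarted k-means++ on Thurstone factor
scores; the number of groups is chosen to maximize the mean silhouette
score (Euclidean distance).  Group labels are canonicalized by
descending cluster size so that "Group 1" is always the largest group.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = [
    "ClusterModel",
    "ClusterError",
    "fit_kmeans",
    "mean_silhouette",
    "silhouette_curve",
    "select_n_groups",
    "assign_group",
]


class ClusterError(ValueError):
    """Raised for degenerate clustering inputs."""


@dataclass
class ClusterModel:
    """A fitted facility grouping.

    ``centroids`` are ordered by descending cluster size; ``labels``
    maps each row id (SNF id) to a group in 1..K.
    """

    K: int
    centroids: np.ndarray
    labels: pd.Series  # index = row ids, values in 1..K
    mean_silhouette: float
    inertia: float
    silhouette_by_K: dict[int, float] = field(default_factory=dict)

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def to_json(self, path) -> None:
        payload = {
            "K": int(self.K),
            "centroids": self.centroids.tolist(),
            "labels": {str(k): int(v) for k, v in self.labels.items()},
            "mean_silhouette": float(self.mean_silhouette),
            "inertia": float(self.inertia),
            "silhouette_by_K": {str(k): float(v) for k, v in self.silhouette_by_K.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        labels = pd.Series({k: v for k, v in d["labels"].items()})
        return cls(
            K=d["K"],
            centroids=np.asarray(d["centroids"]),
            labels=labels,
            mean_silhouette=d["mean_silhouette"],
            inertia=d["inertia"],
            silhouette_by_K={int(k): v for k, v in d.get("silhouette_by_K", {}).items()},
        )


def _as_array(scores):
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), scores.index
    arr = np.asarray(scores, dtype=float)
    return arr, pd.RangeIndex(len(arr))


def fit_kmeans(scores, K: int, seed: int = 0, n_restarts: int = 50) -> ClusterModel:
    """Best of ``n_restarts`` k-means++ runs by inertia, deterministic given seed.

    Cluster labels are renumbered 1..K by descending cluster size
    (stable tie-break on the original k-means label) so labels are
    reproducible across runs.
    """
    X, index = _as_array(scores)
    if K < 2:
        raise ClusterError("K must be >= 2")
    n_distinct = len(np.unique(X, axis=0))
    if K > n_distinct:
        raise ClusterError(f"K={K} exceeds the {n_distinct} distinct rows")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    counts = np.bincount(raw, minlength=K)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(1, K + 1)
    labels = pd.Series(relabel[raw], index=index, name="group")
    centroids = km.cluster_centers_[order]
    sil = mean_silhouette(X, labels.to_numpy())
    return ClusterModel(K=K, centroids=centroids, labels=labels,
                        mean_silhouette=sil, inertia=float(km.inertia_))


def mean_silhouette(scores, labels) -> float:
    """Mean silhouette score with Euclidean distance.

    Per point, ``s = (b - a) / max(a, b)`` where a is the mean
    intra-cluster distance and b the smallest mean distance to another
    cluster; singleton clusters contribute 0.
    """
    X, _ = _as_array(scores)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClusterError("silhouette requires at least two clusters")
    return float(silhouette_samples(X, labels, metric="euclidean").mean())


def silhouette_curve(scores, K_candidates, seed: int = 0, n_restarts: int = 50) -> dict[int, float]:
    """Mean silhouette of the fitted k-means solution per candidate K."""
    K_candidates = sorted(set(int(K) for K in K_candidates))
    if not K_candidates:
        raise ClusterError("empty candidate set")
    return {K: fit_kmeans(scores, K, seed=seed, n_restarts=n_restarts).mean_silhouette
            for K in K_candidates}


def select_n_groups(scores, K_candidates=range(2, 9), seed: int = 0,
                    n_restarts: int = 50) -> int:
    """Number of groups maximizing mean silhouette; ties go to smaller K."""
    curve = silhouette_curve(scores, K_candidates, seed=seed, n_restarts=n_restarts)
    return max(curve, key=lambda K: (curve[K], -K))


def assign_group(model: ClusterModel, new_scores) -> pd.Series:
    """Nearest-centroid (Euclidean) group for new score rows.

    Ties go to the lower group index.
    """
    X, index = _as_array(new_scores)
    if X.shape[1] != model.centroids.shape[1]:
        raise ClusterError(
            f"score dimension {X.shape[1]} does not match centroids "
            f"({model.centroids.shape[1]})")
    d = cdist(X, model.centroids)
    return pd.Series(d.argmin(axis=1) + 1, index=index, name="group")
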