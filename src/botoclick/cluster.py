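"""k-means clustering of click-parameter tables with data-driven k.

Used for the mixed Madeira River population, where three taxa (Bolivian
boto, Amazon boto, hybrids) cannot be told apart visually: features are
z-scored, k-means (Lloyd, multiple restarts) is scanned over a k range,
and the cluster count is chosen by the mean silhouette width, with
Hubert-Gamma and D-index knee curves as corroborating heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterReport",
    "standardize",
    "kmeans_fit",
    "silhouette_scan",
    "knee_indices",
    "run_clustering",
    "CLUSTER_FEATURES",
]

CLUSTER_FEATURES = ["fp_khz", "bw3_khz", "bw10_khz"]
DEFAULT_K_RANGE = range(2, 11)
N_RESTARTS = 25


@dataclass
class ClusterReport:
    k_opt: int
    assignments: np.ndarray  # cluster index per row, for k_opt
    labels: list[str]  # Ispp1..k naming of the clusters
    silhouette: dict[int, float]  # mean silhouette width per scanned k
    hubert: dict[int, float] | None = None
    dindex: dict[int, float] | None = None
    hubert_knee: int | None = None
    dindex_knee: int | None = None
    knee_confident: bool | None = None

    def to_json_dict(self) -> dict:
        return {
            "k_opt": self.k_opt,
            "labels": self.labels,
            "silhouette": {str(k): round(v, 4) for k, v in self.silhouette.items()},
            "hubert": {str(k): round(v, 4) for k, v in (self.hubert or {}).items()},
            "dindex": {str(k): round(v, 4) for k, v in (self.dindex or {}).items()},
            "hubert_knee": self.hubert_knee,
            "dindex_knee": self.dindex_knee,
            "knee_confident": self.knee_confident,
        }


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        cols = [c for c in CLUSTER_FEATURES if c in table.columns]
        X = table[cols].to_numpy(dtype=float) if cols else table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("cluster table contains non-finite values")
    return X


def standardize(X: np.ndarray) -> np.ndarray:
    """z-score columns; constant columns are left centred at zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def kmeans_fit(
    table, k: int, seed: int = 0, n_restarts: int = N_RESTARTS
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts Lloyd k-means on standardized features.

    Returns (assignments, centers in standardized space, within-cluster SS).
    """
    X = standardize(_as_matrix(table))
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_, float(km.inertia_)


def silhouette_scan(table, k_range=DEFAULT_K_RANGE, seed: int = 0) -> ClusterReport:
    """Mean silhouette width for each k; k_opt = argmax (ties -> smaller k)."""
    X = standardize(_as_matrix(table))
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    if any(not 2 <= k <= X.shape[0] - 1 for k in ks):
        raise ValueError("k range must lie within [2, n-1]")
    widths: dict[int, float] = {}
    best_assign: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
        labels = km.fit_predict(X)
        widths[k] = float(silhouette_score(X, labels))
        best_assign[k] = labels
    k_opt = max(sorted(widths), key=lambda k: widths[k])  # ties -> smaller k
    assignments = best_assign[k_opt]
    return ClusterReport(
        k_opt=k_opt,
        assignments=assignments,
        labels=[f"Ispp{i + 1}" for i in range(k_opt)],
        silhouette=widths,
    )


def _hubert_gamma(D: np.ndarray, labels: np.ndarray, centers: np.ndarray,
                  X: np.ndarray) -> float:
    """Normalized Gamma between point distances and their centroid distances."""
    C = pdist(centers[labels])  # distance between the two points' centroids
    d, c = D - D.mean(), C - C.mean()
    denom = np.sqrt((d**2).sum() * (c**2).sum())
    return float((d * c).sum() / denom) if denom > 0 else 0.0


def knee_indices(table, k_range=DEFAULT_K_RANGE, seed: int = 0) -> ClusterReport:
    """Hubert-Gamma and D-index curves over k with knee suggestions.

    The D-index is the mean distance of points to their cluster centroid.
    Each curve's suggested k is the location of the maximum second
    difference (the knee).  The suggestion is flagged low-confidence when
    the largest second difference does not dominate the curve (no sharp
    knee, e.g. structureless data).
    """
    X = standardize(_as_matrix(table))
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty k range")
    if any(not 2 <= k <= X.shape[0] - 1 for k in ks):
        raise ValueError("k range must lie within [2, n-1]")
    D = pdist(X)
    hubert: dict[int, float] = {}
    dindex: dict[int, float] = {}
    assigns: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
        labels = km.fit_predict(X)
        assigns[k] = labels
        hubert[k] = _hubert_gamma(D, labels, km.cluster_centers_, X)
        dists = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
        dindex[k] = float(dists.mean())

    hub_knee, hub_mag = _knee_of(ks, hubert, concave=True)
    d_knee, d_mag = _knee_of(ks, dindex, concave=False)
    # confidence: the winning second difference must dominate the others
    confident = _knee_confident(ks, hubert, True) and _knee_confident(ks, dindex, False)
    sil = silhouette_scan(table, k_range=ks, seed=seed)
    return ClusterReport(
        k_opt=sil.k_opt,
        assignments=sil.assignments,
        labels=sil.labels,
        silhouette=sil.silhouette,
        hubert=hubert,
        dindex=dindex,
        hubert_knee=hub_knee,
        dindex_knee=d_knee,
        knee_confident=confident,
    )


def _second_diffs(ks: list[int], curve: dict[int, float], concave: bool) -> dict[int, float]:
    """Signed second differences oriented so a knee is a large positive value."""
    sign = -1.0 if concave else 1.0
    return {
        ks[i]: sign * (curve[ks[i - 1]] + curve[ks[i + 1]] - 2 * curve[ks[i]])
        for i in range(1, len(ks) - 1)
    }


def _knee_of(ks: list[int], curve: dict[int, float], concave: bool) -> tuple[int | None, float]:
    d2 = _second_diffs(ks, curve, concave)
    if not d2:
        return None, 0.0
    k = min(d2, key=lambda k: (-d2[k], k))
    return k, d2[k]


def _knee_confident(ks: list[int], curve: dict[int, float], concave: bool) -> bool:
    """A knee is confident when its second difference clearly dominates.

    Smooth structureless index curves decay near-geometrically, so their
    consecutive second differences keep a ratio of ~e; a planted-cluster
    knee exceeds the runner-up by an order of magnitude.  The 4x dominance
    threshold separates the two regimes.
    """
    d2 = _second_diffs(ks, curve, concave)
    if len(d2) < 2:
        return False
    vals = sorted(d2.values(), reverse=True)
    if vals[0] <= 0:
        return False
    runner = max(vals[1], 0.0)
    return vals[0] >= 4.0 * runner + 1e-12


def run_clustering(table, k_range=DEFAULT_K_RANGE, seed: int = 0) -> ClusterReport:
    """Silhouette-driven k selection with knee-index corroboration."""
    return knee_indices(table, k_range=k_range, seed=seed)
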