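"""Deterministic k-means state labeling with Calinski-Harabasz selection.

Reproducibility of the state labels matters more here than in generic
clustering: the surrogate test downstream re-clusters hundreds of
phase-randomized copies of the data and compares a statistic across them,
so run-to-run jitter in the partition would contaminate the null
distribution.  Seeds are therefore produced by a deterministic PCA
partitioning — recursively splitting the cluster with the largest within-
cluster scatter at its centroid along its first principal axis — and the
Lloyd iterations use fixed tie-break and empty-cluster rules.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import calinski_harabasz_score

from .core import StateLabeling

_MAX_LLOYD_ITER = 300


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """First principal axis of a point set (unit vector)."""
    centered = points - points.mean(axis=0)
    # SVD of the centered cloud; right singular vector of largest s.v.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # fix sign for determinism: first nonzero coordinate positive
    nz = np.flatnonzero(axis)
    if nz.size and axis[nz[0]] < 0:
        axis = -axis
    return axis


def _pca_partition_seeds(points: np.ndarray, K: int) -> np.ndarray:
    """Deterministic seeds by recursive largest-scatter PCA splitting."""
    n = points.shape[0]
    membership = np.zeros(n, dtype=int)
    n_clusters = 1
    while n_clusters < K:
        # pick the cluster with the largest within-cluster scatter (SSE)
        scatters = np.full(n_clusters, -np.inf)
        for c in range(n_clusters):
            pts = points[membership == c]
            if pts.shape[0] >= 2:
                scatters[c] = float(((pts - pts.mean(axis=0)) ** 2).sum())
        target = int(np.argmax(scatters))
        if not np.isfinite(scatters[target]):
            raise ValueError("cannot split further: too few distinct points for K")
        pts_idx = np.flatnonzero(membership == target)
        pts = points[pts_idx]
        axis = _principal_axis(pts)
        proj = (pts - pts.mean(axis=0)) @ axis
        right = proj > 0
        if right.all() or (~right).all():
            raise ValueError("degenerate split: duplicate points prevent partitioning")
        membership[pts_idx[right]] = n_clusters
        n_clusters += 1
    return np.vstack([points[membership == c].mean(axis=0) for c in range(K)])


def kmeans_deterministic(points: np.ndarray, K: int) -> StateLabeling:
    """Euclidean k-means from a deterministic PCA-partitioning start.

    Identical input always yields identical output (labels are bitwise
    reproducible).  Empty clusters arising during a Lloyd step are reseeded
    at the point farthest from its assigned centroid.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be 2-D (samples x channels)")
    n = points.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if n <= K:
        raise ValueError("need more samples than clusters")
    if np.unique(points, axis=0).shape[0] < K:
        raise ValueError("K exceeds the number of distinct points")

    centroids = _pca_partition_seeds(points, K)
    sq_norms = (points**2).sum(axis=1)
    labels = np.zeros(n, dtype=int)
    for _ in range(_MAX_LLOYD_ITER):
        # squared distances via the expansion ||p||^2 - 2 p.c + ||c||^2
        d2 = sq_norms[:, None] - 2.0 * points @ centroids.T + (centroids**2).sum(axis=1)
        new_labels = np.argmin(d2, axis=1)
        for c in range(K):
            if not np.any(new_labels == c):
                # deterministic reseed: point farthest from its own centroid
                far = int(np.argmax(d2[np.arange(n), new_labels]))
                new_labels[far] = c
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        centroids = np.vstack([points[labels == c].mean(axis=0) for c in range(K)])
    return StateLabeling(labels=labels + 1, K=K, centroids=centroids)


def select_num_states(
    points: np.ndarray, K_range: tuple[int, ...] = tuple(range(2, 11))
) -> StateLabeling:
    """Choose K by the Calinski-Harabasz index over candidate cluster counts.

    Ties in the index break toward the smaller K.
    """
    K_range = tuple(sorted(set(int(k) for k in K_range)))
    if not K_range or K_range[0] < 2 or K_range[-1] > 10:
        raise ValueError("K_range must be a nonempty subset of {2..10}")
    points = np.asarray(points, dtype=float)
    if points.shape[0] <= max(K_range):
        raise ValueError("fewer samples than the largest candidate K")

    best: StateLabeling | None = None
    best_score = -np.inf
    for K in K_range:
        labeling = kmeans_deterministic(points, K)
        score = calinski_harabasz_score(points, labeling.labels)
        if score > best_score:
            best, best_score = labeling, score
    assert best is not None
    return best
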