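"""Clustering validity indices: Davies–Bouldin, Calinski–Harabasz, silhouette.

All distances are Euclidean.  The indices are computed directly from their
definitions; scikit-learn's implementations serve as independent cross-checks
in the test suite.

Note on the silhouette range: the definition s = (b - a)/max(a, b) permits
values in [-1, 1]; negative values simply flag samples closer to a foreign
cluster than to their own.  No clamping to [0, 1] is performed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["davies_bouldin", "calinski_harabasz", "silhouette", "validate_clustering"]


def validate_clustering(points: np.ndarray, labels: np.ndarray,
                        min_clusters: int = 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if points.ndim != 2:
        raise ValueError("points must be an (N, d) matrix")
    if len(labels) != len(points):
        raise ValueError("labels length must match points")
    uniq = np.unique(labels)
    if len(uniq) < min_clusters:
        raise ValueError(f"need at least {min_clusters} clusters")
    return points, labels, uniq


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """DBI = (1/k) sum_i max_{j != i} (s_i + s_j) / d(c_i, c_j).

    ``s_i`` is the mean distance of cluster-i points to their centroid and
    d(c_i, c_j) the distance between centroids; lower is better.
    """
    X, y, uniq = validate_clustering(points, labels)
    k = len(uniq)
    cents = np.stack([X[y == g].mean(axis=0) for g in uniq])
    s = np.array([np.linalg.norm(X[y == g] - cents[i], axis=1).mean()
                  for i, g in enumerate(uniq)])
    total = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            if d == 0.0:
                raise ZeroDivisionError(
                    f"clusters {uniq[i]} and {uniq[j]} have coincident centroids")
            worst = max(worst, (s[i] + s[j]) / d)
        total += worst
    return total / k


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """CHI = [tr(B_k)/tr(W_k)] * [(n - k)/(k - 1)]; higher is better.

    W_k is the within-cluster scatter about the cluster centroids, B_k the
    between-cluster scatter of the (count-weighted) centroids about the
    global centre.
    """
    X, y, uniq = validate_clustering(points, labels)
    n, k = len(X), len(uniq)
    if n <= k:
        raise ValueError("need more points than clusters")
    global_c = X.mean(axis=0)
    tr_W = 0.0
    tr_B = 0.0
    for g in uniq:
        block = X[y == g]
        c = block.mean(axis=0)
        tr_W += float(((block - c) ** 2).sum())
        tr_B += len(block) * float(((c - global_c) ** 2).sum())
    if tr_W == 0.0:
        raise ZeroDivisionError("all clusters are point masses; CHI is infinite")
    return (tr_B / tr_W) * ((n - k) / (k - 1))


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s = (b - a)/max(a, b) over all samples.

    ``a`` is the mean intra-cluster distance (excluding the sample itself),
    ``b`` the mean distance to the nearest other cluster.  A sample that is
    the sole member of its cluster contributes 0 (standard convention).
    """
    X, y, uniq = validate_clustering(points, labels)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 samples")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    D = np.sqrt(np.maximum(d2, 0.0))
    scores = np.zeros(n)
    for i in range(n):
        own = y == y[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: s = 0
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, y == g].mean() for g in uniq if g != y[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())
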