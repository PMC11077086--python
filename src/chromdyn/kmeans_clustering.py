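"""Temporal k-means clustering of normalized enrichment profiles.

Lloyd's algorithm with k-means++ seeding and multiple restarts (default 25)
clusters region × timepoint z-score profiles; the within-cluster sum of
squares (WSS) across a k range drives elbow-based choice of k.  Cluster ids
are relabeled by descending cluster size so output is stable across runs
with the same seed.  The paper-style analysis feeds only expression-
correlated regions (see :func:`filter_regions_for_clustering`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ClusterAssignment:
    labels: pd.Series  # region_id -> cluster id in 1..k
    centroids: pd.DataFrame  # k × timepoints
    wss: float
    k: int
    n_iter: int
    converged: bool
    seed: int
    wss_trace: list[float] = field(default_factory=list)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    iter_max: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """One Lloyd run.  Empty clusters are re-seeded on the point farthest
    from its centroid (documented policy).  Each sweep's WSS is recorded;
    the sequence never increases."""
    k = centers.shape[0]
    labels = np.zeros(X.shape[0], dtype=int)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, iter_max + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        point_d2 = d2[np.arange(X.shape[0]), new_labels]
        for j in range(k):
            sel = new_labels == j
            if sel.any():
                centers[j] = X[sel].mean(axis=0)
            else:  # empty cluster: grab the worst-fit point
                far = point_d2.argmax()
                centers[j] = X[far]
                new_labels[far] = j
                point_d2[far] = 0.0
        wss = float(((X - centers[new_labels]) ** 2).sum())
        trace.append(wss)
        if np.array_equal(new_labels, labels) and n_iter > 1:
            converged = True
            labels = new_labels
            break
        labels = new_labels
    wss = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, wss, n_iter, converged, trace


def _relabel_by_size(labels: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..k by descending size (ties by old id)."""
    k = centers.shape[0]
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[labels], centers[order]


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int = 6,
    iter_max: int = 500,
    n_init: int = 25,
    seed: int = 1,
    init_centers: np.ndarray | None = None,
) -> ClusterAssignment:
    """Best-of-``n_init`` Lloyd clustering of row profiles.

    Deterministic under a fixed seed.  ``init_centers`` adds one extra run
    started from the supplied centers (used by the elbow sweep to make WSS
    non-increasing in k).
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    starts: list[np.ndarray] = [
        _kmeanspp_init(X, k, rng) for _ in range(n_init)
    ]
    if init_centers is not None:
        if init_centers.shape == (k, X.shape[1]):
            starts.append(init_centers.copy())
    for start in starts:
        out = _lloyd(X, start.copy(), iter_max, rng)
        if best is None or out[2] < best[2]:
            best = out
    labels, centers, wss, n_iter, converged, trace = best
    labels, centers = _relabel_by_size(labels, centers)
    centroids = pd.DataFrame(
        centers, index=pd.RangeIndex(1, k + 1, name="cluster_id"), columns=matrix.columns
    )
    return ClusterAssignment(
        labels=pd.Series(labels, index=matrix.index, name="cluster_id"),
        centroids=centroids,
        wss=wss,
        k=k,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        wss_trace=trace,
    )


def elbow_wss(
    matrix: pd.DataFrame,
    k_range: range | list[int] = range(1, 11),
    iter_max: int = 500,
    n_init: int = 25,
    seed: int = 1,
) -> pd.Series:
    """WSS per k (best of restarts).  Each k also restarts from the previous
    solution's centroids plus the worst-fit point, which guarantees the
    reported WSS never increases with k."""
    ks = sorted(set(int(k) for k in k_range))
    X = matrix.to_numpy(dtype=float)
    if ks and ks[-1] > X.shape[0]:
        raise ValueError(f"k={ks[-1]} exceeds number of rows {X.shape[0]}")
    out = {}
    prev: ClusterAssignment | None = None
    for k in ks:
        init = None
        if prev is not None and prev.k == k - 1:
            centers = prev.centroids.to_numpy()
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2).min(axis=1)
            init = np.vstack([centers, X[d2.argmax()]])
        assign = kmeans_cluster(matrix, k, iter_max, n_init, seed, init_centers=init)
        out[k] = assign.wss
        prev = assign
    return pd.Series(out, name="wss").rename_axis("k")


def filter_regions_for_clustering(
    correlations: pd.DataFrame,
    breadth: pd.DataFrame | None = None,
    mode: str = "positive",
    rho_cut: float = 0.3,
) -> pd.Index:
    """Region filter mirroring the published analysis: for H3K27ac keep only
    positively correlated regions (``mode='positive'``); for H3K4me3 keep
    broad peaks with |rho| >= rho_cut (``mode='broad_correlated'``)."""
    if mode == "positive":
        keep = correlations.index[correlations["corr_class"] == "positive"]
    elif mode == "broad_correlated":
        if breadth is None:
            raise ValueError("breadth calls required for broad_correlated mode")
        corr = correlations["rho"].abs() >= rho_cut
        broad = breadth["breadth_class"] == "broad"
        keep = correlations.index[corr & broad.reindex(correlations.index, fill_value=False)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return keep
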