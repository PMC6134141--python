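"""Correlation-threshold clustering of triggered-average waveforms.

Swim-driven and stimulus-driven triggered averages are clustered
independently into activity archetypes.  The procedure is an iterative
centroid-growing scheme with a hard Pearson-correlation threshold
(default 0.75) and a minimum cluster size (50 ROIs at full experimental
scale; configurable for smaller data):

1. z-score each waveform (correlation is scale-invariant, so this only
   fixes the clustering geometry);
2. seed a cluster with the most-correlated remaining pair above the
   threshold (ties broken by lowest waveform index);
3. sweep: recompute the centroid, admit every remaining waveform whose
   correlation with it is at or above the threshold, until membership is
   stable;
4. remove the members and repeat from 2 while a seeding pair exists;
5. discard clusters smaller than the minimum size; their members are
   left unassigned.

Clusters are returned sorted by size, descending.  The procedure is
deterministic given the input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import InvalidParameterError

__all__ = ["Cluster", "CorrelationClusterer", "cluster_traces", "centroid"]


@dataclass
class Cluster:
    """One activity archetype: its members and mean waveform."""

    cluster_id: int
    event_kind: str
    member_ids: np.ndarray
    centroid: np.ndarray
    sem: np.ndarray

    @property
    def n_members(self) -> int:
        return int(self.member_ids.size)


def centroid(waveforms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean waveform and per-timepoint SEM over members."""
    W = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if W.shape[0] == 0:
        raise InvalidParameterError("centroid of an empty member set")
    mean = W.mean(axis=0)
    if W.shape[0] < 2:
        return mean, np.zeros_like(mean)
    return mean, W.std(axis=0, ddof=1) / np.sqrt(W.shape[0])


def _zscore_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores and a validity mask (constant rows are invalid)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    Z = np.zeros_like(X, dtype=float)
    Z[valid] = (X[valid] - mu[valid]) / sd[valid]
    return Z, valid


class CorrelationClusterer(ClusterMixin, BaseEstimator):
    """Correlation-threshold clustering (sklearn estimator).

    Parameters
    ----------
    threshold : float
        Minimum Pearson correlation between a member and the cluster
        centroid (default 0.75).
    min_size : int
        Minimum surviving cluster size (default 50, the full-scale
        experimental value; scale down for small datasets).
    max_sweeps : int
        Safety cap on membership sweeps per cluster.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index per waveform, -1 for unassigned.
    cluster_centers_ : ndarray
        Mean raw waveform per cluster (size-descending order).
    cluster_sems_ : ndarray
        Per-timepoint SEM of each cluster mean.
    """

    def __init__(self, threshold: float = 0.75, min_size: int = 50,
                 max_sweeps: int = 200):
        self.threshold = threshold
        self.min_size = min_size
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise InvalidParameterError("X must be an (n_waveforms, n_samples) array")
        if not 0.0 < self.threshold <= 1.0:
            raise InvalidParameterError("threshold must be in (0, 1]")
        if self.min_size < 1:
            raise InvalidParameterError("min_size must be >= 1")
        n, L = X.shape
        Z, valid = _zscore_rows(X)
        U = Z / np.sqrt(L)  # rows unit-norm; dot products are Pearson r

        labels = np.full(n, -1, dtype=int)
        pool = np.flatnonzero(valid)
        raw_clusters: list[np.ndarray] = []
        while pool.size >= 2:
            C = U[pool] @ U[pool].T
            np.fill_diagonal(C, -np.inf)
            flat = int(np.argmax(C))  # first maximum -> lowest-index tie-break
            best = C.ravel()[flat]
            if best < self.threshold:
                break
            i, j = np.unravel_index(flat, C.shape)
            members = {int(pool[min(i, j)]), int(pool[max(i, j)])}
            for _ in range(self.max_sweeps):
                idx = np.fromiter(sorted(members), dtype=int)
                cen = U[idx].mean(axis=0)
                cen_norm = np.linalg.norm(cen)
                if cen_norm == 0:
                    break
                r = (U[pool] @ cen) / cen_norm
                new_members = set(pool[r >= self.threshold].tolist())
                if not new_members:
                    new_members = members
                    break
                if new_members == members:
                    break
                members = new_members
            member_arr = np.fromiter(sorted(members), dtype=int)
            raw_clusters.append(member_arr)
            pool = np.setdiff1d(pool, member_arr, assume_unique=True)

        if self.min_size == 1:
            # no size floor: leftover waveforms stand as singleton clusters
            raw_clusters.extend(np.array([int(i)]) for i in pool)
            pool = pool[:0]

        surviving = [m for m in raw_clusters if m.size >= self.min_size]
        surviving.sort(key=lambda m: (-m.size, m[0]))
        centers, sems = [], []
        for cid, m in enumerate(surviving):
            labels[m] = cid
            c, s = centroid(X[m])
            centers.append(c)
            sems.append(s)
        self.labels_ = labels
        self.n_clusters_ = len(surviving)
        self.cluster_centers_ = np.asarray(centers) if centers else np.empty((0, L))
        self.cluster_sems_ = np.asarray(sems) if sems else np.empty((0, L))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_


def cluster_traces(
    averages: np.ndarray,
    threshold: float = 0.75,
    min_size: int = 50,
    event_kind: str = "swim",
    roi_ids: np.ndarray | None = None,
) -> tuple[list[Cluster], np.ndarray]:
    """Cluster triggered-average waveforms into archetypes.

    Returns the surviving clusters (size-descending) and the per-waveform
    label array (-1 = unassigned).  ``roi_ids`` maps waveform rows back to
    ROI identifiers.
    """
    X = np.atleast_2d(np.asarray(averages, dtype=float))
    ids = np.arange(X.shape[0]) if roi_ids is None else np.asarray(roi_ids)
    est = CorrelationClusterer(threshold=threshold, min_size=min_size).fit(X)
    clusters = [
        Cluster(
            cluster_id=cid,
            event_kind=event_kind,
            member_ids=ids[est.labels_ == cid],
            centroid=est.cluster_centers_[cid],
            sem=est.cluster_sems_[cid],
        )
        for cid in range(est.n_clusters_)
    ]
    return clusters, est.labels_
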