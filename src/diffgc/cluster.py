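"""Hierarchical clustering with centered-correlation distance and
centroid linkage.

The distance between samples (and between clusters) is ``1 - r`` where r is
the Pearson correlation of expression profiles over a fixed gene list.
Centroid linkage follows the Cluster-3.0 convention: a cluster is
represented by its mean expression profile and the inter-cluster distance
is the centered-correlation distance between centroids, recomputed after
each merge. This is deliberately not the Lance-Williams centroid update,
which assumes squared Euclidean distance and cannot express a correlation
metric. Merge heights are recorded as produced; centroid linkage may yield
inversions, which are flagged rather than hidden.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import ValidationError

log = logging.getLogger(__name__)


def _corr_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson r; distance 2 (maximal) if either profile is constant."""
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt((du * du).sum())
    nv = np.sqrt((dv * dv).sum())
    if nu == 0 or nv == 0:
        return 2.0
    r = float((du * dv).sum() / (nu * nv))
    return 1.0 - max(-1.0, min(1.0, r))


def centered_correlation_distance(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Sample x sample distance matrix d = 1 - r over rows of ``X``.

    Symmetric with zero diagonal, values in [0, 2]. Constant profiles have
    undefined correlation; their distance to every other sample is set to
    the maximum (2) and logged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need >= 2 samples and >= 2 genes")
    sds = X.std(axis=1)
    constant = sds == 0
    if constant.any():
        log.warning("%d constant sample profiles: distance set to 2",
                    int(constant.sum()))
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - r
    d[constant, :] = 2.0
    d[:, constant] = 2.0
    np.fill_diagonal(d, 0.0)
    return d


def centroid_linkage(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Agglomerate samples; returns a scipy-style (n-1, 4) linkage matrix.

    Row i records (cluster_a, cluster_b, height, size) for the i-th merge;
    original samples are clusters 0..n-1 and the i-th merge creates cluster
    n+i. Ties on merge distance are broken by the lexicographically smallest
    (a, b) pair of cluster indices, making the merge order deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 samples to cluster")
    # active clusters: id -> (member count, sum profile)
    sums = {i: X[i].copy() for i in range(n)}
    counts = {i: 1 for i in range(n)}
    active = list(range(n))
    dist: dict[tuple[int, int], float] = {}
    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            a, b = active[ai], active[bi]
            dist[(a, b)] = _corr_distance(X[a], X[b])

    Z = np.zeros((n - 1, 4))
    prev_height = -np.inf
    inversions = 0
    for step in range(n - 1):
        best = min(dist, key=lambda pair: (dist[pair], pair))
        height = dist[best]
        a, b = best
        if height < prev_height:
            inversions += 1
        prev_height = height
        new_id = n + step
        new_sum = sums[a] + sums[b]
        new_count = counts[a] + counts[b]
        Z[step] = (a, b, height, new_count)
        for c in (a, b):
            del sums[c], counts[c]
        active = [c for c in active if c not in (a, b)]
        dist = {pair: d for pair, d in dist.items()
                if a not in pair and b not in pair}
        centroid = new_sum / new_count
        for c in active:
            dist[(c, new_id)] = _corr_distance(sums[c] / counts[c], centroid)
        active.append(new_id)
        sums[new_id] = new_sum
        counts[new_id] = new_count
    if inversions:
        log.warning("centroid linkage produced %d dendrogram inversions", inversions)
    return Z


def cut_clusters(Z: np.ndarray, k: int) -> np.ndarray:
    """Undo the last k-1 merges, yielding k groups labelled 1..k.

    Labels are assigned in order of descending cluster size, ties by the
    smallest member sample index.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    cluster_of_id = {i: i for i in range(n)}
    for step in range(n - k):
        a, b, _, _ = Z[step]
        ra, rb = cluster_of_id[int(a)], cluster_of_id[int(b)]
        ra, rb = find(ra), find(rb)
        parent[rb] = ra
        members[ra] = members[ra] + members[rb]
        del members[rb]
        cluster_of_id[n + step] = ra
    groups = sorted(members.values(), key=lambda m: (-len(m), min(m)))
    labels = np.zeros(n, dtype=int)
    for label, group in enumerate(groups, start=1):
        labels[group] = label
    return labels


class CentroidLinkageClustering(ClusterMixin, BaseEstimator):
    """Scikit-learn estimator wrapping centered-correlation centroid linkage.

    Parameters
    ----------
    n_clusters:
        Number of flat clusters to cut from the dendrogram (default 2,
        the cluster I / cluster II split).

    Attributes
    ----------
    linkage_ : ndarray of shape (n_samples - 1, 4)
        scipy-style merge history (re-cuttable at any k).
    labels_ : ndarray of shape (n_samples,)
        Flat cluster labels in 1..n_clusters.
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = check_array(X)
        self.linkage_ = centroid_linkage(X)
        self.labels_ = cut_clusters(self.linkage_, self.n_clusters)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def assignment_table(sample_ids, labels) -> pd.DataFrame:
    """Tab-separated-ready (sample_id, cluster) table with I/II-style labels."""
    roman = {1: "I", 2: "II", 3: "III", 4: "IV"}
    named = [roman.get(int(l), str(l)) for l in labels]
    return pd.DataFrame({"sample_id": list(sample_ids), "cluster": named})
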