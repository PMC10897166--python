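"""Neighborhood-preservation metrics and set agreement.

KNN (local): the mean, over cells, of the fraction of each cell's K = 10
nearest pre-embedding neighbors that remain among its K = 10 nearest
2D-embedding neighbors.

KNC (global): the mean, over cells, of the fraction of each cell's K = 4
nearest cluster centers (per-dimension medians — robust to outliers) that
remain among its K = 4 nearest cluster centers in the 2D embedding.

Both use Euclidean distance with index (or cluster-id) tie-breaks and are
invariant under rigid motions of either space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .config import ValidationError
from .reliability import _coords


@dataclass
class LabeledCells:
    """Cell identifiers with cluster/type labels (>= 2 distinct clusters)."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(s) for s in self.cell_ids]
        self.labels = [str(s) for s in self.labels]
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids and labels differ in length")

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.labels))


def _knn_sets(X: np.ndarray, k: int) -> list[set]:
    n = X.shape[0]
    D = cdist(X, X)
    D[np.arange(n), np.arange(n)] = np.inf
    order = np.argsort(D, axis=1, kind="stable")
    return [set(order[i, :k]) for i in range(n)]


def knn_preservation(pre, emb, k: int = 10) -> float:
    """Mean per-cell overlap of K nearest neighbors between the two spaces."""
    P = _coords(pre)
    E = _coords(emb)
    n = P.shape[0]
    if E.shape[0] != n:
        raise ValidationError("pre-embedding and embedding are misaligned")
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must be in [1, {n - 1}], got {k}")
    pre_sets = _knn_sets(P, k)
    emb_sets = _knn_sets(E, k)
    return float(np.mean([len(a & b) / k for a, b in zip(pre_sets, emb_sets)]))


def _center_matrix(X: np.ndarray, labels: list[str], clusters: list[str]) -> np.ndarray:
    labels_arr = np.asarray(labels)
    return np.vstack([np.median(X[labels_arr == c], axis=0) for c in clusters])


def knc_preservation(
    pre, emb, labeled: LabeledCells, k: int = 4, exclude_own: bool = False
) -> float:
    """Mean per-cell overlap of the K nearest cluster centers.

    Centers are per-dimension medians of each cluster's member cells,
    computed separately in each space. By default a cell's own cluster
    counts among the candidates (its center is a legitimate nearest center);
    ``exclude_own`` drops it in both spaces.
    """
    P = _coords(pre)
    E = _coords(emb)
    n = P.shape[0]
    if E.shape[0] != n or len(labeled.labels) != n:
        raise ValidationError("pre-embedding, embedding and labels are misaligned")
    clusters = labeled.clusters
    c = len(clusters)
    if c < 2:
        raise ValidationError("KNC needs at least 2 distinct clusters")
    limit = c - 1 if exclude_own else c
    if not 1 <= k <= limit:
        raise ValidationError(f"k must be in [1, {limit}] for {c} clusters, got {k}")
    centers_pre = _center_matrix(P, labeled.labels, clusters)
    centers_emb = _center_matrix(E, labeled.labels, clusters)
    D_pre = cdist(P, centers_pre)
    D_emb = cdist(E, centers_emb)
    cluster_index = {c_: i for i, c_ in enumerate(clusters)}
    overlaps = np.empty(n)
    for i in range(n):
        dp = D_pre[i].copy()
        de = D_emb[i].copy()
        if exclude_own:
            own = cluster_index[labeled.labels[i]]
            dp[own] = np.inf
            de[own] = np.inf
        # stable argsort over cluster order = tie-break by sorted cluster id
        near_pre = set(np.argsort(dp, kind="stable")[:k])
        near_emb = set(np.argsort(de, kind="stable")[:k])
        overlaps[i] = len(near_pre & near_emb) / k
    return float(overlaps.mean())


def jaccard_index(a, b) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 1 when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
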