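"""Hierarchical clustering of the consensus distance and silhouette K-selection.

Ward linkage is applied directly to D = 1 - C. Because D need not be
Euclidean, merge heights are not guaranteed monotone (inversions are
possible); the dendrogram is therefore cut by merge order, which always
yields exactly K nested groups. The number of groups K* maximizes the total
silhouette score computed from the same consensus distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusPartition",
    "ward_linkage",
    "cut_tree",
    "silhouette_from_distance",
    "select_K",
]

_LINKAGE_METHODS = ("ward", "average", "single", "complete")


@dataclass
class ConsensusPartition:
    """Final hierarchical partition of the consensus matrix."""

    linkage: np.ndarray
    silhouette_curve: dict[int, float]
    selected_K: int
    labels: np.ndarray
    per_species_silhouette: np.ndarray
    species_ids: np.ndarray | None = None

    @property
    def n_species(self) -> int:
        return len(self.labels)

    @property
    def mean_silhouette(self) -> float:
        """Mean per-species silhouette at K* (the maximized objective is the
        total; the argmax is identical)."""
        return float(self.silhouette_curve[self.selected_K] / self.n_species)

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


def _check_distance(distance: np.ndarray) -> np.ndarray:
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    if distance.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(distance, distance.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distance), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return 0.5 * (distance + distance.T)


def ward_linkage(distance: np.ndarray, method: str = "ward") -> np.ndarray:
    """Agglomerative linkage over a precomputed dissimilarity matrix.

    Defaults to Ward's minimum-variance criterion (Lance-Williams update on
    the supplied dissimilarities); average/single/complete are exposed for
    applications expecting differently shaped clusters.
    """
    if method not in _LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    distance = _check_distance(distance)
    condensed = squareform(distance, checks=False)
    return _scipy_linkage(condensed, method=method)


def cut_tree(linkage: np.ndarray, n_groups: int) -> np.ndarray:
    """Cut a dendrogram into exactly ``n_groups`` labels (1..K).

    Replays the first N-K merges with a union-find, so the cut is well
    defined even when merge heights are non-monotone, and successive cuts
    are nested (the K+1 cut splits exactly one group of the K cut). Groups
    are numbered by first species occurrence.
    """
    linkage = np.asarray(linkage, dtype=float)
    n = linkage.shape[0] + 1
    if not 1 <= n_groups <= n:
        raise ValueError(f"K={n_groups} out of range [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - n_groups):
        a, b = int(linkage[step, 0]), int(linkage[step, 1])
        node = n + step
        parent[find(a)] = node
        parent[find(b)] = node
    roots = np.array([find(i) for i in range(n)])
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    return labels


def silhouette_from_distance(distance: np.ndarray, labels: np.ndarray
                             ) -> tuple[np.ndarray, float]:
    """Silhouette scores s_i = (b_i - a_i)/max(a_i, b_i) from a distance matrix.

    a_i is the mean distance from i to its own cluster's other members; b_i
    the smallest mean distance to any other cluster. Species in singleton
    clusters (a undefined) score 0 by convention. Returns the per-species
    scores and their total.
    """
    distance = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if distance.shape != (n, n):
        raise ValueError("distance/labels size mismatch")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette is undefined for a single group")
    onehot = (labels[:, None] == uniq[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    row_sums = distance @ onehot  # (N, K) summed distance to each cluster
    own_col = np.searchsorted(uniq, labels)
    own_count = counts[own_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = row_sums[np.arange(n), own_col] / (own_count - 1)
    other = row_sums / counts
    other[np.arange(n), own_col] = np.inf
    b = other.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(own_count > 1, (b - a) / np.maximum(a, b), 0.0)
    s = np.where((own_count > 1) & (np.maximum(a, b) == 0), 0.0, s)
    return s, float(s.sum())


def select_K(linkage: np.ndarray, distance: np.ndarray, k_range,
             species_ids=None) -> ConsensusPartition:
    """Choose the cut level maximizing the total silhouette score.

    Evaluates every K in ``k_range`` via cut + silhouette; ties within
    floating-point resolution break toward the smaller K (parsimony).
    """
    candidates = sorted(set(int(k) for k in k_range))
    n = np.asarray(linkage).shape[0] + 1
    if not candidates:
        raise ValueError("empty K range")
    if candidates[0] < 2 or candidates[-1] > n:
        raise ValueError(f"K range must lie within [2, {n}]")
    distance = _check_distance(distance)
    curve: dict[int, float] = {}
    best_k = None
    best_total = -np.inf
    best = None
    for k in candidates:
        labels = cut_tree(linkage, k)
        scores, total = silhouette_from_distance(distance, labels)
        curve[k] = total
        if total > best_total:
            best_k, best_total, best = k, total, (labels, scores)
    labels, scores = best
    return ConsensusPartition(
        linkage=np.asarray(linkage, dtype=float),
        silhouette_curve=curve,
        selected_K=best_k,
        labels=labels,
        per_species_silhouette=scores,
        species_ids=None if species_ids is None
        else np.asarray(species_ids, dtype=object),
    )
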