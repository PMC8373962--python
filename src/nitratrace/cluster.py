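"""Ward hierarchical clustering on isotope features, with GVF quality scores.

Samples are clustered on their raw (δ¹⁵N, δ¹⁸O) values with squared
Euclidean distance under Ward's minimum-variance criterion, separately per
water type.  Partition quality is reported as the goodness of variance fit

    GVF = 1 − SDCM / SDAM,

where SDAM is the total sum of squared deviations from the grand per-tracer
mean (pooled over tracers by summation, consistent with the squared
Euclidean geometry) and SDCM the same about each class mean.  A per-group
variant relates one group's internal scatter to its members' scatter about
the grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageTree",
    "ClusterResult",
    "WardClusterer",
    "squared_euclidean_matrix",
    "ward_linkage",
    "cut_tree",
    "gvf_partition",
    "gvf_per_group",
]


@dataclass(frozen=True)
class LinkageTree:
    """Agglomeration history: leaves are nodes ``0..n-1``; the merge at
    position ``i`` creates node ``n + i``.  ``cost`` is the increase in
    total within-cluster sum of squares caused by the merge."""

    merges: tuple[tuple[int, int, float, int], ...]
    n_leaves: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a full agglomeration has exactly n_leaves - 1 merges")

    @property
    def costs(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy convention (heights = sqrt(2·ΔSS))."""
        Z = np.zeros((len(self.merges), 4))
        for i, (a, b, cost, size) in enumerate(self.merges):
            Z[i] = (a, b, np.sqrt(max(2.0 * cost, 0.0)), size)
        return Z


@dataclass
class ClusterResult:
    """Flat cut of a linkage tree plus its GVF scores."""

    assignments: dict[str, int]
    k: int
    partition_gvf: float
    per_group_gvf: dict[int, float]
    feature_matrix: np.ndarray
    tree: LinkageTree | None = None
    sample_ids: list[str] = field(default_factory=list)


def squared_euclidean_matrix(features: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances; entry (a, b) = Σ_j (x_aj − x_bj)²."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(
            f"missing/non-finite feature at sample {bad[0]}, tracer column {bad[1]}"
        )
    D = cdist(X, X, metric="sqeuclidean")
    return (D + D.T) / 2.0  # enforce exact symmetry


def ward_linkage(features: np.ndarray) -> LinkageTree:
    """Agglomerate by Ward's criterion: each step merges the pair of clusters
    whose union minimizes the increase in total within-cluster sum of squares.

    Deterministic given the input row order.  Merge costs are reported as
    the within-SS increase itself (ΔSS), not the square-root height.
    """
    X = check_array(np.asarray(features, dtype=float), ensure_min_samples=2)
    Z = hierarchy.linkage(X, method="ward")
    merges = tuple(
        (int(a), int(b), float(h) ** 2 / 2.0, int(size)) for a, b, h, size in Z
    )
    return LinkageTree(merges=merges, n_leaves=X.shape[0])


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Flat ``k``-cluster assignment obtained by undoing the last ``k − 1``
    merges; labels are 1..k in order of first member appearance."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = np.arange(n + len(tree.merges))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idx, (a, b, _, _) in enumerate(tree.merges[: n - k]):
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node
    roots = [find(i) for i in range(n)]
    labels = np.zeros(n, dtype=int)
    relabel: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels


def _pooled_ss(X: np.ndarray) -> float:
    """Sum over samples and tracers of squared deviation from the column means."""
    return float(((X - X.mean(axis=0)) ** 2).sum())


def gvf_partition(features: np.ndarray, assignments: np.ndarray) -> float:
    """GVF = 1 − SDCM/SDAM of a partition; 1 when all classes are internally
    homogeneous, 0 for the trivial single-class partition."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(assignments)
    if X.shape[0] != labels.shape[0] or X.shape[0] < 1:
        raise ValueError("assignments must label every sample")
    sdam = _pooled_ss(X)
    if sdam == 0.0:
        logger.info("all samples identical; GVF defined as 1")
        return 1.0
    sdcm = sum(_pooled_ss(X[labels == lab]) for lab in np.unique(labels))
    return 1.0 - sdcm / sdam


def gvf_per_group(features: np.ndarray, assignments: np.ndarray, label: int) -> float:
    """Single-group GVF: 1 − (within-group SS about the group mean) /
    (SS of the group's members about the grand mean of all samples).

    This per-group construction is this package's documented reading of
    group-wise GVF reporting; the partition-level statistic is
    :func:`gvf_partition`.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(assignments)
    mask = labels == label
    if not mask.any():
        raise ValueError(f"label {label} not present in assignments")
    G = X[mask]
    if G.shape[0] == 1:
        logger.info("group %s has a single member; per-group GVF defined as 1", label)
        return 1.0
    about_grand = float(((G - X.mean(axis=0)) ** 2).sum())
    if about_grand == 0.0:
        logger.info("group %s coincides with the grand mean; per-group GVF = 1", label)
        return 1.0
    return 1.0 - _pooled_ss(G) / about_grand


class WardClusterer(ClusterMixin, BaseEstimator):
    """Ward minimum-variance clustering with GVF quality assessment.

    scikit-learn-style estimator: ``fit(X)`` builds the full linkage tree
    and cuts it at ``n_clusters``; fitted attributes expose the tree, the
    1-based labels, and the partition/per-group GVF scores.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of flat clusters to cut from the tree.
    standardize : bool, default=False
        Z-score each feature column before clustering.  Off by default:
        the dual nitrate isotopes share the ‰ scale.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster labels, 1..k by order of first member appearance.
    tree_ : LinkageTree
        Full agglomeration history with ΔSS merge costs.
    gvf_ : float
        Partition-level goodness of variance fit.
    per_group_gvf_ : dict[int, float]
        Per-label GVF scores.
    """

    def __init__(self, n_clusters: int = 2, standardize: bool = False):
        self.n_clusters = n_clusters
        self.standardize = standardize

    def fit(self, X, y=None):
        X = check_array(np.asarray(X, dtype=float), ensure_min_samples=2)
        if not 1 <= self.n_clusters <= X.shape[0]:
            raise ValueError(
                f"n_clusters must be in [1, {X.shape[0]}], got {self.n_clusters}"
            )
        F = X.copy()
        if self.standardize:
            sd = F.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            F = (F - F.mean(axis=0)) / sd
        self.feature_matrix_ = F
        self.tree_ = ward_linkage(F)
        self.labels_ = cut_tree(self.tree_, self.n_clusters)
        self.gvf_ = gvf_partition(F, self.labels_)
        self.per_group_gvf_ = {
            int(lab): gvf_per_group(F, self.labels_, int(lab))
            for lab in np.unique(self.labels_)
        }
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def gvf_across_k(self, k_max: int | None = None) -> dict[int, float]:
        """Partition GVF along nested cuts k = 1..k_max of the fitted tree."""
        check_is_fitted(self, "tree_")
        k_max = k_max or self.tree_.n_leaves
        return {
            k: gvf_partition(self.feature_matrix_, cut_tree(self.tree_, k))
            for k in range(1, k_max + 1)
        }

    def result(self, sample_ids: list[str] | None = None) -> ClusterResult:
        check_is_fitted(self, "labels_")
        ids = sample_ids or [str(i) for i in range(len(self.labels_))]
        return ClusterResult(
            assignments={sid: int(lab) for sid, lab in zip(ids, self.labels_)},
            k=self.n_clusters,
            partition_gvf=self.gvf_,
            per_group_gvf=self.per_group_gvf_,
            feature_matrix=self.feature_matrix_,
            tree=self.tree_,
            sample_ids=list(ids),
        )
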