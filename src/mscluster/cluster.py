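"""Scikit-learn-style estimator wrapping the multi-level MSC run."""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .core import Hierarchy, RunParams, run_msc
from .io import DistanceMatrix, as_distance_matrix, transform_distances

__all__ = ["MinimumSpanClustering"]


class MinimumSpanClustering(ClusterMixin, BaseEstimator):
    """Multi-level minimum span clustering of a precomputed distance matrix.

    Each node is linked to its nearest neighbor; connected components of the
    nearest-link graph are the level-1 clusters.  Clusters are renormalized
    to single nodes (inter-cluster distance = shortest cross pair) and the
    procedure repeats until at most ``n_limit`` groups remain.  Nodes whose
    nearest distance exceeds ``m * L_med`` (``L_med`` = median of the
    shortest-distance list) are split off as singleton outlier clusters at
    the last two levels.

    Parameters
    ----------
    m : float, default=3.0
        Outlier threshold multiplier.  ``math.inf`` disables outlier
        detection entirely.
    n_limit : int, default=3
        Minimum number of groups desired at the final level; clustering
        stops at the first level with at most this many groups.
    d : float, default=1.0
        Exponent of the ``E^d`` distance transform applied before
        clustering.  Any ``d > 0`` preserves the distance ordering, so the
        partition is unchanged unless the outlier rule fires.
    max_levels : int, default=20
        Safety cap on the number of clustering levels.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Final-level group index of each element.
    level_labels_ : ndarray of shape (n_levels_, n)
        Group index of each element at every level.
    hierarchy_ : Hierarchy
        The full multi-level result (partitions, link structure, matrices).
    n_levels_ : int
        Number of clustering levels.
    n_clusters_ : int
        Number of groups at the final level.
    element_labels_ : tuple of str
        Element identifiers, taken from the input's labels when present.
    outlier_labels_ : frozenset of str
        Elements inside nodes flagged as outliers at the final level.

    Examples
    --------
    >>> import numpy as np
    >>> from mscluster import MinimumSpanClustering
    >>> D = np.array([[0., 1., 9., 9.],
    ...               [1., 0., 9., 9.],
    ...               [9., 9., 0., 2.],
    ...               [9., 9., 2., 0.]])
    >>> MinimumSpanClustering(n_limit=2).fit_predict(D)
    array([0, 0, 1, 1])
    """

    def __init__(self, m: float = 3.0, n_limit: int = 3, d: float = 1.0,
                 max_levels: int = 20):
        self.m = m
        self.n_limit = n_limit
        self.d = d
        self.max_levels = max_levels

    def fit(self, X, y=None) -> "MinimumSpanClustering":
        """Cluster a distance matrix.

        ``X`` may be a labeled ``skbio`` ``DistanceMatrix``, a pandas
        DataFrame with matching index/columns, or a square symmetric
        ndarray (labels default to ``"0" .. "n-1"``).
        """
        dm = as_distance_matrix(X)
        if float(self.d) != 1.0:
            dm = transform_distances(dm, self.d)
        params = RunParams(m=float(self.m), n_limit=int(self.n_limit),
                           max_levels=int(self.max_levels))
        hierarchy = run_msc(dm, params)
        self.hierarchy_: Hierarchy = hierarchy
        self.n_features_in_ = dm.shape[0]
        self.element_labels_ = hierarchy.labels
        self.level_labels_ = hierarchy.membership
        self.labels_ = hierarchy.membership[-1].copy()
        self.n_levels_ = hierarchy.n_levels
        self.n_clusters_ = hierarchy.levels[-1].n_groups
        self.outlier_labels_ = hierarchy.outlier_elements(hierarchy.n_levels)
        return self

    def build_tree(self):
        """Assemble the fitted hierarchy into an :class:`~mscluster.tree.MSCTree`."""
        check_is_fitted(self, "hierarchy_")
        from .tree import build_tree

        return build_tree(self.hierarchy_)

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"pairwise": True}
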