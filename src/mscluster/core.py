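"""The minimum span clustering (MSC) algorithm.

MSC clusters an ``N``-element system from its pairwise distance matrix in
four repeated steps:

1. **Simplification** — the ``N x N`` matrix is reduced to the
   shortest-distance list: each node's nearest other node and that distance.
2. **Clustering** — nodes are partitioned into the connected components of
   the undirected nearest-link graph (every node contributes the edge to its
   nearest neighbor).  Inside each multi-node cluster the closest
   mutual-nearest pair is the *core link*; every other member joins through
   its own nearest link (a *member* / non-core link).
3. **Renormalization** — each cluster becomes a single node of the next
   level; the distance between two clusters is the shortest distance between
   any pair of their members.
4. **Outlier detection** — at the last two levels, a node whose nearest
   distance exceeds ``m * L_med`` (``L_med`` = median of the
   shortest-distance list) is split off as a singleton cluster before the
   level is formed.

Steps 1–3 repeat until the number of groups drops to the target ``N_limit``,
the partition stops changing, or a safety cap on levels is reached.  Because
every decision is a comparison of distances, the resulting hierarchy is
invariant under any strictly increasing rescaling of the distances (e.g.
``E^d`` for any ``d > 0``) as long as the outlier rule does not fire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import DistanceMatrix, as_distance_matrix

__all__ = [
    "RunParams",
    "ShortestDistanceList",
    "LevelClustering",
    "Hierarchy",
    "lower_median",
    "build_sdl",
    "detect_outliers",
    "cluster_level",
    "renormalize",
    "run_msc",
]


@dataclass(frozen=True)
class RunParams:
    """Run parameters of an MSC analysis.

    Parameters
    ----------
    m:
        Outlier threshold multiplier: a node is an outlier when its nearest
        distance exceeds ``m * L_med``.  ``math.inf`` disables detection.
    n_limit:
        Minimum number of groups desired at the final level; clustering
        stops at the first level with at most this many groups.
    max_levels:
        Safety cap on the number of levels.
    """

    m: float = 3.0
    n_limit: int = 3
    max_levels: int = 20

    def __post_init__(self) -> None:
        if not (self.m > 0):
            raise ValueError(f"m must be > 0, got {self.m!r}")
        if not (isinstance(self.n_limit, (int, np.integer)) and self.n_limit >= 1):
            raise ValueError(f"n_limit must be an integer >= 1, got {self.n_limit!r}")
        if not (isinstance(self.max_levels, (int, np.integer)) and self.max_levels >= 1):
            raise ValueError(f"max_levels must be an integer >= 1, got {self.max_levels!r}")


@dataclass(frozen=True)
class ShortestDistanceList:
    """Per-node nearest neighbor, its distance, and the list median L_med."""

    nearest: np.ndarray       # (n,) int: index of each node's nearest other node
    nearest_dist: np.ndarray  # (n,) float: distance to that neighbor
    l_med: float              # lower median of nearest_dist

    @property
    def n(self) -> int:
        return len(self.nearest)


def lower_median(x: Sequence[float] | np.ndarray) -> float:
    """Median of ``x``; the lower of the two middle values for even length."""
    arr = np.sort(np.asarray(x, dtype=float))
    if arr.size == 0:
        raise ValueError("median of empty list")
    return float(arr[(arr.size - 1) // 2])


def build_sdl(dm: DistanceMatrix | np.ndarray) -> ShortestDistanceList:
    """Simplify a distance matrix to its shortest-distance list.

    Ties between equidistant neighbors are broken toward the smallest node
    index, which keeps every downstream step deterministic.
    """
    values = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = values.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 nodes to build a shortest-distance list, got {n}")
    masked = values.copy()
    np.fill_diagonal(masked, np.inf)
    nearest = np.argmin(masked, axis=1)  # argmin takes the smallest index on ties
    nearest_dist = masked[np.arange(n), nearest]
    return ShortestDistanceList(nearest, nearest_dist, lower_median(nearest_dist))


def detect_outliers(sdl: ShortestDistanceList, m: float) -> frozenset[int]:
    """Nodes whose nearest distance exceeds ``m * L_med`` (single pass).

    The median is not recomputed after removal; detection is one sweep over
    the shortest-distance list.
    """
    if not (m > 0):
        raise ValueError(f"m must be > 0, got {m!r}")
    threshold = m * sdl.l_med
    return frozenset(int(i) for i in np.flatnonzero(sdl.nearest_dist > threshold))


@dataclass(frozen=True)
class LevelClustering:
    """One level's partition, with its link structure.

    ``groups`` partitions the level's node indices; groups are sorted by
    their smallest member and labeled ``L{level}G1``, ``L{level}G2``, ...
    Each multi-node group records its *core link* — its closest
    mutual-nearest pair — and, for every other member, the nearest link
    through which it joined.  Outliers are singleton groups with no links.
    """

    level: int
    groups: tuple[tuple[int, ...], ...]
    group_ids: tuple[str, ...]
    core_links: tuple[tuple[int, int, float] | None, ...]  # per group
    member_links: dict[int, tuple[int, float]] = field(default_factory=dict)
    outliers: frozenset[int] = frozenset()

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_nodes(self) -> int:
        return sum(len(g) for g in self.groups)

    def group_of(self) -> np.ndarray:
        """(n_nodes,) array mapping node index -> group index."""
        out = np.empty(self.n_nodes, dtype=int)
        for gi, members in enumerate(self.groups):
            out[list(members)] = gi
        return out


def cluster_level(
    dm: DistanceMatrix | np.ndarray,
    sdl: ShortestDistanceList,
    level: int = 1,
    outlier_set: Iterable[int] = (),
) -> LevelClustering:
    """Partition one level's nodes along their nearest links.

    Outlier nodes are set aside first as singleton groups; the nearest
    neighbors of the remaining nodes are recomputed without them, and the
    connected components of the resulting undirected nearest-link graph are
    the level's groups.
    """
    values = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = values.shape[0]
    if sdl.n != n:
        raise ValueError(f"shortest-distance list length {sdl.n} != matrix size {n}")
    outliers = frozenset(int(i) for i in outlier_set)
    if not all(0 <= i < n for i in outliers):
        raise ValueError("outlier index out of range")

    keep = np.array(sorted(set(range(n)) - outliers), dtype=int)
    comps: list[list[int]] = []
    nn_full: dict[int, tuple[int, float]] = {}  # node -> (nearest kept node, dist)
    if len(keep) >= 2:
        sub = values[np.ix_(keep, keep)].copy()
        np.fill_diagonal(sub, np.inf)
        nn_local = np.argmin(sub, axis=1)
        nd_local = sub[np.arange(len(keep)), nn_local]
        for li, node in enumerate(keep):
            nn_full[int(node)] = (int(keep[nn_local[li]]), float(nd_local[li]))
        rows = np.arange(len(keep))
        graph = coo_matrix(
            (np.ones(len(keep)), (rows, nn_local)), shape=(len(keep), len(keep))
        )
        n_comp, labels = connected_components(graph, directed=False)
        for c in range(n_comp):
            comps.append([int(keep[i]) for i in np.flatnonzero(labels == c)])
    elif len(keep) == 1:
        comps.append([int(keep[0])])

    all_groups = [sorted(g) for g in comps] + [[i] for i in sorted(outliers)]
    all_groups.sort(key=lambda g: g[0])

    core_links: list[tuple[int, int, float] | None] = []
    member_links: dict[int, tuple[int, float]] = {}
    for members in all_groups:
        if len(members) < 2:
            core_links.append(None)
            continue
        mutual = []
        for i in members:
            j, dij = nn_full[i]
            if i < j and nn_full[j][0] == i:
                mutual.append((dij, i, j))
        if not mutual:  # cannot happen for a nearest-link component
            raise RuntimeError(f"no mutual-nearest pair in group {members}")
        dij, ci, cj = min(mutual)
        core_links.append((ci, cj, dij))
        for i in members:
            if i not in (ci, cj):
                member_links[i] = nn_full[i]

    group_ids = tuple(f"L{level}G{k + 1}" for k in range(len(all_groups)))
    return LevelClustering(
        level=level,
        groups=tuple(tuple(g) for g in all_groups),
        group_ids=group_ids,
        core_links=tuple(core_links),
        member_links=member_links,
        outliers=outliers,
    )


def renormalize(dm: DistanceMatrix, clustering: LevelClustering) -> DistanceMatrix:
    """Coarse-grain a matrix: one node per group, min cross-pair distances."""
    values = dm.data
    n = values.shape[0]
    if clustering.n_nodes != n:
        raise ValueError("clustering does not partition the matrix's nodes")
    order = np.concatenate([np.asarray(g, dtype=int) for g in clustering.groups])
    starts = np.cumsum([0] + [len(g) for g in clustering.groups[:-1]])
    permuted = values[np.ix_(order, order)]
    reduced = np.minimum.reduceat(
        np.minimum.reduceat(permuted, starts, axis=0), starts, axis=1
    )
    reduced = np.minimum(reduced, reduced.T)
    np.fill_diagonal(reduced, 0.0)
    return DistanceMatrix(reduced, ids=list(clustering.group_ids))


@dataclass(frozen=True)
class Hierarchy:
    """The full multi-level MSC result.

    ``membership[l - 1, e]`` is the group index of original element ``e`` at
    level ``l``; ``level_matrices[l - 1]`` is the (renormalized) matrix the
    level was clustered from, whose node order matches the previous level's
    group order.
    """

    labels: tuple[str, ...]
    distance_matrix: DistanceMatrix
    levels: tuple[LevelClustering, ...]
    level_matrices: tuple[DistanceMatrix, ...]
    sdls: tuple[ShortestDistanceList, ...]
    membership: np.ndarray  # (n_levels, n) int
    stop_reason: str
    params: RunParams

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def group_counts(self) -> tuple[int, ...]:
        return tuple(lc.n_groups for lc in self.levels)

    def group_id(self, level: int, element: int) -> str:
        return self.levels[level - 1].group_ids[self.membership[level - 1, element]]

    def group_elements(self, level: int, group_index: int) -> list[str]:
        """Original element labels inside a level's group."""
        mask = self.membership[level - 1] == group_index
        return [self.labels[e] for e in np.flatnonzero(mask)]

    def outlier_elements(self, level: int) -> frozenset[str]:
        """Original elements inside nodes flagged as outliers at ``level``.

        At level 1 the flagged nodes are elements themselves; at deeper
        levels they are whole groups from the previous level.
        """
        lc = self.levels[level - 1]
        if not lc.outliers:
            return frozenset()
        if level == 1:
            return frozenset(self.labels[i] for i in lc.outliers)
        prev = self.membership[level - 2]
        out: set[str] = set()
        for node in lc.outliers:
            out.update(self.labels[e] for e in np.flatnonzero(prev == node))
        return frozenset(out)

    def to_assignments(self) -> pd.DataFrame:
        """One row per element: label, group id per level, outlier flags."""
        data: dict[str, list] = {"element": list(self.labels)}
        for lvl in range(1, self.n_levels + 1):
            lc = self.levels[lvl - 1]
            data[f"L{lvl}"] = [
                lc.group_ids[g] for g in self.membership[lvl - 1]
            ]
        for lvl in range(1, self.n_levels + 1):
            flagged = self.outlier_elements(lvl)
            if flagged:
                data[f"outlier_L{lvl}"] = [
                    int(lab in flagged) for lab in self.labels
                ]
        return pd.DataFrame(data)

    def summary(self) -> dict:
        """Per-level group counts/sizes, L_med, outlier counts, stop reason."""
        return {
            "n_elements": self.n,
            "n_levels": self.n_levels,
            "stop_reason": self.stop_reason,
            "params": {
                "m": self.params.m,
                "n_limit": self.params.n_limit,
                "max_levels": self.params.max_levels,
            },
            "levels": [
                {
                    "level": lc.level,
                    "n_groups": lc.n_groups,
                    "group_sizes": [
                        int((self.membership[lc.level - 1] == g).sum())
                        for g in range(lc.n_groups)
                    ],
                    "l_med": float(self.sdls[lc.level - 1].l_med),
                    "n_outlier_nodes": len(lc.outliers),
                    "outlier_elements": sorted(self.outlier_elements(lc.level)),
                }
                for lc in self.levels
            ],
        }


def _run_levels(
    dm: DistanceMatrix, params: RunParams, outlier_from: int | None
) -> tuple[list[LevelClustering], list[DistanceMatrix], list[ShortestDistanceList], str]:
    """One full multi-level pass; detection active at levels >= outlier_from."""
    levels: list[LevelClustering] = []
    matrices: list[DistanceMatrix] = []
    sdls: list[ShortestDistanceList] = []
    current = dm
    reason = "max_levels"
    for level in range(1, params.max_levels + 1):
        n_cur = current.shape[0]
        if n_cur < 2:
            reason = "n_limit"  # a single node is trivially <= n_limit
            break
        sdl = build_sdl(current)
        outliers: frozenset[int] = frozenset()
        if outlier_from is not None and level >= outlier_from and math.isfinite(params.m):
            outliers = detect_outliers(sdl, params.m)
        lc = cluster_level(current, sdl, level=level, outlier_set=outliers)
        levels.append(lc)
        matrices.append(current)
        sdls.append(sdl)
        if lc.n_groups <= params.n_limit:
            reason = "n_limit"
            break
        if lc.n_groups == n_cur:
            reason = "fixed_point"
            break
        if level == params.max_levels:
            reason = "max_levels"
            break
        current = renormalize(current, lc)
    return levels, matrices, sdls, reason


def run_msc(dm: DistanceMatrix | np.ndarray, params: RunParams | None = None) -> Hierarchy:
    """Run the full multi-level MSC analysis on a distance matrix.

    Outlier detection is meant for the last two levels, but the number of
    levels is only known after convergence.  The run is therefore two-pass:
    a first pass without detection fixes the level count ``L``; the second
    pass repeats the analysis with the ``m * L_med`` rule active from level
    ``L - 1`` onward, and its result is returned.
    """
    dm = as_distance_matrix(dm)
    if params is None:
        params = RunParams()
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 elements to cluster")

    first = _run_levels(dm, params, outlier_from=None)
    if math.isinf(params.m):
        levels, matrices, sdls, reason = first
    else:
        n_levels_first = len(first[0])
        levels, matrices, sdls, reason = _run_levels(
            dm, params, outlier_from=max(1, n_levels_first - 1)
        )

    n = dm.shape[0]
    membership = np.empty((len(levels), n), dtype=int)
    node_of_elem = np.arange(n)
    for li, lc in enumerate(levels):
        group_of_node = lc.group_of()
        membership[li] = group_of_node[node_of_elem]
        node_of_elem = membership[li]

    return Hierarchy(
        labels=tuple(dm.ids),
        distance_matrix=dm,
        levels=tuple(levels),
        level_matrices=tuple(matrices),
        sdls=tuple(sdls),
        membership=membership,
        stop_reason=reason,
        params=params,
    )
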