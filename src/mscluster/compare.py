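"""Partition comparison: pair-counting Jaccard similarity.

Two clusterings of the same elements are compared through their sets of
co-clustered (unordered) element pairs.  Writing ``S_p`` for the pairs that
share a group in partition ``p``, the Jaccard similarity is
``|S_p & S_q| / |S_p | S_q|`` — 1.0 iff the partitions are identical, 0.0
when no co-clustered pair is shared, and invariant to group relabeling.
The degenerate all-singleton vs all-singleton case (both pair sets empty)
is defined as 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics.cluster import pair_confusion_matrix

from .core import Hierarchy, RunParams, run_msc
from .io import DistanceMatrix, transform_distances

__all__ = ["Partition", "jaccard_pairs", "cut_partition", "compare_runs"]


@dataclass(frozen=True)
class Partition:
    """A hard partition: every element label maps to exactly one group."""

    assignment: Mapping[str, Hashable]

    def __post_init__(self) -> None:
        if len(self.assignment) == 0:
            raise ValueError("empty partition")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.assignment)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def co_clustered_pairs(self) -> frozenset[tuple[str, str]]:
        """All unordered co-clustered label pairs (for small partitions)."""
        by_group: dict[Hashable, list[str]] = {}
        for lab, grp in self.assignment.items():
            by_group.setdefault(grp, []).append(lab)
        pairs: set[tuple[str, str]] = set()
        for members in by_group.values():
            pairs.update(tuple(sorted(p)) for p in combinations(members, 2))
        return frozenset(pairs)


def jaccard_pairs(p: Partition, q: Partition) -> float:
    """Pair-counting Jaccard similarity between two partitions.

    Raises ``ValueError`` when the partitions cover different label sets.
    """
    if p.universe != q.universe:
        raise ValueError(
            "partitions cover different universes "
            f"({len(p.universe)} vs {len(q.universe)} labels, "
            f"symmetric difference size {len(p.universe ^ q.universe)})"
        )
    order = sorted(p.universe)
    a = pd.factorize(np.asarray([p.assignment[lab] for lab in order], dtype=object))[0]
    b = pd.factorize(np.asarray([q.assignment[lab] for lab in order], dtype=object))[0]
    c = pair_confusion_matrix(a, b)  # ordered-pair counts (2x unordered)
    n11, n10, n01 = c[1, 1] / 2, c[1, 0] / 2, c[0, 1] / 2
    union = n11 + n10 + n01
    if union == 0:  # both all-singleton: identical by convention
        return 1.0
    return float(n11 / union)


def cut_partition(hierarchy: Hierarchy, level: int) -> Partition:
    """The partition of the original elements at a given level."""
    if not (1 <= level <= hierarchy.n_levels):
        raise ValueError(
            f"level {level} out of range 1..{hierarchy.n_levels}"
        )
    lc = hierarchy.levels[level - 1]
    return Partition(
        {
            lab: lc.group_ids[g]
            for lab, g in zip(hierarchy.labels, hierarchy.membership[level - 1])
        }
    )


def compare_runs(
    dm: DistanceMatrix,
    params: RunParams,
    exponents: list[float],
) -> pd.DataFrame:
    """Cluster under each ``E^d`` transform and cross-tabulate agreement.

    Runs the full multi-level analysis on ``transform_distances(dm, d)`` for
    every exponent and reports, for every exponent pair and every level
    common to both runs, the pair-counting Jaccard similarity of the two
    partitions.  Columns: ``level, d_a, d_b, jaccard``.
    """
    if not exponents:
        raise ValueError("need at least one exponent")
    runs = {d: run_msc(transform_distances(dm, d), params) for d in exponents}
    rows = []
    for ia, da in enumerate(exponents):
        for db in exponents[ia:]:
            common = min(runs[da].n_levels, runs[db].n_levels)
            for level in range(1, common + 1):
                rows.append(
                    {
                        "level": level,
                        "d_a": da,
                        "d_b": db,
                        "jaccard": jaccard_pairs(
                            cut_partition(runs[da], level),
                            cut_partition(runs[db], level),
                        ),
                    }
                )
    return pd.DataFrame(rows, columns=["level", "d_a", "d_b", "jaccard"])
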