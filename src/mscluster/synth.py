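"""Planted-partition distance matrices for benchmarking MSC.

The generator emulates the shape of real molecular-distance data — tight
families of related sequences separated by much larger between-family
distances, plus a few far-away outliers — while keeping recovery provable.

Elements are organized into bottom-level *blocks*, optionally nested into
super-blocks of arbitrary depth.  The distance between two elements is
drawn uniformly from the interval assigned to the depth of their lowest
common super-block: ``noise_interval`` within a block, ``level_gaps[t]``
between blocks whose lowest common super-block sits ``t + 1`` levels up.
With *separation* enabled (each interval strictly below the next coarser
one) every nearest link stays within the finest enclosing block, so the
recovered level-``t`` partition equals the planted one.

Uniform draws alone do not guarantee that a block forms a **single**
nearest-link component (a block of four can split into two tight pairs).
Each block therefore uses a hub profile: distances from the block's first
element (the hub) are drawn from the lower half of the interval and all
other within-block pairs from the upper half, making the hub every
member's nearest neighbor.  The same trick is applied one level up — the
first child of each super-block is the hub child — so recovery holds at
every depth, for every seed.  Outlier elements are given distances at
least ``outlier_scale`` times the top of the coarsest interval to *every*
other element, which provably trips the ``m * L_med`` rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compare import Partition
from .io import DistanceMatrix, make_distance_matrix

__all__ = ["PlantedSpec", "PlantedResult", "generate"]

BlockTree = int | list  # nested lists of block indices


@dataclass(frozen=True)
class PlantedSpec:
    """Specification of a planted hierarchical distance matrix.

    Parameters
    ----------
    block_sizes:
        Elements per bottom-level block (each >= 2 when separation is on).
    hierarchy_tree:
        Nested lists of block indices describing how blocks group into
        super-blocks, e.g. ``[[0, 1], [2, 3]]``.  ``None`` puts all blocks
        directly under one root.
    noise_interval:
        ``(low, high)`` for within-block distances.  The default (0.5, 1.0)
        bounds the nearest-distance spread so the default outlier
        multiplier ``m = 3`` can never false-flag a planted element.
    level_gaps:
        One ``(low, high)`` interval per super-block depth, finest first.
    n_outliers:
        Number of extra far-away elements.
    outlier_scale:
        Outlier distances are drawn from
        ``[outlier_scale * top_high, 1.01 * outlier_scale * top_high]``.
    separation:
        Require strictly ordered intervals (guaranteed recovery).  Disable
        only for adversarial fixtures.
    seed:
        RNG seed; the same spec + seed always yields the same matrix.
    """

    block_sizes: tuple[int, ...] = (5, 5, 5)
    hierarchy_tree: BlockTree | None = None
    noise_interval: tuple[float, float] = (0.5, 1.0)
    level_gaps: tuple[tuple[float, float], ...] = ((5.0, 6.0),)
    n_outliers: int = 0
    outlier_scale: float = 100.0
    separation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(s) for s in self.block_sizes))
        object.__setattr__(
            self, "level_gaps", tuple((float(a), float(b)) for a, b in self.level_gaps)
        )
        if not self.block_sizes:
            raise ValueError("need at least one block")
        if any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        lo, hi = self.noise_interval
        if not (0 < lo < hi):
            raise ValueError(f"noise_interval must satisfy 0 < low < high, got {self.noise_interval}")
        for a, b in self.level_gaps:
            if not (0 < a < b):
                raise ValueError(f"level gap must satisfy 0 < low < high, got {(a, b)}")
        if self.separation:
            if any(s < 2 for s in self.block_sizes):
                raise ValueError(
                    "separation requires block sizes >= 2 (a singleton block's "
                    "nearest link necessarily leaves the block)"
                )
            prev_hi = hi
            for a, b in self.level_gaps:
                if a <= prev_hi:
                    raise ValueError(
                        f"separation violated: interval ({a}, {b}) overlaps the "
                        f"finer scale ending at {prev_hi}"
                    )
                prev_hi = b
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")
        if self.n_outliers and self.outlier_scale <= 1:
            raise ValueError("outlier_scale must exceed 1")


@dataclass(frozen=True)
class PlantedResult:
    """Generated matrix plus planted ground truth."""

    distance_matrix: DistanceMatrix
    partitions: tuple[Partition, ...]  # finest (blocks) -> coarsest
    outlier_labels: tuple[str, ...]
    spec: PlantedSpec


def _tree_height(node: BlockTree) -> int:
    if isinstance(node, int):
        return 0
    return 1 + max(_tree_height(child) for child in node)


def _max_branching_height(node: BlockTree) -> int:
    """Greatest height at which the tree actually branches (needs a gap)."""
    if isinstance(node, int):
        return 0
    own = _tree_height(node) if len(node) >= 2 else 0
    return max([own] + [_max_branching_height(child) for child in node])


def _leaves(node: BlockTree) -> list[int]:
    if isinstance(node, int):
        return [node]
    out: list[int] = []
    for child in node:
        out.extend(_leaves(child))
    return out


def _assign_bands(
    node: BlockTree,
    k: int,
    gaps: Sequence[tuple[float, float]],
    band_lo: np.ndarray,
    band_hi: np.ndarray,
) -> None:
    """Fill per-block-pair sampling bands for cross-child pairs of ``node``."""
    if isinstance(node, int):
        return
    if len(node) >= 2:
        height = _tree_height(node)
        lo, hi = gaps[height - 1]
        mid = (lo + hi) / 2.0
        child_leaves = [_leaves(child) for child in node]
        _fill_cross_bands(node, child_leaves, lo, mid, hi, band_lo, band_hi)
    for child in node:
        _assign_bands(child, k, gaps, band_lo, band_hi)


def _fill_cross_bands(node, child_leaves, lo, mid, hi, band_lo, band_hi) -> None:
    for i in range(len(node)):
        for j in range(i + 1, len(node)):
            # the first child is the hub: its cross distances sit in the
            # lower half-band, making it every sibling's nearest relative
            a, b = (lo, mid) if (i == 0 or j == 0) else (mid, hi)
            for bi in child_leaves[i]:
                for bj in child_leaves[j]:
                    band_lo[bi, bj] = band_lo[bj, bi] = a
                    band_hi[bi, bj] = band_hi[bj, bi] = b


def generate(spec: PlantedSpec) -> PlantedResult:
    """Draw a labeled distance matrix with planted structure from ``spec``."""
    k = len(spec.block_sizes)
    tree: BlockTree = spec.hierarchy_tree if spec.hierarchy_tree is not None else list(range(k))
    leaves = sorted(_leaves(tree))
    if leaves != list(range(k)):
        raise ValueError(
            f"hierarchy_tree must cover block indices 0..{k - 1} exactly, got {leaves}"
        )
    height = _tree_height(tree)
    needed = _max_branching_height(tree)
    if needed > len(spec.level_gaps):
        raise ValueError(
            f"hierarchy_tree has depth {needed} but only "
            f"{len(spec.level_gaps)} level gaps were given"
        )

    rng = np.random.default_rng(spec.seed)
    band_lo = np.full((k, k), np.nan)
    band_hi = np.full((k, k), np.nan)
    _assign_bands(tree, k, spec.level_gaps, band_lo, band_hi)

    block_of: list[int] = []
    labels: list[str] = []
    hub_flags: list[bool] = []
    for b, size in enumerate(spec.block_sizes):
        for e in range(size):
            block_of.append(b)
            labels.append(f"B{b + 1}N{e + 1}")
            hub_flags.append(e == 0)  # first element of each block is the hub
    n_core = len(labels)
    is_hub = np.array(hub_flags)

    n_lo, n_hi = spec.noise_interval
    n_mid = (n_lo + n_hi) / 2.0
    blocks = np.asarray(block_of)
    # per-pair sampling bands, vectorized over the upper triangle
    pair_lo = band_lo[blocks][:, blocks]
    pair_hi = band_hi[blocks][:, blocks]
    same = blocks[:, None] == blocks[None, :]
    hub_pair = is_hub[:, None] | is_hub[None, :]
    pair_lo = np.where(same, np.where(hub_pair, n_lo, n_mid), pair_lo)
    pair_hi = np.where(same, np.where(hub_pair, n_mid, n_hi), pair_hi)
    iu = np.triu_indices(n_core, k=1)
    draws = rng.uniform(pair_lo[iu], pair_hi[iu])
    values = np.zeros((n_core, n_core))
    values[iu] = draws
    values = values + values.T

    outlier_labels = tuple(f"OUT{o + 1}" for o in range(spec.n_outliers))
    if spec.n_outliers:
        top_hi = spec.level_gaps[height - 1][1] if height else n_hi
        floor = spec.outlier_scale * top_hi
        n_tot = n_core + spec.n_outliers
        full = np.zeros((n_tot, n_tot))
        full[:n_core, :n_core] = values
        for o in range(n_core, n_tot):
            draws = rng.uniform(floor, 1.01 * floor, size=o)
            full[o, :o] = full[:o, o] = draws
        values = full
        labels = labels + list(outlier_labels)

    dm = make_distance_matrix(values, labels)

    partitions: list[Partition] = []
    # depth 0: the blocks themselves
    assign: dict[str, str] = {
        lab: f"block{block_of[e] + 1}" for e, lab in enumerate(labels[:n_core])
    }
    assign.update({lab: lab for lab in outlier_labels})
    partitions.append(Partition(dict(assign)))
    # deeper depths: group blocks by their ancestor at each height
    for h in range(1, height + 1):
        ancestor = _ancestors_at_height(tree, h, k)
        assign = {
            lab: f"d{h}s{ancestor[block_of[e]] + 1}"
            for e, lab in enumerate(labels[:n_core])
        }
        assign.update({lab: lab for lab in outlier_labels})
        partitions.append(Partition(dict(assign)))

    return PlantedResult(dm, tuple(partitions), outlier_labels, spec)


def _ancestors_at_height(tree: BlockTree, h: int, k: int) -> np.ndarray:
    """Index of each block's enclosing subtree at height ``h`` (root-level
    subtrees are numbered in tree order; blocks above the cut keep their own
    slot)."""
    out = np.empty(k, dtype=int)
    counter = [0]

    def walk(node: BlockTree) -> None:
        if _tree_height(node) <= h:
            idx = counter[0]
            counter[0] += 1
            for leaf in _leaves(node):
                out[leaf] = idx
            return
        assert isinstance(node, list)
        for child in node:
            walk(child)

    walk(tree)
    return out
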