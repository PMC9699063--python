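# Methods

## The MSC model

Minimum span clustering treats a system of *N* elements as a network whose
only structure is the pairwise distance matrix. Distances need not satisfy
the triangle inequality; they only need to be non-negative, finite, and
(after averaging of near-symmetric input) symmetric. Typical sources are
evolutionary distances from substitution models (substitutions/site) and
BLAST E-values, optionally transformed as *E<sup>d</sup>*.

One clustering level consists of:

1. *Simplification* — the matrix is reduced to the shortest-distance list:
   `nearest[i]` (index of i's nearest other node) and `nearest_dist[i]`.
   This is the only place the full matrix is consulted, so a level costs
   O(N²) time and the whole run is a small multiple of that.
2. *Clustering* — groups are the connected components of the undirected
   graph with an edge {i, nearest[i]} for every node i. Every component of
   size ≥ 2 contains exactly one mutual-nearest pair under a consistent
   tie-break (see below); the minimum-distance such pair is the group's
   *core link*, and each remaining member is attached by its own nearest
   link (*member link*).
3. *Renormalization* — each group becomes one node; the distance between
   two groups is the minimum over cross pairs of the previous level's
   distances (and hence, inductively, of the original matrix).
4. *Outlier detection* — a node whose nearest distance exceeds
   m × L_med, where L_med is the median of the shortest-distance list, is
   split off as a singleton group **before** components are formed; the
   nearest neighbors of the remaining nodes are recomputed without the
   outliers. Detection is a single pass: L_med is not recomputed after
   removal, and removal is not iterated to a fixed point.

Levels repeat until the group count is ≤ N_limit, the partition stops
changing (fixed point — possible only when detection turns every node into
a singleton), or `max_levels` is hit. The stop reason is reported in the
result, never raised as an error.

### Placement of the outlier pass

Outlier detection belongs to the *last two* levels, but the final level is
unknown until the run converges. `run_msc` therefore runs twice: a first
pass without detection fixes the level count L, and a second pass enables
the rule from level L − 1 onward. "Onward" rather than exactly {L − 1, L}:
outlier singletons can raise a level's group count above N_limit and force
extra levels, and those extra final levels should be screened by the same
rule. When `m = inf` the second pass is skipped (it would be identical).
Detection at level ℓ ≥ 2 operates on the level's nodes, i.e. on whole
groups from level ℓ − 1; an isolated *cluster* far from everything is an
outlier in exactly the same sense as an isolated element at level 1.

### Determinism and tie-breaking

All ordering decisions are fixed:

- equidistant nearest neighbors resolve to the smallest node index
  (`np.argmin` semantics);
- the median of an even-length list is the **lower** middle value;
- groups are numbered G1, G2, … by their smallest member, which at deeper
  levels coincides with ordering by smallest original element, because the
  previous level's groups are already ordered that way;
- core links tie-break by (distance, smaller index pair);
- merge-edge anchors take the first (row-major, i.e. lexicographically
  smallest) element pair achieving the minimum cross distance.

With these rules, identical input and parameters give bit-identical output,
including exported files.

Consistent index tie-breaking also guarantees the structural fact the core
link relies on: in the nearest-link digraph every weakly connected component
contains exactly one cycle, and that cycle is a mutual-nearest 2-cycle
(around any longer cycle the nearest distances would have to be
non-increasing and hence all equal, and the index rule then forces a
contradiction). The implementation asserts this rather than assuming it.

### Invariance under monotone transforms

Every decision above is a comparison of two distances, so any strictly
increasing transform f with f(0) = 0 — in particular x ↦ x^d for d > 0 —
leaves the entire hierarchy unchanged, group ids included. One step is
**not** comparison-only: the outlier rule compares `nearest_dist` with
m × L_med, and under x ↦ x^d the effective multiplier becomes m^(1/d)
(x > m·L_med ⇔ x^d > m^d·L_med^d). The invariance is therefore exact
whenever detection does not fire, and the invariance tests and the
acceptance script run with `m = inf`. On real data with well-separated
outliers the flagged sets typically coincide across exponents — strongly
compressing transforms (d ≪ 1) simply stop flagging anything — but that is
a property of the data, not a theorem, and the documentation treats it as
such.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| m | outlier multiplier on L_med (unitless) | 3.0 | `inf` disables detection; values ≤ 1 flag aggressively |
| N_limit | minimum desired group count at the final level | 3 | stop at the first level with ≤ N_limit groups |
| d | exponent of the E^d input transform | 1.0 | any d > 0 is order-preserving |
| max_levels | safety cap on levels | 20 | generous: planted and random systems converge in ≤ ~6 |

The defaults are package choices (tunable per run); they produce a few
characteristic levels on the synthetic systems used throughout the tests.

## The synthetic generator

`mscluster.synth` plants a known partition: elements fall into blocks,
blocks optionally nest into super-blocks, and each pair's distance is drawn
uniformly from the interval assigned to the depth of its lowest common
super-block (`noise_interval` within blocks, `level_gaps[t]` between
blocks meeting t+1 levels up). With *separation* (each interval strictly
below the next coarser one) every nearest link stays inside the finest
enclosing block.

Separation alone does not make a block a *single* nearest-link component —
a uniform block of four can split into two tight pairs. The generator
therefore superimposes a **hub profile**: the first element of each block
draws its within-block distances from the lower half of `noise_interval`
and all other pairs from the upper half, making the hub every member's
nearest neighbor; the same rule is applied to the first child of each
super-block one level up. Under separation + hub profile, recovery of the
planted partition at each depth is exact for every seed, which turns the
recovery tests into deterministic guarantees instead of high-probability
statements.

Two defaults are deliberate:

- `noise_interval = (0.5, 1.0)` keeps every planted element's nearest
  distance in [0.5, 0.75], a max/min ratio ≤ 1.5 < 3, so the default m = 3
  can never false-flag a planted element;
- outlier elements draw **all** their distances from
  [100·top, 101·top] (scale 100 over the coarsest interval), so their
  nearest distance exceeds 3 × L_med whenever outliers are a minority —
  the m × L_med rule provably flags exactly the planted outliers.

What the generator does **not** emulate: triangle-inequality violations of
real E-values beyond what independent uniform draws produce, heteroscedastic
noise, overlapping families, or missing data. Passing the recovery tests
shows the algorithm is correct under its own assumptions (separated,
hub-connected families); it does not certify performance on data where
families genuinely overlap.

## MSC-tree conventions

- Mutual nearest links (i→j and j→i) collapse to one undirected core edge,
  so a level-ℓ group of k nodes contributes exactly k − 1 edges; a run
  ending in one group yields a spanning tree with n − 1 edges.
- A merge edge between two groups is anchored at the concrete element pair
  realizing the minimum cross-group distance in the **original** matrix
  (equal, by the min-of-mins induction, to the renormalized entry). The
  choice of anchor pair among ties is lexicographic.
- No edges are drawn between the final level's groups; the exported graph
  is connected iff the run ended in a single group.
- GraphML edge colors: level 1 black, level 2 red, level 3 yellow; merge
  edges created at the final level green; deeper levels gray.
- Newick: internal nodes are groups (`L{level}G{n}`), a leaf's branch
  length is the nearest-link distance through which it joined its level-1
  group, and a group's branch length is its joining link distance at the
  merging level. These are link annotations — the tree is **not** additive
  or ultrametric, and no height correction (e.g. halving) is applied.
  Multi-group final levels hang from an unlabeled root with zero-length
  edges so the output stays a single valid tree.

## Numerical choices and degenerate inputs

- Asymmetry up to 1e-6 relative (1e-12 absolute floor) is averaged;
  beyond that the matrix is rejected. The diagonal is forced to zero.
- Zero off-diagonal distances are legal (identical sequences) and always
  co-cluster at level 1. If more than half of all nearest distances are
  zero, L_med = 0 and every node with a positive nearest distance exceeds
  m × L_med — the rule is applied as defined.
- Missing entries are not supported: every pairwise distance must be
  present.
- Renormalization uses an O(N²) double `minimum.reduceat` over the
  group-permuted matrix; all reductions are exact min operations, so no
  floating-point accumulation error is introduced anywhere in the pipeline.
- File writers emit `repr(float)` (shortest exact round-trip), so
  read(write(M)) reproduces M bit-for-bit in all three dialects.

## Problem sizes used in tests and the acceptance script

Oracle-agreement and invariance checks use random uniform matrices with
n ≤ 50 (200 and 50 replicates); planted-recovery uses 100 seeded matrices of
3 blocks (12–18 elements) plus 30 outlier scenarios; the feasibility run
clusters a 3481-element system (59 planted families of 59) end to end —
about a second of compute — and verifies exact family recovery. These sizes
were chosen so the full suite exercises every guarantee at scales where the
independent brute-force oracles remain cheap to evaluate.

## Known limitations

- MSC is a hard-partition method: no overlapping or soft clusters.
- The nearest-link graph is sensitive to single bridging elements: one
  element placed between two families merges them at level 1 (chaining, as
  in single linkage).
- The outlier rule is scale-dependent (see invariance discussion) and uses
  a single pass; a different convention (recomputing L_med after removal,
  or iterating) would flag different sets on borderline data.
- Newick branch lengths are not evolutionary time estimates; use the edge
  list or GraphML when downstream analysis needs the actual link distances
  with their levels.
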