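# mscluster

Multi-level **minimum span clustering (MSC)** of distance matrices, with MSC-tree
construction for phylogenetic applications and pair-counting Jaccard comparison
of clusterings.

## The problem

Given the pairwise distances between *N* elements — evolutionary distances
between protein sequences, BLAST E-values, or any other non-negative
dissimilarity (no triangle inequality required) — we want a hierarchical
clustering of the system at its characteristic levels of organisation,
without specifying the number of clusters in advance, and fast enough for
systems of thousands of elements. Classical agglomerative clustering costs
O(N³) and needs the cluster count a priori; distance-based tree builders such
as neighbor joining are sensitive to monotone rescalings of the distance.

MSC addresses both issues with a simple, comparison-only procedure:

1. **Simplification.** The N×N matrix is reduced to the *shortest-distance
   list*: for each node, its nearest other node and that distance
   (ties broken toward the smaller index).
2. **Clustering.** Each node contributes the undirected link to its nearest
   neighbor; the connected components of this nearest-link graph are the
   clusters. Inside each cluster the closest mutual-nearest pair is the
   **core link**; every other member attaches through its own nearest link
   (a non-core, *member* link).
3. **Renormalization.** Each cluster becomes one node of the next level; the
   distance between two clusters is the shortest distance between any pair of
   their members. Steps 1–2 repeat on the renormalized matrix.
4. **Outlier detection.** At the last two levels, any node whose nearest
   distance exceeds *m* × *L*<sub>med</sub> (*L*<sub>med</sub> = median of the
   shortest-distance list) is split off as a singleton outlier cluster, and
   the remaining nodes are reclustered without it.

Iteration stops at the first level with at most *N*<sub>limit</sub> groups
(the minimum desired group count), at a fixed point, or at a safety cap.
Because every step compares distances rather than using their magnitudes,
the hierarchy is invariant under any strictly increasing transform of the
distances — e.g. E-values enter as *E<sup>d</sup>* and give the same
clustering for *d* = 1 and *d* = 0.02 (the outlier rule is the one
scale-dependent step; see `docs/methods.md`).

The multi-level result is assembled into an **MSC tree**: one graph over the
original elements whose edges carry their clustering level, core/non-core
status, and the inter-cluster distance, with each cluster merge anchored at
the concrete element pair realizing the minimum cross-cluster distance. A
hierarchy that ends in a single group over *n* elements yields a spanning
tree of *n* − 1 edges.

## Worked example

Five elements in two families: d(A,B)=1, d(A,C)=d(B,C)=2, d(D,E)=1, all
cross-family distances 10.

```python
import numpy as np
from mscluster import MinimumSpanClustering, make_distance_matrix

labels = list("ABCDE")
D = np.full((5, 5), 10.0); np.fill_diagonal(D, 0)
D[0,1] = D[1,0] = 1; D[0,2] = D[2,0] = 2; D[1,2] = D[2,1] = 2; D[3,4] = D[4,3] = 1
dm = make_distance_matrix(D, labels)

est = MinimumSpanClustering(m=10, n_limit=1).fit(dm)
print(est.hierarchy_.group_counts)   # (2, 1)
```

Level 1 finds the two families — {A, B, C} (A–B is the core link, C joins
through its nearest link to A) and {D, E} — and level 2 merges them into one
group, so the group counts per level are `(2, 1)`. The same run from the
command line:

```console
$ mscluster cluster toy.tsv -m 10 -n 1 -o toy --edges --newick
level 1: 2 groups, L_med=1, 0 outlier node(s)
level 2: 1 groups, L_med=10, 0 outlier node(s)
stopped: n_limit
wrote: toy.assignments.tsv, toy.summary.json, toy.edges.tsv, toy.nwk
```

`toy.assignments.tsv` maps every element to its group at each level
(`L1G1` = level 1, group 1):

```text
element L1      L2
A       L1G1    L2G1
B       L1G1    L2G1
C       L1G1    L2G1
D       L1G2    L2G1
E       L1G2    L2G1
```

`toy.edges.tsv` is the MSC tree — 4 edges over 5 elements, i.e. a spanning
tree; the level-2 merge is anchored at (A, D), a pair realizing the minimum
cross-family distance 10:

```text
source  target  level  kind           distance
A       B       1      core           1
C       A       1      member         2
D       E       1      core           1
A       D       2      inter_cluster  10
```

and `toy.nwk` renders the hierarchy for phylogenetic toolchains, with groups
as labeled internal nodes:

```text
((A:1.0,B:1.0,C:2.0)L1G1:10.0,(D:1.0,E:1.0)L1G2:10.0)L2G1;
```

The CLI also provides `mscluster compare` (cross-compare runs under
different *E<sup>d</sup>* exponents, or score a run against an external
assignment table with the pair-counting Jaccard similarity) and
`mscluster synth` (planted-partition benchmark matrices with ground truth).
Input matrices may be square delimited, lower-triangular, or PHYLIP distance
format; exports include the assignment table, a JSON run summary, the
edge-list TSV, GraphML (for Cytoscape), and Newick.

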