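"""MSC-tree assembly and export (edge list, GraphML, Newick).

The MSC tree integrates all clustering levels into one graph over the
original elements.  Level-1 groups contribute their core link (the group's
closest mutual-nearest pair) and one member link per remaining node.  Each
deeper level contributes, for every merge, the nearest-link structure among
the merged groups, with each group-to-group link realized as an edge between
the concrete element pair achieving the shortest cross-group distance and
annotated with that distance.  A hierarchy that ends in a single group over
``n`` elements therefore yields a spanning tree of ``n - 1`` edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np

from .core import Hierarchy

__all__ = [
    "TreeEdge",
    "MSCTree",
    "build_tree",
    "export_edge_list",
    "export_graphml",
    "export_newick",
    "export_cluster_boxes",
]

#: Edge colors by clustering level, matching the usual MSC-tree rendering
#: (level 1 black, level 2 red, level 3 yellow); merge edges created at the
#: final level are drawn green, deeper levels fall back to gray.
LEVEL_COLORS = {1: "black", 2: "red", 3: "yellow"}
FINAL_LEVEL_COLOR = "green"
FALLBACK_COLOR = "gray"


@dataclass(frozen=True)
class TreeEdge:
    source: str
    target: str
    level: int
    kind: str  # "core" | "member" | "inter_cluster"
    distance: float


@dataclass(frozen=True)
class MSCTree:
    """Integrated multi-level graph over the original elements."""

    labels: tuple[str, ...]
    node_groups: dict[str, dict[int, str]]       # label -> {level: group id}
    edges: tuple[TreeEdge, ...]
    cluster_boxes: dict[int, dict[str, tuple[str, ...]]]  # level -> gid -> labels
    n_levels: int

    def undirected_edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((e.source, e.target))) for e in self.edges}


def _anchor_pair(values: np.ndarray, elems_a: np.ndarray, elems_b: np.ndarray
                 ) -> tuple[int, int, float]:
    """Element pair realizing the min cross distance (lexicographic ties)."""
    sub = values[np.ix_(elems_a, elems_b)]
    flat = int(np.argmin(sub))
    i, j = np.unravel_index(flat, sub.shape)
    return int(elems_a[i]), int(elems_b[j]), float(sub[i, j])


def build_tree(hierarchy: Hierarchy) -> MSCTree:
    """Assemble a Hierarchy into the integrated MSC tree."""
    labels = hierarchy.labels
    values = hierarchy.distance_matrix.data
    edges: list[TreeEdge] = []

    # level 1: concrete element links
    lc1 = hierarchy.levels[0]
    for gi, members in enumerate(lc1.groups):
        core = lc1.core_links[gi]
        if core is not None:
            i, j, dij = core
            edges.append(TreeEdge(labels[i], labels[j], 1, "core", dij))
        for node in members:
            if node in lc1.member_links:
                tgt, dist = lc1.member_links[node]
                edges.append(TreeEdge(labels[node], labels[tgt], 1, "member", dist))

    # deeper levels: links between groups, anchored at the closest element pair
    for lvl in range(2, hierarchy.n_levels + 1):
        lc = hierarchy.levels[lvl - 1]
        prev_membership = hierarchy.membership[lvl - 2]
        elements_of = [
            np.flatnonzero(prev_membership == node) for node in range(lc.n_nodes)
        ]

        def add_group_edge(g: int, h: int) -> None:
            a, b, dist = _anchor_pair(values, elements_of[g], elements_of[h])
            edges.append(TreeEdge(labels[a], labels[b], lvl, "inter_cluster", dist))

        for gi in range(lc.n_groups):
            core = lc.core_links[gi]
            if core is not None:
                add_group_edge(core[0], core[1])
        for node, (tgt, _dist) in sorted(lc.member_links.items()):
            add_group_edge(node, tgt)

    node_groups = {
        lab: {
            lvl: hierarchy.group_id(lvl, e)
            for lvl in range(1, hierarchy.n_levels + 1)
        }
        for e, lab in enumerate(labels)
    }
    cluster_boxes = {
        lvl: {
            hierarchy.levels[lvl - 1].group_ids[g]: tuple(
                hierarchy.group_elements(lvl, g)
            )
            for g in range(hierarchy.levels[lvl - 1].n_groups)
        }
        for lvl in range(1, hierarchy.n_levels + 1)
    }
    edges.sort(key=lambda e: (e.level, e.source, e.target))
    return MSCTree(
        labels=labels,
        node_groups=node_groups,
        edges=tuple(edges),
        cluster_boxes=cluster_boxes,
        n_levels=hierarchy.n_levels,
    )


def edge_color(edge: TreeEdge, n_levels: int) -> str:
    if edge.kind == "inter_cluster" and edge.level == n_levels:
        return FINAL_LEVEL_COLOR
    return LEVEL_COLORS.get(edge.level, FALLBACK_COLOR)


def export_edge_list(tree: MSCTree, path: str | Path) -> Path:
    """TSV edge list: source, target, level, kind, distance (6 sig. digits)."""
    path = Path(path)
    lines = ["source\ttarget\tlevel\tkind\tdistance"]
    for e in tree.edges:  # already sorted (level, source, target)
        lines.append(f"{e.source}\t{e.target}\t{e.level}\t{e.kind}\t{e.distance:.6g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def to_networkx(tree: MSCTree) -> nx.Graph:
    """The MSC tree as an undirected networkx graph with full attributes."""
    g = nx.Graph()
    for lab in tree.labels:
        attrs = {f"L{lvl}": gid for lvl, gid in tree.node_groups[lab].items()}
        g.add_node(lab, **attrs)
    for e in tree.edges:
        g.add_edge(
            e.source,
            e.target,
            level=e.level,
            kind=e.kind,
            distance=float(e.distance),
            color=edge_color(e, tree.n_levels),
        )
    return g


def export_cluster_boxes(tree: MSCTree, path: str | Path) -> Path:
    """JSON mapping each level's group ids to their member element labels."""
    path = Path(path)
    payload = {
        f"L{lvl}": {gid: list(members) for gid, members in boxes.items()}
        for lvl, boxes in tree.cluster_boxes.items()
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def export_graphml(tree: MSCTree, path: str | Path) -> Path:
    """Write the MSC tree as GraphML (importable into Cytoscape)."""
    path = Path(path)
    nx.write_graphml(to_networkx(tree), path)
    return path


def export_newick(hierarchy: Hierarchy, path: str | Path | None = None) -> str:
    """Render the hierarchy as a Newick string (optionally writing ``path``).

    Internal nodes are the groups, labeled ``L{level}G{n}``; leaves are the
    element labels.  A leaf's branch length is the nearest-link distance
    through which it joined its level-1 group; a group's branch length to
    its parent is its nearest-group distance at the merging level.  These
    lengths are link annotations, not additive/ultrametric heights.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def joining_distance(lc, gi: int, node: int) -> float:
        """Distance of the nearest link through which ``node`` joined."""
        core = lc.core_links[gi]
        if core is not None and node in (core[0], core[1]):
            return float(core[2])
        if node in lc.member_links:
            return float(lc.member_links[node][1])
        return 0.0

    lc1 = hierarchy.levels[0]
    nodes_prev: list[dendropy.Node] = []
    for gi, members in enumerate(lc1.groups):
        gnode = dendropy.Node()
        gnode.label = lc1.group_ids[gi]
        for elem in members:
            leaf = dendropy.Node()
            leaf.taxon = taxa.new_taxon(hierarchy.labels[elem])
            leaf.edge.length = joining_distance(lc1, gi, elem)
            gnode.add_child(leaf)
        nodes_prev.append(gnode)

    for lvl in range(2, hierarchy.n_levels + 1):
        lc = hierarchy.levels[lvl - 1]
        nodes_cur: list[dendropy.Node] = []
        for gi, members in enumerate(lc.groups):
            gnode = dendropy.Node()
            gnode.label = lc.group_ids[gi]
            for child in members:
                child_node = nodes_prev[child]
                child_node.edge.length = joining_distance(lc, gi, child)
                gnode.add_child(child_node)
            nodes_cur.append(gnode)
        nodes_prev = nodes_cur

    if len(nodes_prev) == 1:
        tree.seed_node = nodes_prev[0]
    else:
        for gnode in nodes_prev:
            gnode.edge.length = 0.0
            tree.seed_node.add_child(gnode)

    newick = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick
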