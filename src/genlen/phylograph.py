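"""Rooted phylogenetic graphs: Newick I/O, pruning with location bookkeeping.

A `PhyloGraph` is the directed-graph view of a rooted tree: vertices in
preorder (root first), one edge per non-root vertex connecting it to its
parent, with strictly positive edge lengths φ.  Edge j corresponds to
vertex j+1.  Tips carry unique species labels.

`graph_locations` removes a set of target tips, collapses the resulting
unifurcations (summing edge lengths), and records each target's attachment
point on the reduced graph — attachment edge, distance from the edge's
rootward origin, and pendant length — so its eigenvector scores remain
computable against a basis built on the reduced graph.  `reattach` inverts
the operation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from genlen.records import canonical_name


@dataclass(frozen=True)
class PhyloGraph:
    """Directed phylogenetic graph in preorder array form.

    parent[i] is the parent vertex of i (−1 for the root, vertex 0);
    length[i] is the length of the edge above vertex i (0 at the root);
    labels[i] is the tip label, or None for internal vertices.
    """

    parent: np.ndarray
    length: np.ndarray
    labels: tuple

    def __post_init__(self):
        parent = np.asarray(self.parent, int)
        length = np.asarray(self.length, float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "length", length)
        nv = parent.size
        if nv < 2:
            raise ValueError("graph needs at least two vertices")
        if parent[0] != -1 or np.any(parent[1:] < 0):
            raise ValueError("vertex 0 must be the single root")
        if np.any(parent[1:] >= np.arange(1, nv)):
            raise ValueError("vertices must be in preorder (parent before child)")
        if np.any(length[1:] <= 0):
            raise ValueError("edge lengths must be strictly positive")
        has_child = np.zeros(nv, bool)
        has_child[parent[1:]] = True
        tips = np.flatnonzero(~has_child)
        tip_labels = [self.labels[int(t)] for t in tips]
        if any(lab is None or lab == "" for lab in tip_labels):
            raise ValueError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("duplicate tip labels")
        object.__setattr__(self, "_tips", tips)

    # -- basic structure ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.parent.size

    @property
    def n_edges(self) -> int:
        return self.parent.size - 1

    @property
    def tip_ids(self) -> np.ndarray:
        return self._tips

    @property
    def n_tips(self) -> int:
        return self._tips.size

    @property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[int(t)] for t in self._tips)

    def children(self) -> list:
        out = [[] for _ in range(self.n_vertices)]
        for v in range(1, self.n_vertices):
            out[self.parent[v]].append(v)
        return out

    def depths(self) -> np.ndarray:
        """Root-to-vertex path lengths."""
        d = np.zeros(self.n_vertices)
        for v in range(1, self.n_vertices):
            d[v] = d[self.parent[v]] + self.length[v]
        return d

    def root_path_edges(self, vertex: int) -> list:
        """Edge indices (edge j = vertex j+1) on the root→vertex path."""
        path = []
        v = int(vertex)
        while v != 0:
            path.append(v - 1)
            v = int(self.parent[v])
        return path[::-1]

    def influence_matrix(self) -> np.ndarray:
        """Binary tips × edges matrix; entry (i, j) = 1 iff edge j lies on
        the root-to-tip-i path."""
        B = np.zeros((self.n_tips, self.n_edges))
        for i, t in enumerate(self._tips):
            B[i, self.root_path_edges(int(t))] = 1.0
        return B

    def tip_distance_matrix(self) -> np.ndarray:
        """Patristic distances between tips (used for round-trip checks)."""
        d = self.depths()
        B = self.influence_matrix()
        phi = self.length[1:]
        shared = (B * phi) @ B.T
        td = d[self._tips]
        return td[:, None] + td[None, :] - 2.0 * shared

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloGraph":
        root = tree.seed_node
        order = list(root.preorder_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        nv = len(order)
        parent = np.full(nv, -1, int)
        length = np.zeros(nv)
        labels = [None] * nv
        for i, nd in enumerate(order):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError("tree has an edge without a length")
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled tip in tree")
                # same normalisation as the record compiler, so tree tips and
                # database species names line up regardless of underscore style
                labels[i] = canonical_name(nd.taxon.label)
        return cls(parent=parent, length=length, labels=tuple(labels))

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloGraph":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # duplicate taxa, malformed syntax, ...
            raise ValueError(f"invalid newick tree: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_vertices)]
        tree.seed_node = nodes[0]
        for v in range(1, self.n_vertices):
            nodes[self.parent[v]].add_child(nodes[v])
            nodes[v].edge.length = float(self.length[v])
        for t in self._tips:
            nodes[int(t)].taxon = taxa.new_taxon(self.labels[int(t)])
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def with_lengths(self, new_lengths: np.ndarray) -> "PhyloGraph":
        length = np.asarray(new_lengths, float).copy()
        length[0] = 0.0
        return PhyloGraph(parent=self.parent.copy(), length=length, labels=self.labels)


def tree_to_graph(newick_or_tree) -> PhyloGraph:
    """Convert a rooted Newick string / dendropy tree to a PhyloGraph.

    Rejects non-positive branch lengths and duplicate tip labels; root-to-tip
    path lengths equal the tree's tip depths.
    """
    if isinstance(newick_or_tree, PhyloGraph):
        return newick_or_tree
    if isinstance(newick_or_tree, dendropy.Tree):
        return PhyloGraph.from_dendropy(newick_or_tree)
    return PhyloGraph.from_newick(str(newick_or_tree))


def branch_length_variants(
    graph: PhyloGraph,
    mode: str,
    lower: PhyloGraph | None = None,
    upper: PhyloGraph | None = None,
) -> PhyloGraph:
    """Phylogenetic-uncertainty variants of a dated tree.

    ``point`` returns the graph unchanged; ``equal`` sets every branch
    length to 1 (the no-reliable-dating scenario); ``lower``/``upper``
    require alternative trees built from the divergence-time confidence
    bounds and return them after a tip-set consistency check.
    """
    if mode == "point":
        return graph
    if mode == "equal":
        return graph.with_lengths(np.ones(graph.n_vertices))
    if mode in ("lower", "upper"):
        alt = lower if mode == "lower" else upper
        if alt is None:
            raise ValueError(f"mode {mode!r} requires the corresponding bound tree")
        if set(alt.tip_labels) != set(graph.tip_labels):
            raise ValueError("bound tree carries a different tip set")
        return alt
    raise ValueError(f"unknown branch-length mode {mode!r}")


@dataclass(frozen=True)
class GraphLocation:
    """Attachment point of a removed tip on the reduced graph.

    ``edge`` indexes a reduced-graph edge; ``distance`` is measured from the
    edge's rootward origin (0 ≤ distance ≤ edge length, the upper end
    meaning attachment at the edge's child vertex); ``pendant`` is the
    length of the terminal branch down to the removed tip, including any
    collapsed intermediate edges.
    """

    species: str
    edge: int
    distance: float
    pendant: float


def graph_locations(
    graph: PhyloGraph, targets: Iterable[str]
) -> tuple[PhyloGraph, list[GraphLocation]]:
    """Remove target tips, collapse unifurcations, record attachment points.

    Returns the reduced graph and one `GraphLocation` per target (input
    order).  An empty target set returns the graph unchanged.
    """
    targets = list(targets)
    if not targets:
        return graph, []
    label2tip = {graph.labels[int(t)]: int(t) for t in graph.tip_ids}
    missing = [s for s in targets if s not in label2tip]
    if missing:
        raise ValueError(f"targets not in tree: {missing}")
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate targets")
    target_ids = {label2tip[s] for s in targets}
    if graph.n_tips - len(target_ids) < 2:
        raise ValueError("removing targets would leave fewer than 2 tips")

    nv = graph.n_vertices
    children = graph.children()
    depths = graph.depths()
    is_tip = np.zeros(nv, bool)
    is_tip[graph.tip_ids] = True

    # retained: vertex has >= 1 non-target descendant tip
    retained = np.zeros(nv, bool)
    for v in range(nv - 1, -1, -1):
        if is_tip[v]:
            retained[v] = v not in target_ids
        else:
            retained[v] = any(retained[c] for c in children[v])

    # kept: survives as a vertex of the reduced graph
    n_ret_children = np.array([sum(retained[c] for c in children[v]) for v in range(nv)])
    kept = retained & (is_tip | (np.arange(nv) == 0) | (n_ret_children >= 2))

    kept_ids = np.flatnonzero(kept)
    new_id = {int(v): i for i, v in enumerate(kept_ids)}

    def nearest_kept_ancestor(v: int) -> int:
        p = int(graph.parent[v])
        while not kept[p]:
            p = int(graph.parent[p])
        return p

    red_parent = np.full(kept_ids.size, -1, int)
    red_length = np.zeros(kept_ids.size)
    red_labels = [None] * kept_ids.size
    for v in kept_ids:
        i = new_id[int(v)]
        if v != 0:
            anc = nearest_kept_ancestor(int(v))
            red_parent[i] = new_id[anc]
            red_length[i] = depths[v] - depths[anc]
        if is_tip[v]:
            red_labels[i] = graph.labels[int(v)]
    reduced = PhyloGraph(parent=red_parent, length=red_length, labels=tuple(red_labels))

    red_children = reduced.children()

    locations = []
    for species in targets:
        t = label2tip[species]
        pendant = float(graph.length[t])
        v = int(graph.parent[t])
        while not retained[v]:
            pendant += float(graph.length[v])
            v = int(graph.parent[v])
        if kept[v]:
            if v == 0:
                # attachment at the root: distance 0 on its first reduced child edge
                child = min(red_children[0])
                edge, dist = child - 1, 0.0
            else:
                edge = new_id[v] - 1
                dist = float(reduced.length[new_id[v]])
        else:
            # v sits strictly inside a reduced edge; find its kept endpoints
            w = v
            while not kept[w]:
                w = next(c for c in children[w] if retained[c])
            anc = nearest_kept_ancestor(v)
            edge = new_id[w] - 1
            dist = float(depths[v] - depths[anc])
        locations.append(GraphLocation(species=species, edge=edge, distance=dist, pendant=pendant))
    return reduced, locations


def reattach(reduced: PhyloGraph, locations: Sequence[GraphLocation]) -> PhyloGraph:
    """Re-insert removed tips at their recorded locations.

    Inverts `graph_locations` up to vertex numbering: the returned graph has
    the same tip set and patristic distances as the original.
    """
    tol = 1e-9 * max(1.0, float(np.max(reduced.length)))
    # mutable node table: [parent, length, label]
    nodes: list[list] = [
        [int(reduced.parent[v]), float(reduced.length[v]), reduced.labels[v]]
        for v in range(reduced.n_vertices)
    ]

    by_edge: dict[int, list[GraphLocation]] = {}
    for loc in locations:
        if not 0 <= loc.edge < reduced.n_edges:
            raise ValueError(f"location for {loc.species!r} references unknown edge {loc.edge}")
        by_edge.setdefault(loc.edge, []).append(loc)

    for edge, locs in sorted(by_edge.items()):
        child = edge + 1
        total = float(reduced.length[child])
        locs = sorted(locs, key=lambda l: l.distance)
        cur_parent = nodes[child][0]
        prev_d = 0.0
        for loc in locs:
            d = float(loc.distance)
            if d < -tol or d > total + tol:
                raise ValueError(f"location for {loc.species!r} lies outside its edge")
            if d >= total - tol:
                # attachment at the child vertex itself
                nodes.append([child, float(loc.pendant), loc.species])
                continue
            if d - prev_d <= tol:
                # attachment at the current origin vertex (no split)
                nodes.append([cur_parent, float(loc.pendant), loc.species])
                continue
            nodes.append([cur_parent, d - prev_d, None])  # split vertex
            cur_parent = len(nodes) - 1
            prev_d = d
            nodes.append([cur_parent, float(loc.pendant), loc.species])
        nodes[child][0] = cur_parent
        nodes[child][1] = total - prev_d

    # renumber to preorder
    kids: dict[int, list[int]] = {}
    for i, (p, _, _) in enumerate(nodes):
        if p >= 0:
            kids.setdefault(p, []).append(i)
    order = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(kids.get(v, [])))
    remap = {old: new for new, old in enumerate(order)}
    parent = np.array([-1 if nodes[v][0] < 0 else remap[nodes[v][0]] for v in order], int)
    length = np.array([nodes[v][1] for v in order])
    labels = tuple(nodes[v][2] for v in order)
    return PhyloGraph(parent=parent, length=length, labels=labels)


def restrict_to(graph: PhyloGraph, species: Iterable[str]) -> PhyloGraph:
    """Prune the graph down to the given tip set (unifurcations collapsed)."""
    keep = set(species)
    unknown = keep - set(graph.tip_labels)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    drop = [s for s in graph.tip_labels if s not in keep]
    if not drop:
        return graph
    reduced, _ = graph_locations(graph, drop)
    return reduced
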