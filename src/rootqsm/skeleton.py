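"""Curve-skeleton extraction by geodesic binning of a shortest-path tree.

The cloud is turned into a symmetric k-nearest-neighbor graph (bridged into
a single component if necessary), Dijkstra's algorithm is run from a source
vertex at the root collar, and points are grouped by geodesic distance into
bins of length ``bin_length``.  Each bin is split into spatially coherent
clusters; cluster centroids become skeleton nodes and parent links follow
the shortest-path tree, yielding a rooted 1D skeleton of the root system.

``bin_length`` corresponds to the height-segmentation (HS) knob of
QSM-style reconstruction pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .pointcloud import PointCloud

__all__ = [
    "NeighborGraph",
    "ShortestPathTree",
    "SkeletonNode",
    "Skeleton",
    "build_neighbor_graph",
    "select_root_vertex",
    "shortest_path_tree",
    "collar_shortest_path_tree",
    "extract_skeleton",
]


@dataclass
class NeighborGraph:
    """Undirected weighted graph over cloud points; weights are Euclidean distances."""

    n_vertices: int
    adjacency: sp.csr_matrix  # symmetric, zero diagonal

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2


@dataclass
class ShortestPathTree:
    source: int
    dist: np.ndarray       # geodesic distance from source, meters
    parent: np.ndarray     # predecessor index; -1 at the source


@dataclass
class SkeletonNode:
    position: np.ndarray           # centroid of member points, meters
    bin_index: int
    member_points: np.ndarray      # indices into the cloud
    parent: int | None = None      # skeleton node id
    children: list[int] = field(default_factory=list)


@dataclass
class Skeleton:
    nodes: list[SkeletonNode]
    root_node: int

    @property
    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) node-id pairs."""
        return [
            (node.parent, i)
            for i, node in enumerate(self.nodes)
            if node.parent is not None
        ]

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes])


def build_neighbor_graph(pc: PointCloud, k: int = 10) -> NeighborGraph:
    """Symmetric k-NN graph, bridged to a single connected component.

    Disconnected components (occlusion gaps, separated root fragments) are
    joined by repeatedly adding the single shortest edge between the two
    closest components until the graph is connected.
    """
    n = len(pc)
    if n < 2:
        raise ValueError("need at least 2 points to build a neighbor graph")
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pc.coords)
    dist, nbr = nn.kneighbors(pc.coords)
    rows = np.repeat(np.arange(n), k_eff)
    cols = nbr[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    adj = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)  # symmetrize

    n_comp, labels = connected_components(adj, directed=False)
    while n_comp > 1:
        i, j, w = _closest_intercomponent_edge(pc.coords, labels)
        bridge = sp.coo_matrix(([w, w], ([i, j], [j, i])), shape=(n, n)).tocsr()
        adj = adj.maximum(bridge)
        n_comp, labels = connected_components(adj, directed=False)
    return NeighborGraph(n_vertices=n, adjacency=adj)


def _closest_intercomponent_edge(
    coords: np.ndarray, labels: np.ndarray
) -> tuple[int, int, float]:
    """Globally closest pair of points lying in two different components."""
    best = (None, None, np.inf)
    comps = np.unique(labels)
    # Query each component's points against a tree over all *other* points.
    for c in comps:
        mask = labels == c
        if mask.sum() >= len(labels) - mask.sum():
            continue  # query from the smaller side only, once per pair direction
        other_idx = np.flatnonzero(~mask)
        tree = cKDTree(coords[other_idx])
        d, j = tree.query(coords[mask])
        a = int(np.argmin(d))
        if d[a] < best[2]:
            best = (int(np.flatnonzero(mask)[a]), int(other_idx[j[a]]), float(d[a]))
    if best[0] is None:  # two components of equal size: fall back to brute pairs
        c0 = comps[0]
        i_idx = np.flatnonzero(labels == c0)
        j_idx = np.flatnonzero(labels != c0)
        tree = cKDTree(coords[j_idx])
        d, j = tree.query(coords[i_idx])
        a = int(np.argmin(d))
        best = (int(i_idx[a]), int(j_idx[j[a]]), float(d[a]))
    return best


def select_root_vertex(pc: PointCloud, slab: float = 0.01, search: float = 0.05) -> int:
    """Pick the collar vertex of an inverted (collar-down) cloud.

    Scans 1-cm z-slabs over the bottom ``search`` meters, selects the densest
    slab, and returns its lowest-z point; ties break to the lowest point
    index.  The density criterion makes the choice robust to a few stray
    points hanging below the collar.
    """
    z = pc.coords[:, 2]
    z0 = z.min()
    edges = np.arange(z0, z0 + search + slab, slab)
    counts, _ = np.histogram(z, bins=edges)
    dense = int(np.argmax(counts))  # argmax takes the first (lowest) on ties
    in_slab = np.flatnonzero((z >= edges[dense]) & (z <= edges[dense + 1]))
    if in_slab.size == 0:  # all points above the search window: fall back
        in_slab = np.arange(len(pc))
    zs = z[in_slab]
    return int(in_slab[np.argmin(zs)])  # argmin returns first -> lowest index


def collar_shortest_path_tree(
    g: NeighborGraph, pc: PointCloud, slab: float = 0.01
) -> ShortestPathTree:
    """Multi-source shortest-path tree seeded from the whole bottom slab.

    Geodesic distance from a single surface vertex wraps around the collar
    (points on the far side of the basal ring sit ~pi*r away), which smears
    the lowest bins into spiral artifacts.  Seeding Dijkstra from every
    point within ``slab`` meters of the lowest z instead makes distance
    behave like arc length along the root, with the entire collar
    cross-section at distance ~0.
    """
    z = pc.coords[:, 2]
    sources = np.flatnonzero(z <= z.min() + slab)
    dist, parent, _ = dijkstra(
        g.adjacency,
        directed=False,
        indices=sources,
        return_predecessors=True,
        min_only=True,
    )
    if not np.isfinite(dist).all():
        raise ValueError(
            "graph is disconnected; bridge components before the shortest-path tree"
        )
    parent = parent.astype(np.int64)
    parent[parent < 0] = -1  # every seed vertex acts as a root
    rep = select_root_vertex(pc, slab=slab)
    return ShortestPathTree(source=rep, dist=dist, parent=parent)


def shortest_path_tree(g: NeighborGraph, source: int) -> ShortestPathTree:
    """Dijkstra geodesics and predecessors from ``source`` over the graph."""
    if not 0 <= source < g.n_vertices:
        raise ValueError(f"source {source} out of range")
    dist, parent = dijkstra(
        g.adjacency, directed=False, indices=source, return_predecessors=True
    )
    if not np.isfinite(dist).all():
        raise ValueError(
            "graph is disconnected; bridge components before the shortest-path tree"
        )
    parent = parent.astype(np.int64)
    parent[source] = -1
    return ShortestPathTree(source=source, dist=dist, parent=parent)


def extract_skeleton(
    pc: PointCloud,
    spt: ShortestPathTree,
    bin_length: float,
    graph: NeighborGraph | None = None,
    max_extent_factor: float = 4.0,
    prune_min_points: int = 0,
) -> Skeleton:
    """Condense the shortest-path tree into a skeleton.

    Points are binned by ``floor(dist / bin_length)``; inside each bin,
    clusters are the connected components of the neighbor graph restricted to
    the bin (k-means sub-splitting any cluster whose spatial extent exceeds
    ``max_extent_factor * bin_length``).  Every cluster centroid becomes a
    node; a node's parent is the node containing the shortest-path-tree
    parents of the majority of its members.

    ``prune_min_points`` > 0 iteratively removes leaf nodes with fewer member
    points, folding their members into the parent node — this suppresses
    spurious one-node stubs on noisy tubes without touching real laterals.
    """
    if bin_length <= 0:
        raise ValueError("bin_length must be > 0")
    n = len(pc)
    if spt.dist.shape[0] != n:
        raise ValueError("shortest-path tree does not cover the cloud")

    bins = np.floor(spt.dist / bin_length).astype(np.int64)
    point_node = np.full(n, -1, dtype=np.int64)
    nodes: list[SkeletonNode] = []

    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        for cluster in _bin_clusters(pc.coords, members, graph, bin_length, max_extent_factor):
            node_id = len(nodes)
            nodes.append(
                SkeletonNode(
                    position=pc.coords[cluster].mean(axis=0),
                    bin_index=int(b),
                    member_points=cluster,
                )
            )
            point_node[cluster] = node_id

    root_node = int(point_node[spt.source])
    _link_parents(nodes, point_node, spt, root_node)
    if prune_min_points > 0:
        nodes, root_node = _prune(nodes, root_node, prune_min_points, pc.coords)
    return Skeleton(nodes=nodes, root_node=root_node)


def _bin_clusters(coords, members, graph, bin_length, max_extent_factor):
    """Split one geodesic bin into spatially disjoint clusters."""
    if graph is not None:
        sub = graph.adjacency[members][:, members]
        n_comp, labels = connected_components(sub, directed=False)
        comps = [members[labels == c] for c in range(n_comp)]
    else:
        comps = [members]
    out = []
    for comp in comps:
        out.extend(_split_by_extent(coords, comp, bin_length, max_extent_factor))
    return out


def _split_by_extent(coords, cluster, bin_length, max_extent_factor):
    """K-means sub-split (k = 1, 2, ...) until every part is compact."""
    limit = max_extent_factor * bin_length
    if _extent(coords[cluster]) <= limit or len(cluster) < 2:
        return [cluster]
    for k in range(2, min(len(cluster), 64) + 1):
        km = KMeans(n_clusters=k, n_init=3, random_state=0).fit(coords[cluster])
        parts = [cluster[km.labels_ == c] for c in range(k)]
        parts = [p for p in parts if len(p)]
        if all(_extent(coords[p]) <= limit for p in parts):
            return parts
    return parts


def _extent(xyz: np.ndarray) -> float:
    """Maximum pairwise distance (exact, via convex-hull vertices)."""
    if len(xyz) < 2:
        return 0.0
    pts = xyz
    if len(pts) > 50:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar/collinear) input: use all points
            pass
    if len(pts) > 2000:  # pathological hull; bbox diagonal upper bound
        span = pts.max(axis=0) - pts.min(axis=0)
        return float(np.linalg.norm(span))
    d = pdist(pts)
    return float(d.max()) if d.size else 0.0


def _link_parents(nodes, point_node, spt, root_node) -> None:
    for node_id, node in enumerate(nodes):
        if node_id == root_node:
            continue
        parents = spt.parent[node.member_points]
        parents = parents[parents >= 0]
        cand = point_node[parents]
        cand = cand[cand != node_id]  # ignore intra-node links
        if cand.size == 0:
            # isolated node (e.g. source-only bin sibling): attach to the
            # spatially nearest node in a strictly lower bin
            node.parent = _nearest_lower(nodes, node_id)
        else:
            vals, counts = np.unique(cand, return_counts=True)
            best = vals[counts == counts.max()]
            if len(best) == 1:
                node.parent = int(best[0])
            else:  # tie: spatially nearest candidate
                d = [np.linalg.norm(nodes[c].position - node.position) for c in best]
                node.parent = int(best[int(np.argmin(d))])
    # guard against rare same-bin 2-cycles
    for node_id, node in enumerate(nodes):
        if node.parent is None and node_id != root_node:
            node.parent = _nearest_lower(nodes, node_id)
    _break_cycles(nodes, root_node)
    for node_id, node in enumerate(nodes):
        if node.parent is not None:
            nodes[node.parent].children.append(node_id)


def _nearest_lower(nodes, node_id) -> int | None:
    node = nodes[node_id]
    cands = [
        (np.linalg.norm(n.position - node.position), i)
        for i, n in enumerate(nodes)
        if n.bin_index < node.bin_index
    ]
    return min(cands)[1] if cands else None


def _break_cycles(nodes, root_node) -> None:
    """Reroute any parent chain that fails to reach the root."""
    for node_id in range(len(nodes)):
        seen = set()
        cur = node_id
        while cur is not None and cur != root_node and cur not in seen:
            seen.add(cur)
            cur = nodes[cur].parent
        if cur in seen or cur is None:
            # cycle or dead end: cut at the offending node
            bad = node_id
            nodes[bad].parent = _nearest_lower(nodes, bad)
            if nodes[bad].parent is None:
                nodes[bad].parent = root_node if bad != root_node else None


def _prune(nodes, root_node, min_points, coords):
    """Drop small leaf nodes, merging their members into the parent."""
    alive = [True] * len(nodes)
    changed = True
    while changed:
        changed = False
        child_count = [0] * len(nodes)
        for i, node in enumerate(nodes):
            if alive[i] and node.parent is not None and alive[node.parent]:
                child_count[node.parent] += 1
        for i, node in enumerate(nodes):
            if (
                alive[i]
                and i != root_node
                and child_count[i] == 0
                and len(node.member_points) < min_points
                and node.parent is not None
            ):
                parent = nodes[node.parent]
                parent.member_points = np.concatenate(
                    [parent.member_points, node.member_points]
                )
                alive[i] = False
                changed = True
    remap = {}
    new_nodes: list[SkeletonNode] = []
    for i, node in enumerate(nodes):
        if alive[i]:
            remap[i] = len(new_nodes)
            new_nodes.append(node)
    for node in new_nodes:
        node.position = coords[node.member_points].mean(axis=0)
        node.parent = remap[node.parent] if node.parent is not None else None
        node.children = []
    for i, node in enumerate(new_nodes):
        if node.parent is not None:
            new_nodes[node.parent].children.append(i)
    return new_nodes, remap[root_node]
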