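import itertools

import numpy as np
import pytest

from rootqsm.pointcloud import PointCloud
from rootqsm.skeleton import (
    NeighborGraph,
    build_neighbor_graph,
    collar_shortest_path_tree,
    extract_skeleton,
    select_root_vertex,
    shortest_path_tree,
)


def brute_force_distances(n, edges, source):
    """Exhaustive enumeration of all simple paths: the independent oracle."""
    adj = {i: [] for i in range(n)}
    for i, j, w in edges:
        adj[i].append((j, w))
        adj[j].append((i, w))
    best = {source: 0.0}

    def walk(v, dist, seen):
        for u, w in adj[v]:
            if u in seen:
                continue
            d = dist + w
            if d < best.get(u, np.inf):
                best[u] = d
            walk(u, d, seen | {u})

    walk(source, 0.0, {source})
    return best


def graph_from_edges(n, edges):
    import scipy.sparse as sp

    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    vals = [e[2] for e in edges] * 2
    return NeighborGraph(n, sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr())


class TestBuildNeighborGraph:
    def test_two_points_single_edge(self):
        pc = PointCloud(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        g = build_neighbor_graph(pc, k=1)
        assert g.n_edges == 1
        assert g.edges[0] == (0, 1, pytest.approx(5.0))

    def test_collinear_chain_connected_after_symmetrization(self):
        pc = PointCloud(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
        g = build_neighbor_graph(pc, k=1)
        assert {(i, j) for i, j, _ in g.edges} == {(0, 1), (1, 2)}

    def test_bridges_clusters_with_minimal_edge(self, rng):
        a = rng.uniform(0, 0.1, size=(30, 3))
        b = rng.uniform(0, 0.1, size=(30, 3)) + [1.0, 0, 0]
        pc = PointCloud(np.vstack([a, b]))
        g = build_neighbor_graph(pc, k=4)
        # brute-force minimal inter-cluster distance
        from scipy.spatial.distance import cdist

        want = cdist(a, b).min()
        crossing = [
            w for i, j, w in g.edges if (i < 30) != (j < 30)
        ]
        assert len(crossing) == 1
        assert crossing[0] == pytest.approx(want)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            build_neighbor_graph(PointCloud(np.zeros((1, 3))), k=1)

    def test_weights_are_euclidean(self, rng):
        pts = rng.normal(size=(40, 3))
        g = build_neighbor_graph(PointCloud(pts), k=5)
        for i, j, w in g.edges:
            assert w == pytest.approx(np.linalg.norm(pts[i] - pts[j]), abs=1e-9)


class TestSelectRootVertex:
    def test_unique_minimum_is_chosen(self):
        pts = np.array([[0.0, 0, 0.5], [0.1, 0, 0.6], [0, 0.2, -0.1]])
        assert select_root_vertex(PointCloud(pts)) == 2

    def test_tie_returns_lowest_index(self):
        pts = np.array([[0.0, 0, 0.0], [1.0, 0, 0.0], [0, 0, 1.0]])
        assert select_root_vertex(PointCloud(pts)) == 0

    def test_synthetic_collar_found_on_basal_ring(self, small_root):
        pc, truth = small_root
        idx = select_root_vertex(pc)
        collar = truth.model.branches[0].base_position
        r0 = truth.model.branches[0].basal_radius
        assert np.linalg.norm(pc.coords[idx] - collar) <= r0 + 0.02


class TestShortestPathTree:
    def test_path_graph(self):
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        spt = shortest_path_tree(g, 0)
        np.testing.assert_allclose(spt.dist, [0, 1, 2])
        assert spt.parent.tolist() == [-1, 0, 1]

    def test_shortcut_not_taken(self):
        g = graph_from_edges(4, [(0, 1, 1), (1, 2, 1), (0, 2, 3), (2, 3, 1)])
        spt = shortest_path_tree(g, 0)
        assert spt.dist[3] == pytest.approx(3.0)  # via 0-1-2-3
        assert spt.parent[3] == 2 and spt.parent[2] == 1

    def test_parent_distances_consistent(self, rng):
        pts = rng.normal(size=(100, 3))
        g = build_neighbor_graph(PointCloud(pts), k=6)
        spt = shortest_path_tree(g, 0)
        adj = g.adjacency
        for v in range(1, 100):
            p = spt.parent[v]
            assert spt.dist[v] == pytest.approx(
                spt.dist[p] + adj[p, v], abs=1e-9
            )

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_enumeration_on_small_graphs(self, trial):
        g_rng = np.random.default_rng(1000 + trial)
        n = int(g_rng.integers(3, 9))
        all_pairs = list(itertools.combinations(range(n), 2))
        n_edges = int(g_rng.integers(n - 1, len(all_pairs) + 1))
        chosen = [all_pairs[i] for i in g_rng.choice(len(all_pairs), n_edges, replace=False)]
        # force connectivity with a random spanning chain
        perm = g_rng.permutation(n)
        chain = list(zip(perm[:-1], perm[1:]))
        edges = {tuple(sorted(e)) for e in chosen} | {tuple(sorted(e)) for e in chain}
        weighted = [(i, j, float(g_rng.uniform(0.1, 2.0))) for i, j in edges]
        g = graph_from_edges(n, weighted)
        spt = shortest_path_tree(g, 0)
        oracle = brute_force_distances(n, weighted, 0)
        for v in range(n):
            assert spt.dist[v] == pytest.approx(oracle[v], abs=1e-12)


class TestExtractSkeleton:
    def test_straight_line_yields_single_chain(self):
        z = np.linspace(0, 1, 200)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        pc = PointCloud(pts)
        g = build_neighbor_graph(pc, k=4)
        spt = shortest_path_tree(g, 0)
        skel = extract_skeleton(pc, spt, bin_length=0.05, graph=g)
        children = [len(n.children) for n in skel.nodes]
        assert max(children) == 1  # pure chain, no bifurcations
        for node in skel.nodes:
            assert abs(node.position[0]) < 1e-9 and abs(node.position[1]) < 1e-9

    def test_every_point_in_exactly_one_node(self, small_root):
        pc, _ = small_root
        g = build_neighbor_graph(pc, k=10)
        spt = collar_shortest_path_tree(g, pc)
        skel = extract_skeleton(pc, spt, bin_length=0.04, graph=g)
        seen = np.concatenate([n.member_points for n in skel.nodes])
        assert len(seen) == len(pc)
        assert len(np.unique(seen)) == len(pc)

    def test_child_bins_never_below_parent(self, small_root):
        pc, _ = small_root
        g = build_neighbor_graph(pc, k=10)
        spt = collar_shortest_path_tree(g, pc)
        skel = extract_skeleton(pc, spt, bin_length=0.04, graph=g)
        for node in skel.nodes:
            if node.parent is not None:
                assert node.bin_index >= skel.nodes[node.parent].bin_index

    def test_geodesic_monotonicity_along_paths(self, small_root):
        pc, _ = small_root
        g = build_neighbor_graph(pc, k=10)
        spt = collar_shortest_path_tree(g, pc)
        skel = extract_skeleton(pc, spt, bin_length=0.04, graph=g)
        for node in skel.nodes:
            if node.parent is not None:
                own = spt.dist[node.member_points].mean()
                up = spt.dist[skel.nodes[node.parent].member_points].mean()
                assert own > up

    def test_y_shape_splits_into_two_chains(self):
        # trunk along +z, two arms diverging at z = 1
        t = np.linspace(0, 1, 120)
        trunk = np.column_stack([np.zeros_like(t), np.zeros_like(t), t])
        s = np.linspace(0, 0.6, 80)
        arm1 = np.column_stack([s, np.zeros_like(s), 1 + s])
        arm2 = np.column_stack([-s, np.zeros_like(s), 1 + s])
        pc = PointCloud(np.vstack([trunk, arm1, arm2]))
        g = build_neighbor_graph(pc, k=4)
        spt = shortest_path_tree(g, 0)
        skel = extract_skeleton(pc, spt, bin_length=0.08, graph=g)
        n_leaves = sum(1 for n in skel.nodes if not n.children)
        n_junctions = sum(1 for n in skel.nodes if len(n.children) > 1)
        assert n_leaves == 2
        assert n_junctions == 1

    def test_rejects_nonpositive_bin(self, small_root):
        pc, _ = small_root
        g = build_neighbor_graph(pc, k=10)
        spt = collar_shortest_path_tree(g, pc)
        with pytest.raises(ValueError):
            extract_skeleton(pc, spt, bin_length=0.0)
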