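import numpy as np
import pytest

from rootqsm.pointcloud import PointCloud
from rootqsm.qsm import (
    Branch,
    Cylinder,
    CylinderFitError,
    RootModel,
    assign_orders,
    fit_cylinder,
    model_from_skeleton,
    triangle_centroid,
    triangle_normal,
)
from rootqsm.skeleton import (
    build_neighbor_graph,
    collar_shortest_path_tree,
    extract_skeleton,
    shortest_path_tree,
)


def cylinder_points(r=0.05, length=0.4, n=200, seed=0, sigma=0.0,
                    axis_point=(0, 0, 0), axis=(0, 0, 1), even_z=False):
    g = np.random.default_rng(seed)
    theta = g.uniform(0, 2 * np.pi, n)
    z = np.linspace(0, length, n) if even_z else g.uniform(0, length, n)
    radii = np.full(n, r) + (g.normal(0, sigma, n) if sigma > 0 else 0.0)
    d = np.asarray(axis, float)
    d = d / np.linalg.norm(d)
    probe = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = np.cross(d, probe)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return (
        np.asarray(axis_point, float)
        + z[:, None] * d
        + radii[:, None] * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    )


class TestFitCylinder:
    def test_noiseless_exact_recovery(self):
        pts = cylinder_points(even_z=True)
        cyl = fit_cylinder(pts, ((0, 0, 0.2), (0, 0, 1)))
        assert cyl.radius == pytest.approx(0.05, abs=1e-6)
        assert abs(cyl.axis @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-6)
        assert cyl.length == pytest.approx(0.4, abs=1e-3)
        assert cyl.rmse_fit < 1e-9

    def test_tilted_axis_with_offset_start(self):
        axis = np.array([0.3, -0.2, 1.0])
        pts = cylinder_points(axis_point=(1, 2, 3), axis=axis, seed=4)
        # seed the fit with a deliberately imperfect axis
        cyl = fit_cylinder(pts, ((1, 2, 3.2), axis + [0.05, 0.05, 0]))
        assert cyl.radius == pytest.approx(0.05, rel=1e-4)
        assert abs(cyl.axis @ (axis / np.linalg.norm(axis))) > 1 - 1e-6

    def test_noisy_monte_carlo_mean_radius(self):
        radii = [
            fit_cylinder(
                cylinder_points(sigma=0.001, seed=s), ((0, 0, 0.2), (0, 0, 1))
            ).radius
            for s in range(20)
        ]
        assert np.mean(radii) == pytest.approx(0.05, rel=0.05)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.linspace(0, 1, 6)])
        with pytest.raises(CylinderFitError):
            fit_cylinder(np.vstack([pts, pts[:1]]), ((0, 0, 0), (0, 0, 1)))

    def test_too_few_points_rejected(self):
        with pytest.raises(CylinderFitError, match="7"):
            fit_cylinder(np.zeros((5, 3)), ((0, 0, 0), (0, 0, 1)))

    def test_matches_brute_force_grid_search(self):
        """NLLS against an independent grid search over tilt and radius."""
        pts = cylinder_points(n=300, seed=9)
        fitted = fit_cylinder(pts, ((0, 0, 0.2), (0, 0, 1))).radius

        radii = np.linspace(0.04, 0.06, 41)  # +/- 20%, step 5e-4
        tilts = np.deg2rad(np.linspace(-5, 5, 11))
        best = (np.inf, None)
        for ta in tilts:
            for tb in tilts:
                d = np.array([np.sin(ta), np.sin(tb), 1.0])
                d /= np.linalg.norm(d)
                rel = pts - pts.mean(axis=0)
                dist = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
                for r in radii:
                    cost = ((dist - r) ** 2).sum()
                    if cost < best[0]:
                        best = (cost, r)
        assert abs(fitted - best[1]) <= (radii[1] - radii[0])


class TestTriangleGeometry:
    def test_unit_right_triangle_normal(self):
        n = triangle_normal((0, 0, 0), (1, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(n, [0, 0, 1])

    def test_collinear_vertices_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            triangle_normal((0, 0, 0), (1, 1, 1), (2, 2, 2))

    def test_normal_matches_cross_product_oracle(self, rng):
        for _ in range(200):
            g1, g2, g3 = rng.normal(size=(3, 3))
            n = triangle_normal(g1, g2, g3)
            np.testing.assert_allclose(n, np.cross(g2 - g1, g3 - g1), atol=1e-12)
            assert abs(n @ (g2 - g1)) < 1e-9 * np.linalg.norm(n)
            assert abs(n @ (g3 - g1)) < 1e-9 * np.linalg.norm(n)

    def test_centroid_examples_and_oracle(self, rng):
        np.testing.assert_allclose(
            triangle_centroid((0, 0, 0), (3, 0, 0), (0, 3, 0)), [1, 1, 0]
        )
        v = np.array([2.0, -1.0, 7.0])
        np.testing.assert_allclose(triangle_centroid(v, v, v), v)
        tri = rng.normal(size=(3, 3))
        np.testing.assert_allclose(
            triangle_centroid(*tri), tri.sum(axis=0) / 3.0, atol=1e-12
        )


def chain_model(radii, step=0.1):
    """Unbranched vertical cylinder chain with the given radii."""
    cyls = [
        Cylinder(start=(0, 0, i * step), end=(0, 0, (i + 1) * step), radius=r)
        for i, r in enumerate(radii)
    ]
    return RootModel(cylinders=cyls, cyl_parent=[-1] + list(range(len(radii) - 1)))


class TestAssignOrders:
    def test_unbranched_chain_is_single_order_zero_branch(self):
        model = assign_orders(chain_model([0.03, 0.03, 0.03]))
        assert len(model.branches) == 1
        assert model.branches[0].order == 0
        assert model.branches[0].parent_branch is None

    def test_thick_child_continues_thin_child_branches(self):
        # parent 3 cm splits into 3 cm and 1 cm children
        cyls = [
            Cylinder((0, 0, 0), (0, 0, 0.1), 0.03),
            Cylinder((0, 0, 0.1), (0, 0, 0.2), 0.03),
            Cylinder((0, 0, 0.1), (0.1, 0, 0.15), 0.01),
        ]
        model = assign_orders(RootModel(cylinders=cyls, cyl_parent=[-1, 0, 0]))
        orders = sorted(b.order for b in model.branches)
        assert orders == [0, 1]
        taproot = model.branches_of_order(0)[0]
        assert len(taproot.cylinders) == 2
        assert taproot.cylinders[-1].radius == 0.03

    def test_radius_tie_breaks_on_direction(self):
        cyls = [
            Cylinder((0, 0, 0), (0, 0, 0.1), 0.03),
            Cylinder((0, 0, 0.1), (0, 0, 0.2), 0.02),     # straight ahead
            Cylinder((0, 0, 0.1), (0.1, 0, 0.12), 0.02),  # sharp turn
        ]
        model = assign_orders(RootModel(cylinders=cyls, cyl_parent=[-1, 0, 0]))
        taproot = model.branches_of_order(0)[0]
        assert taproot.cylinders[-1].end[2] == pytest.approx(0.2)

    def test_cycle_rejected(self):
        cyls = [
            Cylinder((0, 0, 0), (0, 0, 1), 0.01),
            Cylinder((0, 0, 1), (0, 0, 2), 0.01),
        ]
        with pytest.raises(ValueError, match="cycle|root"):
            assign_orders(RootModel(cylinders=cyls, cyl_parent=[1, 0]))

    def test_child_order_is_parent_plus_one(self, small_root):
        pc, truth = small_root
        for b in truth.model.branches:
            if b.parent_branch is not None:
                assert b.order == truth.model.branches[b.parent_branch].order + 1

    def test_order_conservation_on_synthetic_truth(self, small_root):
        _, truth = small_root
        model = truth.model
        for q in (0, 1):
            side_children = sum(
                len([c for c in model.topology[i] ])
                for i, b in enumerate(model.branches)
                if b.order == q
            )
            assert side_children == len(model.branches_of_order(q + 1))


class TestModelFromSkeleton:
    def _skeleton(self, pc, bin_length=0.05, k=6, source=None):
        g = build_neighbor_graph(pc, k=k)
        if source is None:
            spt = collar_shortest_path_tree(g, pc)
        else:
            spt = shortest_path_tree(g, source)
        return extract_skeleton(pc, spt, bin_length=bin_length, graph=g)

    def test_noiseless_cylinder_single_branch_accurate_radii(self):
        pts = cylinder_points(r=0.03, length=1.0, n=4000, seed=2)
        pc = PointCloud(pts)
        skel = self._skeleton(pc)
        model = model_from_skeleton(pc, skel)
        assert len(model.branches) == 1
        for cyl in model.branches[0].cylinders:
            assert cyl.radius == pytest.approx(0.03, abs=1e-3)

    def test_cylinder_count_equals_skeleton_edges(self):
        pts = cylinder_points(r=0.03, length=1.0, n=4000, seed=2)
        pc = PointCloud(pts)
        skel = self._skeleton(pc)
        model = model_from_skeleton(pc, skel)
        assert model.n_cylinders == len(skel.edges)

    def test_branch_chains_are_contiguous(self, small_root):
        pc, _ = small_root
        skel = self._skeleton(pc, bin_length=0.04, k=10)
        model = model_from_skeleton(pc, skel, min_branch_length=0.08)
        for branch in model.branches:
            for a, b in zip(branch.cylinders[:-1], branch.cylinders[1:]):
                assert np.linalg.norm(a.end - b.start) < 1e-6

    def test_single_node_skeleton_rejected(self):
        pts = cylinder_points(n=50)
        pc = PointCloud(pts)
        skel = self._skeleton(pc, bin_length=10.0)
        with pytest.raises(ValueError, match="single node"):
            model_from_skeleton(pc, skel)

    def test_synthetic_y_root_two_branches(self):
        t = np.linspace(0, 1, 150)
        trunk = cylinder_points(r=0.03, length=1.0, n=3000, seed=5)
        arm = cylinder_points(
            r=0.015, length=0.5, n=1200, seed=6,
            axis_point=(0, 0, 1.0), axis=(0.6, 0, 0.8),
        )
        cont = cylinder_points(
            r=0.028, length=0.5, n=2000, seed=7, axis_point=(0, 0, 1.0)
        )
        pc = PointCloud(np.vstack([trunk, arm, cont]))
        skel = self._skeleton(pc, bin_length=0.05, k=8)
        model = model_from_skeleton(pc, skel, min_branch_length=0.1)
        assert sorted(b.order for b in model.branches) == [0, 1]
        assert model.branches_of_order(1)[0].basal_radius < 0.022
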