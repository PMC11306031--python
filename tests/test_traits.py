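import numpy as np
import pytest

from rootqsm.pointcloud import PointCloud
from rootqsm.qsm import Branch, Cylinder, RootModel
from rootqsm.traits import (
    MeasurementError,
    basal_diameter,
    cp_sweep,
    extract_traits,
    fit_circle,
)


def circle_points(center=(0, 0), r=1.0, n=50, arc=360.0, start=0.0, sigma=0.0, seed=0):
    g = np.random.default_rng(seed)
    theta = np.deg2rad(start) + np.deg2rad(arc) * g.uniform(0, 1, n)
    radii = r + (g.normal(0, sigma, n) if sigma else 0.0)
    return np.column_stack(
        [center[0] + radii * np.cos(theta), center[1] + radii * np.sin(theta)]
    )


class TestFitCircle:
    def test_noiseless_circle_exact(self):
        pts = circle_points(center=(1, 2), r=0.02)
        center, r, rms = fit_circle(pts)
        np.testing.assert_allclose(center, [1, 2], atol=1e-9)
        assert r == pytest.approx(0.02, abs=1e-9)
        assert rms < 1e-9

    def test_circumcircle_of_three_points(self):
        center, r, rms = fit_circle([(0, 0), (2, 0), (1, 1)])
        np.testing.assert_allclose(center, [1, 0], atol=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("arc", [120.0, 180.0, 300.0])
    def test_partial_arcs_exact(self, arc):
        pts = circle_points(center=(-0.5, 3), r=0.75, arc=arc, start=40.0)
        center, r, rms = fit_circle(pts)
        np.testing.assert_allclose(center, [-0.5, 3], atol=1e-7)
        assert r == pytest.approx(0.75, abs=1e-7)
        assert rms < 1e-9

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(ValueError):
            fit_circle(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle([(0, 0), (1, 0)])


class TestBasalDiameter:
    def _vertical_cylinder_cloud(self, r, sigma=0.0, seed=0, length=0.3, density=3e4):
        g = np.random.default_rng(seed)
        n = int(density * 2 * np.pi * r * length)
        theta = g.uniform(0, 2 * np.pi, n)
        z = g.uniform(0, length, n)
        radii = r + (g.normal(0, sigma, n) if sigma else 0.0)
        pts = np.column_stack([radii * np.cos(theta), radii * np.sin(theta), z])
        return PointCloud(pts)

    def _branch(self, r, length=0.3):
        return Branch(
            cylinders=[Cylinder((0, 0, 0), (0, 0, length), r)], order=0
        )

    def test_noiseless_cylinder_diameter(self):
        pc = self._vertical_cylinder_cloud(0.025)
        m = basal_diameter(pc, self._branch(0.025))
        assert m.RD == pytest.approx(5.0, abs=0.1)
        assert m.n_slices_averaged == 3

    def test_noisy_monte_carlo_mean(self):
        rds = [
            basal_diameter(
                self._vertical_cylinder_cloud(0.025, sigma=5e-4, seed=s),
                self._branch(0.025),
            ).RD
            for s in range(20)
        ]
        assert np.mean(rds) == pytest.approx(5.0, rel=0.02)

    def test_too_few_points_raises(self):
        pc = PointCloud(np.random.default_rng(0).uniform(0, 0.1, (10, 3)))
        with pytest.raises(MeasurementError, match="points"):
            basal_diameter(pc, self._branch(0.02))


def single_cylinder_model(r=0.05, length=1.0):
    cyl = Cylinder((0, 0, 0), (0, 0, length), r)
    branch = Branch(cylinders=[cyl], order=0)
    return RootModel(
        cylinders=[cyl], cyl_parent=[-1], branches=[branch], topology={0: []}
    )


class TestExtractTraits:
    def test_single_cylinder_closed_form(self):
        table = extract_traits(single_cylinder_model(), pc=None)
        assert table.root_length == pytest.approx(1.0)
        assert table.root_volume == pytest.approx(np.pi * 0.0025, abs=1e-7)
        assert table.root_surface_area == pytest.approx(2 * np.pi * 0.05, abs=1e-7)
        assert table.n_roots == 1
        assert table.mean_basal_diameter == pytest.approx(10.0)

    def test_threshold_filters_thin_laterals(self):
        # laterals of basal diameters 0.4 and 0.6 cm: only the thicker counts
        trunk = Cylinder((0, 0, 0), (0, 0, 1), 0.05)
        thin = Cylinder((0, 0, 0.4), (0.2, 0, 0.5), 0.002)
        thick = Cylinder((0, 0, 0.6), (-0.2, 0, 0.7), 0.003)
        branches = [
            Branch([trunk], order=0),
            Branch([thin], order=1, parent_branch=0, attach_point=thin.start),
            Branch([thick], order=1, parent_branch=0, attach_point=thick.start),
        ]
        model = RootModel(
            cylinders=[trunk, thin, thick],
            cyl_parent=[-1, 0, 0],
            branches=branches,
            topology={0: [1, 2], 1: [], 2: []},
        )
        table = extract_traits(model, pc=None, min_basal_diameter_cm=0.5)
        assert table.per_order_counts == {0: 1, 1: 1}

    def test_raising_threshold_never_increases_counts(self, small_root):
        _, truth = small_root
        lo = extract_traits(truth.model, pc=None, min_basal_diameter_cm=0.0)
        hi = extract_traits(truth.model, pc=None, min_basal_diameter_cm=1.5)
        for order, count in hi.per_order_counts.items():
            assert count <= lo.per_order_counts.get(order, 0)

    def test_totals_additive_over_branches(self, small_root):
        _, truth = small_root
        model = truth.model
        table = extract_traits(model, pc=None)
        assert table.root_length == pytest.approx(
            sum(b.length for b in model.branches), abs=1e-9
        )
        assert table.root_volume == pytest.approx(
            sum(c.volume for b in model.branches for c in b.cylinders), abs=1e-12
        )

    def test_unordered_model_rejected(self):
        model = RootModel(cylinders=[], cyl_parent=[])
        with pytest.raises(ValueError, match="order"):
            extract_traits(model, pc=None)


class TestCpSweep:
    def test_rows_match_cps_and_zero_cp_is_identity(self, small_root):
        pc, _ = small_root
        frame = cp_sweep(
            pc, [0.0, 0.004], pipeline_config={"hs": 0.04}, tree_id="t"
        )
        assert len(frame) == 2
        assert (frame["tree_id"] == "t").all()
        assert frame.loc[0, "n_points"] == len(pc)
        assert frame.loc[1, "n_points"] < len(pc)
        assert (frame["error"] == "").all()

    def test_empty_cp_list_rejected(self, small_root):
        pc, _ = small_root
        with pytest.raises(ValueError):
            cp_sweep(pc, [])

    def test_stage_failure_recorded_not_raised(self):
        # two points cannot be skeletonized; the sweep must still return
        pc = PointCloud(np.array([[0.0, 0, 0], [0.1, 0, 0.1]]))
        frame = cp_sweep(pc, [0.0], pipeline_config={"hs": 0.04})
        assert len(frame) == 1
        assert frame.loc[0, "error"] != ""
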