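"""Procedural root-system point clouds with exact cylinder-level ground truth.

Real excavated-root TLS scans are rarely shareable, so every stage of the
pipeline is exercised against synthetic root systems instead: a tapered
taproot with first- and second-order laterals, surface-sampled at TLS-like
density, with optional mm-scale radial Gaussian noise and scanner-shadow
occlusion (contiguous angular sectors, the dominant TLS failure mode on
excavated roots).

Clouds are generated collar-down (growth direction +z), i.e. already in the
frame the reconstruction works in.  Geometry is piecewise-constant-radius:
each branch is a straight chain of short constant-radius cylinders whose
radii follow a linear taper, so every ground-truth trait is an exact finite
sum over cylinders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pointcloud import PointCloud
from .qsm import Branch, Cylinder, RootModel
from .traits import TraitTable

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "generate_root_system",
    "vertical_and_horizontal_presets",
    "preset",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic root system.

    Defaults describe a mature deep-rooted ornamental/timber tree of the kind
    field studies excavate: ~2 m rooting depth, taproot basal diameter 8 cm,
    a handful of coarse first-order laterals each carrying a couple of
    second-order laterals, and a surface point density giving a ~4-5 mm
    point spacing (a registered multi-station TLS scan).
    """

    taproot_length: float = 2.0          # m
    taproot_basal_radius: float = 0.04   # m
    taper_rate: float = 0.35             # fraction of basal radius lost per m
    n_first_order: int = 5
    n_second_order_per_first: int = 2
    branch_angle_deg: float = 45.0       # mean insertion angle off the parent axis
    child_radius_ratio: float = 0.55     # child basal radius / parent radius at attachment
    point_density: float = 2.0e4         # points per m^2 of lateral surface
    noise_sigma: float = 0.001           # m, radial Gaussian (clipped at 6 sigma)
    occlusion_fraction: float = 0.0      # fraction of each branch's circumference shadowed
    seed: int = 0
    # geometry shaping (secondary knobs)
    lateral_length_factor: float = 0.45  # child length / parent length
    angle_jitter_deg: float = 5.0
    segment_length: float = 0.1          # m, ground-truth cylinder length
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if min(self.taproot_length, self.taproot_basal_radius, self.point_density) <= 0:
            raise ValueError("lengths, radii and density must be > 0")
        if not 0.0 <= self.occlusion_fraction < 1.0:
            raise ValueError("occlusion_fraction must be in [0, 1)")
        if not 0.0 < self.child_radius_ratio <= 1.0:
            raise ValueError("child_radius_ratio must be in (0, 1]")
        if self.noise_sigma < 0 or self.taper_rate < 0:
            raise ValueError("noise_sigma and taper_rate must be >= 0")


@dataclass
class GroundTruth:
    """True cylinder model and analytically derived traits."""

    model: RootModel
    traits: TraitTable

    def reference_roots(self) -> list[tuple[int, np.ndarray]]:
        """(order, basal position) pairs for detection matching."""
        return [(b.order, b.base_position.copy()) for b in self.model.branches]


# ---------------------------------------------------------------------------
# construction


@dataclass
class _BranchPlan:
    base: np.ndarray
    direction: np.ndarray  # unit
    length: float
    base_radius: float
    order: int
    parent_branch: int | None
    parent_cyl_of_attach: int | None  # global cylinder id on the parent


def _taper_radius(r0: float, s: float, rate: float) -> float:
    return r0 * max(1.0 - rate * s, 0.2)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tilted_direction(parent_dir, angle_deg, azimuth, min_z=0.05):
    """Unit vector at ``angle_deg`` off ``parent_dir`` at the given azimuth."""
    d = _unit(parent_dir)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(d @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, probe))
    e2 = np.cross(d, e1)
    a = np.deg2rad(angle_deg)
    out = np.cos(a) * d + np.sin(a) * (np.cos(azimuth) * e1 + np.sin(azimuth) * e2)
    return _unit(out)


def _plan_branches(spec: SynthSpec) -> list[_BranchPlan]:
    rng = np.random.default_rng([spec.seed, 0])
    plans = [
        _BranchPlan(
            base=np.zeros(3),
            direction=np.array([0.0, 0.0, 1.0]),
            length=spec.taproot_length,
            base_radius=spec.taproot_basal_radius,
            order=0,
            parent_branch=None,
            parent_cyl_of_attach=None,
        )
    ]
    # first-order laterals: stratified heights and azimuths + seeded jitter
    first_ids = []
    n1 = spec.n_first_order
    for i in range(n1):
        frac = 0.15 + 0.7 * (i + 0.5) / n1 + rng.uniform(-0.25, 0.25) * 0.7 / n1
        s = frac * spec.taproot_length
        azimuth = 2 * np.pi * i / n1 + rng.uniform(-0.3, 0.3)
        angle = spec.branch_angle_deg + rng.normal(0, spec.angle_jitter_deg)
        direction = _tilted_direction(np.array([0.0, 0.0, 1.0]), angle, azimuth)
        parent_r = _taper_radius(spec.taproot_basal_radius, s, spec.taper_rate)
        first_ids.append(len(plans))
        plans.append(
            _BranchPlan(
                base=np.array([0.0, 0.0, s]),
                direction=direction,
                length=spec.lateral_length_factor * spec.taproot_length
                * float(rng.uniform(0.85, 1.15)),
                base_radius=spec.child_radius_ratio * parent_r,
                order=1,
                parent_branch=0,
                parent_cyl_of_attach=None,  # resolved during cylinder build
            )
        )
    # second-order laterals off each first-order branch
    for bi in first_ids:
        parent = plans[bi]
        n2 = spec.n_second_order_per_first
        for j in range(n2):
            frac = 0.2 + 0.6 * (j + 0.5) / n2 + rng.uniform(-0.2, 0.2) * 0.6 / n2
            s = frac * parent.length
            # redraw azimuth until the child does not dive below the collar
            for _ in range(64):
                azimuth = rng.uniform(0, 2 * np.pi)
                angle = spec.branch_angle_deg + rng.normal(0, spec.angle_jitter_deg)
                direction = _tilted_direction(parent.direction, angle, azimuth)
                if direction[2] >= 0.05:
                    break
            parent_r = _taper_radius(parent.base_radius, s, spec.taper_rate)
            plans.append(
                _BranchPlan(
                    base=parent.base + s * parent.direction,
                    direction=direction,
                    length=spec.lateral_length_factor * parent.length
                    * float(rng.uniform(0.85, 1.15)),
                    base_radius=spec.child_radius_ratio * parent_r,
                    order=2,
                    parent_branch=bi,
                    parent_cyl_of_attach=None,
                )
            )
    return plans


def _build_model(spec: SynthSpec, plans: list[_BranchPlan]) -> RootModel:
    cylinders: list[Cylinder] = []
    cyl_parent: list[int] = []
    branches: list[Branch] = []
    branch_cyl_ids: list[list[int]] = []

    for plan in plans:
        n_seg = max(1, int(np.ceil(plan.length / spec.segment_length)))
        seg_len = plan.length / n_seg
        ids = []
        for k in range(n_seg):
            s0, s1 = k * seg_len, (k + 1) * seg_len
            r = _taper_radius(plan.base_radius, 0.5 * (s0 + s1), spec.taper_rate)
            cyl = Cylinder(
                start=plan.base + s0 * plan.direction,
                end=plan.base + s1 * plan.direction,
                radius=r,
                rmse_fit=0.0,
            )
            idx = len(cylinders)
            cylinders.append(cyl)
            if k > 0:
                cyl_parent.append(ids[-1])
            elif plan.parent_branch is None:
                cyl_parent.append(-1)
            else:
                # attach to the parent cylinder whose span covers the base
                parent_ids = branch_cyl_ids[plan.parent_branch]
                pplan = plans[plan.parent_branch]
                s_attach = float((plan.base - pplan.base) @ pplan.direction)
                pseg = pplan.length / len(parent_ids)
                j = min(int(s_attach / pseg), len(parent_ids) - 1)
                cyl_parent.append(parent_ids[j])
            ids.append(idx)
        branch_cyl_ids.append(ids)
        branches.append(
            Branch(
                cylinders=[cylinders[i] for i in ids],
                order=plan.order,
                parent_branch=plan.parent_branch,
                attach_point=plan.base.copy(),
            )
        )
    topology: dict[int, list[int]] = {i: [] for i in range(len(branches))}
    for i, b in enumerate(branches):
        if b.parent_branch is not None:
            topology[b.parent_branch].append(i)
    return RootModel(
        cylinders=cylinders, cyl_parent=cyl_parent, branches=branches, topology=topology
    )


def _analytic_traits(spec: SynthSpec, model: RootModel) -> TraitTable:
    length = sum(c.length for c in model.cylinders)
    volume = sum(c.volume for c in model.cylinders)
    area = sum(c.lateral_area for c in model.cylinders)
    per_order: dict[int, int] = {}
    diams: dict[int, list[float]] = {}
    counted = []
    for b in model.branches:
        d_cm = 2.0 * b.basal_radius * 100.0
        if d_cm > 0.5:
            per_order[b.order] = per_order.get(b.order, 0) + 1
            diams.setdefault(b.order, []).append(d_cm)
            if b.order in (0, 1, 2):
                counted.append(d_cm)
    return TraitTable(
        tree_id=spec.name,
        n_roots=sum(per_order.get(o, 0) for o in (0, 1, 2)),
        mean_basal_diameter=float(np.mean(counted)) if counted else 0.0,
        root_volume=volume,
        root_surface_area=area,
        root_length=length,
        per_order_counts=per_order,
        basal_diameters_cm=diams,
    )


def _sample_surface(spec: SynthSpec, model: RootModel) -> np.ndarray:
    """Poisson surface sampling with per-cylinder seeded substreams."""
    points = []
    # map each cylinder to its branch for the per-branch occlusion sector
    cyl_branch = {}
    for bi, b in enumerate(model.branches):
        for c in b.cylinders:
            cyl_branch[id(c)] = bi
    sector_phase = {
        bi: float(np.random.default_rng([spec.seed, 1, bi]).uniform(0, 2 * np.pi))
        for bi in range(len(model.branches))
    }
    sector_width = 2 * np.pi * spec.occlusion_fraction

    for ci, cyl in enumerate(model.cylinders):
        rng = np.random.default_rng([spec.seed, 2, ci])
        lam = spec.point_density * cyl.lateral_area
        n = rng.poisson(lam)
        if n == 0:
            continue
        s = rng.uniform(0.0, cyl.length, size=n)
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        if spec.noise_sigma > 0:
            dr = np.clip(
                rng.normal(0.0, spec.noise_sigma, size=n),
                -6 * spec.noise_sigma,
                6 * spec.noise_sigma,
            )
        else:
            dr = np.zeros(n)
        d = cyl.axis
        probe = np.array([1.0, 0.0, 0.0])
        if abs(d @ probe) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        e1 = _unit(np.cross(d, probe))
        e2 = np.cross(d, e1)
        if sector_width > 0:
            phase = sector_phase[cyl_branch[id(cyl)]]
            ang = (theta - phase) % (2 * np.pi)
            keep = ang >= sector_width
            s, theta, dr = s[keep], theta[keep], dr[keep]
        radial = (cyl.radius + dr)[:, None] * (
            np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
        )
        points.append(cyl.start + s[:, None] * d + radial)
    if not points:
        raise ValueError("spec produced an empty cloud (density too low?)")
    return np.vstack(points)


def generate_root_system(spec: SynthSpec) -> tuple[PointCloud, GroundTruth]:
    """Deterministically generate (cloud, ground truth) for a spec.

    The same spec (including seed) always yields bit-identical output;
    per-branch and per-cylinder random substreams keep one branch's points
    independent of every other branch's parameters.
    """
    plans = _plan_branches(spec)
    model = _build_model(spec, plans)
    traits = _analytic_traits(spec, model)
    coords = _sample_surface(spec, model)
    pc = PointCloud(coords, crs_note=f"synthetic:{spec.name}:seed={spec.seed}")
    return pc, GroundTruth(model=model, traits=traits)


def vertical_and_horizontal_presets() -> list[SynthSpec]:
    """The two canonical root habits: deep taproot vs shallow spreading crown.

    "vertical" has a long taproot with steep laterals; "horizontal" a short
    taproot with wide shallow laterals, so the vertical preset's z-extent
    exceeds the horizontal one's.
    """
    vertical = SynthSpec(
        name="vertical",
        taproot_length=2.0,
        taproot_basal_radius=0.04,
        branch_angle_deg=35.0,
        n_first_order=5,
        n_second_order_per_first=2,
        seed=11,
    )
    horizontal = SynthSpec(
        name="horizontal",
        taproot_length=0.9,
        taproot_basal_radius=0.05,
        branch_angle_deg=72.0,
        n_first_order=6,
        n_second_order_per_first=2,
        lateral_length_factor=0.8,
        seed=23,
    )
    return [vertical, horizontal]


def preset(name: str, **overrides) -> SynthSpec:
    """Fetch a named preset, optionally overriding fields (e.g. seed, noise)."""
    for spec in vertical_and_horizontal_presets():
        if spec.name == name:
            return replace(spec, **overrides) if overrides else spec
    raise KeyError(f"unknown preset {name!r} (have: vertical, horizontal)")
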