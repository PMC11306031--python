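"""Structural phenotypes of a reconstructed root system.

From a cylinder model: total root length, volume, lateral surface area,
per-order branch counts under the coarse-root rule (basal diameter above
0.5 cm counts; thinner laterals are treated as fine roots and ignored), and
the mean basal diameter of counted roots.  Basal diameters can also be
measured directly from the point cloud by slicing the root base and fitting
least-squares circles, which is the more accurate of the two routes.

Diameters are reported in centimeters; lengths, areas and volumes stay in
meters, m^2 and m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pointcloud import PointCloud
from .preprocess import DownsampleParams, downsample_cp
from .qsm import Branch, RootModel

__all__ = [
    "TraitTable",
    "DiameterMeasurement",
    "MeasurementError",
    "fit_circle",
    "basal_diameter",
    "extract_traits",
    "cp_sweep",
    "COARSE_ROOT_MIN_DIAMETER_CM",
]

COARSE_ROOT_MIN_DIAMETER_CM = 0.5  # coarse-root field rule


class MeasurementError(ValueError):
    """Too few points (or degenerate geometry) for a diameter measurement."""


@dataclass
class DiameterMeasurement:
    RD: float                 # basal diameter, cm
    center: np.ndarray        # circle center in the slice plane
    fit_rms: float            # mean circle-fit residual, m
    n_slices_averaged: int


@dataclass
class TraitTable:
    tree_id: str
    n_roots: int                      # taproot + order-1 + order-2 passing the rule
    mean_basal_diameter: float        # cm, over counted roots
    root_volume: float                # m^3
    root_surface_area: float          # m^2 (lateral surface only)
    root_length: float                # m
    per_order_counts: dict[int, int] = field(default_factory=dict)
    basal_diameters_cm: dict[int, list[float]] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "tree_id": self.tree_id,
            "n_roots": self.n_roots,
            "mean_basal_diameter_cm": round(self.mean_basal_diameter, 2),
            "root_volume_m3": self.root_volume,
            "root_surface_area_m2": self.root_surface_area,
            "root_length_m": self.root_length,
        }
        for order in sorted(self.per_order_counts):
            row[f"count_order_{order}"] = self.per_order_counts[order]
        return row


# ---------------------------------------------------------------------------
# circle fitting


def fit_circle(points2d) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through planar points: (center, radius, rms).

    Algebraic (Kasa) solution of x^2 + y^2 + D x + E y + F = 0, refined by
    one Gauss-Newton pass on the geometric residuals d_i - r.  Exact on
    noiseless circular arcs regardless of arc coverage.
    """
    pts = np.asarray(points2d, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError(f"need >= 3 planar points, got shape {pts.shape}")
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-12):
        raise ValueError("degenerate circle fit: points are collinear")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("degenerate circle fit (collinear points?)")
    r = float(np.sqrt(r2))
    # one Gauss-Newton step on (cx, cy, r) against geometric residuals
    for _ in range(1):
        dx, dy = x - cx, y - cy
        d = np.hypot(dx, dy)
        if (d < 1e-15).any():
            break
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        res = d - r
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        cx, cy, r = cx + step[0], cy + step[1], r + step[2]
    d = np.hypot(x - cx, y - cy)
    rms = float(np.sqrt(np.mean((d - r) ** 2)))
    if r <= 0 or not np.isfinite(r):
        raise ValueError("degenerate circle fit")
    return np.array([cx, cy]), float(r), rms


def _robust_circle(pts: np.ndarray, max_iter: int = 3):
    """Circle fit with iterative residual trimming.

    Points grazing a neighboring surface sit far off the ring and would pull
    the algebraic fit; dropping large-residual points and refitting a few
    times converges to the dominant circle.
    """
    center, r, rms = fit_circle(pts)
    for _ in range(max_iter):
        d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        res = np.abs(d - r)
        mad = float(np.median(res))
        thr = max(4.0 * 1.4826 * mad, 0.05 * r)
        keep = res <= thr
        if keep.all() or keep.sum() < 3:
            break
        pts = pts[keep]
        center, r, rms = fit_circle(pts)
    return center, r, rms


def _rotation_to_vertical(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` to +z (Rodrigues)."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(a @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def basal_diameter(
    pc: PointCloud,
    branch: Branch,
    n_slabs: int = 3,
    slab_thickness: float = 0.01,
    slab_offset: float = 0.01,
    min_points: int = 30,
) -> DiameterMeasurement:
    """Basal diameter (RD, cm) of a branch measured from the point cloud.

    The cloud local to the branch base is rotated so the first cylinder's
    axis is vertical; ``n_slabs`` slabs of ``slab_thickness`` m starting
    ``slab_offset`` m above the attachment are projected onto the plane and
    a least-squares circle is fitted to each; RD is the mean of the slab
    diameters.
    """
    if not branch.cylinders:
        raise MeasurementError("branch has no cylinders")
    base = branch.cylinders[0].start
    # the first cylinder spans the junction and its direction is the least
    # reliable; orient the slice stack along the second cylinder when present
    axis = branch.cylinders[min(1, len(branch.cylinders) - 1)].axis
    radius_hint = max(branch.basal_radius, 1e-3)

    rot = _rotation_to_vertical(axis)
    local = (pc.coords - base) @ rot.T  # base at origin, axis now +z
    span = slab_offset + n_slabs * slab_thickness
    lateral = np.hypot(local[:, 0], local[:, 1])
    nearby = (
        (local[:, 2] >= 0)
        & (local[:, 2] <= span)
        & (lateral <= 3.0 * radius_hint)
    )
    if nearby.sum() < min_points:
        raise MeasurementError(
            f"only {int(nearby.sum())} points near the base of branch at "
            f"{np.round(base, 3).tolist()} (need {min_points})"
        )
    local = local[nearby]

    diameters, centers, rmss, used = [], [], [], 0
    for s in range(n_slabs):
        z_lo = slab_offset + s * slab_thickness
        sel = (local[:, 2] >= z_lo) & (local[:, 2] < z_lo + slab_thickness)
        if sel.sum() < 3:
            continue
        slab_pts = local[sel, :2]
        # trim points whose radial distance is far from the slab median:
        # they belong to a grazing neighbor surface, not this root's ring
        rad = np.hypot(slab_pts[:, 0], slab_pts[:, 1])
        med = float(np.median(rad))
        trim = (rad >= 0.4 * med) & (rad <= 1.6 * med)
        if trim.sum() >= 3:
            slab_pts = slab_pts[trim]
        try:
            center, r, rms = _robust_circle(slab_pts)
        except ValueError:
            continue
        diameters.append(2.0 * r)
        centers.append(center)
        rmss.append(rms)
        used += 1
    if used == 0:
        raise MeasurementError(
            f"no slab near branch base at {np.round(base, 3).tolist()} had "
            "enough points for a circle fit"
        )
    if used >= 2:
        # a slab whose circle latched onto a neighboring surface deviates
        # grossly from its siblings; drop slabs > 30% off the median
        med = float(np.median(diameters))
        ok = [i for i, d in enumerate(diameters) if abs(d - med) <= 0.3 * med]
        diameters = [diameters[i] for i in ok]
        centers = [centers[i] for i in ok]
        rmss = [rmss[i] for i in ok]
        used = len(ok)
    return DiameterMeasurement(
        RD=float(np.mean(diameters) * 100.0),
        center=np.mean(centers, axis=0),
        fit_rms=float(np.mean(rmss)),
        n_slices_averaged=used,
    )


# ---------------------------------------------------------------------------
# trait extraction


def _parent_clearance(
    branch: Branch, model: RootModel, margin: float = 1.3, pad: float = 0.004,
    slack: float = 0.006,
) -> float:
    """Offset that clears the parent root's surface at the attachment.

    A lateral's first cylinder starts on the parent's axis, so measurement
    slabs must begin past the parent's radius or they sample the parent's
    surface instead of the lateral's.  The offset tracks the exclusion zone
    of :func:`_without_parent_surface` (``margin * r + pad``) plus a little
    slack so the first slab is never empty by construction.
    """
    if branch.parent_branch is None:
        return 0.01
    parent = model.branches[branch.parent_branch]
    attach = branch.attach_point
    near = min(
        parent.cylinders,
        key=lambda c: np.linalg.norm(0.5 * (c.start + c.end) - attach),
    )
    return margin * near.radius + pad + slack


def _without_parent_surface(
    pc: PointCloud, branch: Branch, model: RootModel, margin: float = 1.3,
    pad: float = 0.004, reach: float = 0.3,
) -> PointCloud:
    """Drop points lying on the parent branch's surface near the attachment.

    For steep laterals the measurement slabs overlap the parent's ring, whose
    larger and denser circle would dominate the fit; points within
    ``margin`` x radius of a nearby parent cylinder axis are removed.
    """
    if branch.parent_branch is None:
        return pc
    attach = branch.attach_point
    keep = np.ones(len(pc), dtype=bool)
    for cyl in model.branches[branch.parent_branch].cylinders:
        mid = 0.5 * (cyl.start + cyl.end)
        if np.linalg.norm(mid - attach) > reach:
            continue
        d = cyl.axis
        rel = pc.coords - cyl.start
        t = np.clip(rel @ d, 0.0, cyl.length)
        radial = np.linalg.norm(rel - t[:, None] * d, axis=1)
        keep &= radial > margin * cyl.radius + pad
    if not keep.any():
        return pc
    return pc.select(np.flatnonzero(keep))


def _branch_basal_diameter_cm(
    branch: Branch, pc: PointCloud | None, model: RootModel
) -> float:
    """Point-cloud slab measurement when possible, else 2 x fitted radius."""
    if pc is not None:
        try:
            local = _without_parent_surface(pc, branch, model)
            return basal_diameter(
                local, branch, slab_offset=_parent_clearance(branch, model)
            ).RD
        except MeasurementError:
            pass
    return 2.0 * branch.basal_radius * 100.0


def extract_traits(
    model: RootModel,
    pc: PointCloud | None = None,
    min_basal_diameter_cm: float = COARSE_ROOT_MIN_DIAMETER_CM,
    tree_id: str = "root",
    counted_orders: tuple[int, ...] = (0, 1, 2),
) -> TraitTable:
    """Phenotype table of a reconstructed root system.

    Length/volume/surface totals run over *all* cylinders; the per-order
    counts apply the coarse-root rule to each branch's measured basal
    diameter, and ``n_roots`` follows the field convention of counting only
    the taproot and the first- and second-order laterals.
    """
    if not model.branches:
        raise ValueError("model has no branches; run order assignment first")
    length = sum(c.length for c in model.cylinders)
    volume = sum(c.volume for c in model.cylinders)
    area = sum(c.lateral_area for c in model.cylinders)

    per_order: dict[int, int] = {}
    diam_by_order: dict[int, list[float]] = {}
    counted_diams: list[float] = []
    for branch in model.branches:
        d_cm = _branch_basal_diameter_cm(branch, pc, model)
        if d_cm > min_basal_diameter_cm:
            per_order[branch.order] = per_order.get(branch.order, 0) + 1
            diam_by_order.setdefault(branch.order, []).append(d_cm)
            if branch.order in counted_orders:
                counted_diams.append(d_cm)
    n_roots = sum(per_order.get(o, 0) for o in counted_orders)
    return TraitTable(
        tree_id=tree_id,
        n_roots=n_roots,
        mean_basal_diameter=float(np.mean(counted_diams)) if counted_diams else 0.0,
        root_volume=volume,
        root_surface_area=area,
        root_length=length,
        per_order_counts=per_order,
        basal_diameters_cm=diam_by_order,
    )


def cp_sweep(
    pc: PointCloud,
    cps,
    pipeline_config: dict | None = None,
    tree_id: str = "root",
) -> pd.DataFrame:
    """Run the full pipeline once per CP value and tabulate the traits.

    Each row carries the CP, the post-thinning point count, the extracted
    traits, and an ``error`` column naming the failed stage when a CP run
    aborts (the sweep itself never does).
    """
    from .pipeline import reconstruct_cloud  # deferred: pipeline imports traits

    cps = list(cps)
    if not cps:
        raise ValueError("cps must be non-empty")
    if any(cp < 0 for cp in cps):
        raise ValueError("cp values must be >= 0")
    config = dict(pipeline_config or {})
    rows = []
    for cp in cps:
        row: dict = {"tree_id": tree_id, "cp": cp}
        try:
            thinned = downsample_cp(pc, DownsampleParams(cp=cp))
            row["n_points"] = len(thinned)
            model, _ = reconstruct_cloud(thinned, **config)
            traits = extract_traits(model, thinned, tree_id=tree_id)
            row.update(traits.as_row())
            row["error"] = ""
        except Exception as exc:  # record, keep sweeping
            row.setdefault("n_points", len(pc))
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
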