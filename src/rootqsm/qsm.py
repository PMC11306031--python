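"""Cylinder-based quantitative structure model (QSM) of a root system.

Each skeleton edge receives a cylinder fitted to the member points of its two
endpoint nodes by nonlinear least squares; cylinders are chained into
branches, and branching orders are graded bottom-up from the collar: the
taproot is order 0, roots branching off it are order 1, and so on.  At each
bifurcation the child whose first cylinder is thickest continues the parent
branch (the alternative longest-path rule is available via
``continuation="length"``).

Also provides the triangle normal/centroid primitives used by TIN-style
surface representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .pointcloud import PointCloud
from .skeleton import Skeleton

__all__ = [
    "Cylinder",
    "Branch",
    "RootModel",
    "CylinderFitError",
    "fit_cylinder",
    "model_from_skeleton",
    "assign_orders",
    "triangle_normal",
    "triangle_centroid",
]

MAX_CHILD_RADIUS_RATIO = 1.2  # tapering prior: child radius <= 1.2 x parent


class CylinderFitError(ValueError):
    """Degenerate input or non-convergent cylinder fit."""


@dataclass
class Cylinder:
    start: np.ndarray
    end: np.ndarray
    radius: float
    rmse_fit: float = 0.0
    fitted: bool = True    # False -> radius interpolated from neighbors
    clamped: bool = False  # True -> radius reduced by the tapering prior

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.float64)
        self.end = np.asarray(self.end, dtype=np.float64)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def axis(self) -> np.ndarray:
        v = self.end - self.start
        return v / np.linalg.norm(v)

    @property
    def volume(self) -> float:
        return float(np.pi * self.radius**2 * self.length)

    @property
    def lateral_area(self) -> float:
        return float(2.0 * np.pi * self.radius * self.length)


@dataclass
class Branch:
    """Ordered chain of cylinders; consecutive cylinders share endpoints."""

    cylinders: list[Cylinder]
    order: int = 0
    parent_branch: int | None = None
    attach_point: np.ndarray | None = None

    @property
    def length(self) -> float:
        return sum(c.length for c in self.cylinders)

    @property
    def basal_radius(self) -> float:
        return self.cylinders[0].radius

    @property
    def base_position(self) -> np.ndarray:
        return self.cylinders[0].start


@dataclass
class RootModel:
    """Branch hierarchy plus the underlying cylinder tree.

    ``cyl_parent[i]`` is the index of the cylinder whose end meets cylinder
    i's start (-1 at the collar); branches are a view derived from it.
    """

    cylinders: list[Cylinder]
    cyl_parent: list[int]
    branches: list[Branch] = field(default_factory=list)
    topology: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_cylinders(self) -> int:
        return len(self.cylinders)

    def branches_of_order(self, order: int) -> list[Branch]:
        return [b for b in self.branches if b.order == order]

    @property
    def max_order(self) -> int:
        return max(b.order for b in self.branches)


# ---------------------------------------------------------------------------
# cylinder fitting


def _orthobasis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to d."""
    probe = np.array([1.0, 0.0, 0.0])
    if abs(d @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, probe)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def fit_cylinder(points, init_axis) -> Cylinder:
    """Nonlinear least-squares cylinder: minimize sum (d_i - r)^2.

    ``d_i`` is the distance of point i to the axis; free parameters are the
    axis point (2 dof, in the plane orthogonal to the initial direction), the
    axis direction (2 dof, as in-plane perturbations of the initial
    direction), and the radius.  The axis is seeded from ``init_axis``,
    normally a skeleton edge.  Endpoints of the returned cylinder are the
    extreme projections of the points onto the fitted axis.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 7:
        raise CylinderFitError(f"need >= 7 points in 3D, got shape {pts.shape}")
    p0 = np.asarray(init_axis[0], dtype=np.float64)
    d0 = np.asarray(init_axis[1], dtype=np.float64)
    nd0 = np.linalg.norm(d0)
    if nd0 == 0:
        raise CylinderFitError("zero-length initial axis direction")
    d0 = d0 / nd0
    # collinearity check: centered points must span >= 2 dimensions
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1.0):
        raise CylinderFitError("points are collinear; no cylinder is defined")

    e1, e2 = _orthobasis(d0)

    def unpack(x):
        u, v, a, b, r = x
        p = p0 + u * e1 + v * e2
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        return p, d, r

    def residuals(x):
        p, d, r = unpack(x)
        rel = pts - p
        radial = rel - np.outer(rel @ d, d)
        return np.linalg.norm(radial, axis=1) - r

    rel0 = pts - p0
    radial0 = np.linalg.norm(rel0 - np.outer(rel0 @ d0, d0), axis=1)
    x0 = np.array([0.0, 0.0, 0.0, 0.0, max(radial0.mean(), 1e-6)])
    sol = least_squares(
        residuals, x0, method="lm", xtol=1e-8, ftol=1e-8, max_nfev=200 * 5
    )
    if not sol.success:
        raise CylinderFitError(
            f"cylinder fit did not converge (final cost {sol.cost:.3e})"
        )
    p, d, r = unpack(sol.x)
    r = abs(float(r))
    if r <= 0 or not np.isfinite(r):
        raise CylinderFitError(f"degenerate fitted radius {r}")
    t = (pts - p) @ d
    start = p + t.min() * d
    end = p + t.max() * d
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return Cylinder(start=start, end=end, radius=r, rmse_fit=rmse)


# ---------------------------------------------------------------------------
# skeleton -> model


def model_from_skeleton(
    pc: PointCloud,
    skel: Skeleton,
    continuation: str = "radius",
    min_fit_points: int = 7,
    min_branch_length: float = 0.0,
) -> RootModel:
    """Fit one cylinder per skeleton edge and assemble the branch hierarchy.

    Cylinder endpoints are the skeleton node positions, which makes every
    branch an exactly contiguous chain; the nonlinear fit supplies radius and
    fit RMSE.  Edges whose fit fails (too few points, degeneracy,
    non-convergence) get a radius interpolated from tree-adjacent successful
    fits and are flagged ``fitted=False``.
    """
    edges = skel.edges
    if not edges:
        raise ValueError("skeleton has a single node; nothing to fit")

    node_of_edge = {}
    cylinders: list[Cylinder] = []
    cyl_parent: list[int] = []
    # edges arrive in node-id order; parents always precede children
    for parent_node, child_node in edges:
        pn, cn = skel.nodes[parent_node], skel.nodes[child_node]
        # at a bifurcation the parent node's members mix several roots, which
        # badly biases the fit; use the child's own points when they suffice
        if len(pn.children) > 1 and len(cn.member_points) >= 2 * min_fit_points:
            member = cn.member_points
        else:
            member = np.concatenate([pn.member_points, cn.member_points])
        direction = cn.position - pn.position
        radius, rmse, ok = np.nan, np.nan, False
        if len(member) >= min_fit_points and np.linalg.norm(direction) > 0:
            try:
                fit = fit_cylinder(pc.coords[member], (pn.position, direction))
                radius, rmse, ok = fit.radius, fit.rmse_fit, True
            except CylinderFitError:
                pass
        cyl = Cylinder(
            start=pn.position, end=cn.position, radius=radius,
            rmse_fit=rmse if ok else np.nan, fitted=ok,
        )
        idx = len(cylinders)
        cylinders.append(cyl)
        cyl_parent.append(node_of_edge.get(parent_node, -1))
        node_of_edge[child_node] = idx

    _extend_terminals(pc, skel, cylinders, node_of_edge)
    _fill_missing_radii(cylinders, cyl_parent)
    model = RootModel(cylinders=cylinders, cyl_parent=cyl_parent)
    model = assign_orders(model, continuation=continuation)
    if min_branch_length > 0:
        model = prune_short_branches(model, min_branch_length, continuation)
    _extend_branch_bases(model)
    _clamp_radii(model)
    return model


def _extend_branch_bases(model: RootModel, max_extension: float = 0.15) -> None:
    """Stretch each side branch's first cylinder back to the parent's axis.

    A lateral's true base sits on the parent root's central axis, but the
    skeleton places the branch start at a junction-node centroid offset from
    it, systematically shortening every lateral by roughly the parent
    radius; moving the start to the closest point (on the branch axis) to
    the parent's axis removes that bias.
    """
    for branch in model.branches:
        if branch.parent_branch is None or not branch.cylinders:
            continue
        first = branch.cylinders[0]
        parent = model.branches[branch.parent_branch]
        # the junction node itself is displaced toward the lateral, so the
        # parent axis must be estimated from segments not touching it
        clean = [
            c
            for c in parent.cylinders
            if np.linalg.norm(c.start - first.start) > 1e-9
            and np.linalg.norm(c.end - first.start) > 1e-9
        ] or parent.cylinders
        near = min(
            clean,
            key=lambda c: np.linalg.norm(0.5 * (c.start + c.end) - first.start),
        )
        # the branch's own centerline is best estimated from its second
        # cylinder (the first is a junction connector that cuts the corner)
        guide = branch.cylinders[min(1, len(branch.cylinders) - 1)]
        d1, d2 = guide.axis, near.axis
        cross = float(d1 @ d2)
        denom = 1.0 - cross**2
        if denom < 1e-6:  # near-parallel axes: no well-defined base
            continue
        w = guide.start - near.start
        t1 = (cross * (w @ d2) - (w @ d1)) / denom  # closest-approach param
        # guide.start coincides with first.end for multi-cylinder branches
        # (chain contiguity), so the rebuilt first cylinder is the straight
        # buried run from the parent axis to the first clean node
        anchor = guide.start
        if -max_extension < t1 < 0:
            new_start = anchor + t1 * d1
            branch.attach_point = new_start.copy()
            first.start = new_start


def prune_short_branches(
    model: RootModel, min_length: float, continuation: str = "radius"
) -> RootModel:
    """Remove leaf branches shorter than ``min_length`` meters.

    Such stubs are skeletonization artifacts at junctions (a real lateral
    spans many skeleton bins); their removal repeats until stable, and
    orders are re-assigned on the cleaned cylinder tree.
    """
    while True:
        doomed: set[int] = set()
        for bid, branch in enumerate(model.branches):
            if (
                branch.parent_branch is not None
                and not model.topology.get(bid, [])
                and branch.length < min_length
            ):
                doomed.update(id(c) for c in branch.cylinders)
        if not doomed:
            return model
        keep = [i for i, c in enumerate(model.cylinders) if id(c) not in doomed]
        remap = {old: new for new, old in enumerate(keep)}
        cylinders = [model.cylinders[i] for i in keep]
        cyl_parent = [
            remap[model.cyl_parent[i]] if model.cyl_parent[i] >= 0 else -1
            for i in keep
        ]
        model = assign_orders(
            RootModel(cylinders=cylinders, cyl_parent=cyl_parent),
            continuation=continuation,
        )


def _extend_terminals(pc, skel, cylinders, node_of_edge) -> None:
    """Stretch tip and collar cylinders to cover their nodes' extreme points.

    Skeleton chains end at bin centroids, which truncates every root tip by
    about half a bin and the collar by the same; extending the terminal
    cylinders to the extreme member-point projections removes that
    systematic length underestimate.
    """
    for node_id, node in enumerate(skel.nodes):
        if node_id == skel.root_node or node.children:
            if node_id != skel.root_node:
                continue
            # collar: stretch the first cylinder(s) down to the lowest member
            for child in node.children:
                cyl = cylinders[node_of_edge[child]]
                d = cyl.axis
                t = (pc.coords[node.member_points] - cyl.start) @ d
                t_min = float(t.min())
                if t_min < 0:
                    cyl.start = cyl.start + t_min * d
            continue
        cyl = cylinders[node_of_edge[node_id]]
        d = cyl.axis
        t = (pc.coords[node.member_points] - cyl.start) @ d
        t_max = float(t.max())
        if t_max > cyl.length:
            cyl.end = cyl.start + t_max * d


def _fill_missing_radii(cylinders, cyl_parent) -> None:
    """Diffuse radii from fitted neighbors onto failed fits along the tree."""
    children: dict[int, list[int]] = {}
    for i, p in enumerate(cyl_parent):
        children.setdefault(p, []).append(i)
    missing = [i for i, c in enumerate(cylinders) if not np.isfinite(c.radius)]
    guard = 0
    while missing and guard < len(cylinders) + 1:
        guard += 1
        still = []
        for i in missing:
            nb = []
            p = cyl_parent[i]
            if p >= 0 and np.isfinite(cylinders[p].radius):
                nb.append(cylinders[p].radius)
            nb += [
                cylinders[c].radius
                for c in children.get(i, [])
                if np.isfinite(cylinders[c].radius)
            ]
            if nb:
                cylinders[i].radius = float(np.mean(nb))
            else:
                still.append(i)
        missing = still
    if missing:  # no successful fit anywhere: last-resort nominal radius
        for i in missing:
            cylinders[i].radius = 0.01


def _clamp_radii(model: RootModel) -> None:
    children: dict[int, list[int]] = {}
    for i, p in enumerate(model.cyl_parent):
        children.setdefault(p, []).append(i)
    stack = list(children.get(-1, []))
    while stack:
        i = stack.pop()
        p = model.cyl_parent[i]
        if p >= 0:
            cap = MAX_CHILD_RADIUS_RATIO * model.cylinders[p].radius
            if model.cylinders[i].radius > cap:
                model.cylinders[i].radius = cap
                model.cylinders[i].clamped = True
        stack.extend(children.get(i, []))


def assign_orders(model: RootModel, continuation: str = "radius") -> RootModel:
    """Rebuild branches from the cylinder tree and grade orders bottom-up.

    Starting at the collar, each branch follows the continuation rule at
    bifurcations: ``"radius"`` continues through the child with the largest
    first-cylinder radius (ties to the smaller direction change),
    ``"length"`` through the child with the longest downstream path.  Side
    children get the parent's order + 1.
    """
    if continuation not in ("radius", "length"):
        raise ValueError(f"unknown continuation rule {continuation!r}")
    children: dict[int, list[int]] = {}
    for i, p in enumerate(model.cyl_parent):
        children.setdefault(p, []).append(i)
    roots = children.get(-1, [])
    if len(roots) != 1:
        raise ValueError(f"cylinder tree must have exactly 1 root, got {len(roots)}")
    _check_acyclic(model.cyl_parent)

    subtree_len = _longest_downstream(model, children)

    branches: list[Branch] = []
    topology: dict[int, list[int]] = {}
    # stack of (first cylinder of branch, order, parent branch id)
    stack = [(roots[0], 0, None)]
    while stack:
        cyl_id, order, parent_branch = stack.pop()
        chain = []
        cur = cyl_id
        while True:
            chain.append(cur)
            kids = children.get(cur, [])
            if not kids:
                break
            cont = _pick_continuation(model, children, cur, kids, continuation, subtree_len)
            this_branch = len(branches)
            for k in kids:
                if k != cont:
                    stack.append((k, order + 1, this_branch))
            cur = cont
        branches.append(
            Branch(
                cylinders=[model.cylinders[i] for i in chain],
                order=order,
                parent_branch=parent_branch,
                attach_point=model.cylinders[chain[0]].start.copy(),
            )
        )
    topology = {i: [] for i in range(len(branches))}
    for i, b in enumerate(branches):
        if b.parent_branch is not None:
            topology[b.parent_branch].append(i)
    return RootModel(
        cylinders=model.cylinders,
        cyl_parent=model.cyl_parent,
        branches=branches,
        topology=topology,
    )


def _check_acyclic(cyl_parent) -> None:
    for start in range(len(cyl_parent)):
        seen = set()
        cur = start
        while cur != -1:
            if cur in seen:
                raise ValueError("cylinder topology contains a cycle")
            seen.add(cur)
            cur = cyl_parent[cur]


def _chain_radius(model, children, k, depth: int = 3) -> float:
    """Median radius over the first cylinders of a child's unbranched chain.

    Looking a few cylinders past the junction makes the continuation choice
    robust to a single biased fit right at the bifurcation.
    """
    radii = []
    cur = k
    while len(radii) < depth:
        radii.append(model.cylinders[cur].radius)
        nxt = children.get(cur, [])
        if len(nxt) != 1:
            break
        cur = nxt[0]
    return float(np.median(radii))


def _pick_continuation(model, children, cur, kids, rule, subtree_len):
    if len(kids) == 1:
        return kids[0]
    if rule == "length":
        return max(kids, key=lambda k: subtree_len[k])
    # a root does not end at a bifurcation: avoid continuing into a child
    # that dies within ~2 skeleton bins (junction artifacts with unreliable,
    # often inflated, radii) when a sibling carries real downstream length
    typical = float(np.median([c.length for c in model.cylinders]))
    eligible = [k for k in kids if subtree_len[k] >= 2.5 * typical]
    if not eligible:
        eligible = list(kids)
    radii = np.array([_chain_radius(model, children, k) for k in eligible])
    best = np.flatnonzero(radii == radii.max())
    if len(best) == 1:
        return eligible[int(best[0])]
    # tie: smallest direction change relative to the current cylinder
    axis = model.cylinders[cur].axis
    angles = [
        np.arccos(np.clip(model.cylinders[eligible[b]].axis @ axis, -1.0, 1.0))
        for b in best
    ]
    return eligible[int(best[int(np.argmin(angles))])]


def _longest_downstream(model, children):
    """Longest root-ward-to-tip path length through each cylinder."""
    out: dict[int, float] = {}

    def rec(i):
        kids = children.get(i, [])
        best = max((rec(k) for k in kids), default=0.0)
        out[i] = model.cylinders[i].length + best
        return out[i]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(model.cylinders) + 100))
    try:
        for r in children.get(-1, []):
            rec(r)
    finally:
        sys.setrecursionlimit(old)
    return out


# ---------------------------------------------------------------------------
# TIN triangle geometry


def triangle_normal(g1, g2, g3) -> np.ndarray:
    """Normal N = (A, B, C) of the triangle (G1, G2, G3).

    A = (Y2-Y1)(Z3-Z1) - (Z2-Z1)(Y3-Y1), and cyclically for B and C — the
    cross product of the edge vectors G1G2 and G1G3 (not normalized).
    """
    g1, g2, g3 = (np.asarray(g, dtype=np.float64) for g in (g1, g2, g3))
    e12 = g2 - g1
    e13 = g3 - g1
    n = np.array(
        [
            e12[1] * e13[2] - e12[2] * e13[1],
            e12[2] * e13[0] - e12[0] * e13[2],
            e12[0] * e13[1] - e12[1] * e13[0],
        ]
    )
    if np.linalg.norm(n) == 0:
        raise ValueError("degenerate triangle: vertices are collinear")
    return n


def triangle_centroid(g1, g2, g3) -> np.ndarray:
    """Center of mass C_k: the componentwise mean of the three vertices."""
    g1, g2, g3 = (np.asarray(g, dtype=np.float64) for g in (g1, g2, g3))
    return (g1 + g2 + g3) / 3.0
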