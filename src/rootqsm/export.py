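"""Tabular and mesh exports of skeletons and cylinder models."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qsm import RootModel
from .skeleton import Skeleton

__all__ = ["skeleton_to_csv", "model_to_csv", "model_to_obj", "ORDER_COLORS"]

# branching-order display colors: taproot brown, then green, cyan, red, blue
ORDER_COLORS = {
    0: (0.55, 0.27, 0.07),
    1: (0.00, 0.60, 0.00),
    2: (0.00, 0.75, 0.75),
    3: (0.85, 0.10, 0.10),
    4: (0.10, 0.10, 0.85),
}


def skeleton_to_csv(skel: Skeleton, path) -> Path:
    rows = [
        {
            "id": i,
            "x": n.position[0],
            "y": n.position[1],
            "z": n.position[2],
            "bin": n.bin_index,
            "parent_id": -1 if n.parent is None else n.parent,
            "n_member_points": len(n.member_points),
        }
        for i, n in enumerate(skel.nodes)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def model_to_csv(model: RootModel, path) -> Path:
    rows = []
    for bid, branch in enumerate(model.branches):
        for cyl in branch.cylinders:
            rows.append(
                {
                    "branch_id": bid,
                    "order": branch.order,
                    "parent_branch": -1 if branch.parent_branch is None else branch.parent_branch,
                    "start_x": cyl.start[0],
                    "start_y": cyl.start[1],
                    "start_z": cyl.start[2],
                    "end_x": cyl.end[0],
                    "end_y": cyl.end[1],
                    "end_z": cyl.end[2],
                    "radius_m": cyl.radius,
                    "rmse_fit": cyl.rmse_fit,
                    "fitted": cyl.fitted,
                    "clamped": cyl.clamped,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def model_to_obj(model: RootModel, path, sections: int = 12) -> Path:
    """Capped-cylinder mesh, one material per branching order.

    Writes ``path`` plus a sibling ``.mtl`` holding the order colors
    (taproot brown, then green/cyan/red/blue for orders 1-4 and beyond).
    """
    path = Path(path)
    mtl_path = path.with_suffix(".mtl")
    with open(mtl_path, "w") as fh:
        for order in sorted({b.order for b in model.branches}):
            r, g, b = ORDER_COLORS.get(min(order, 4), (0.5, 0.5, 0.5))
            fh.write(f"newmtl order{order}\nKd {r:.3f} {g:.3f} {b:.3f}\n")
    with open(path, "w") as fh:
        fh.write(f"mtllib {mtl_path.name}\n")
        v_offset = 1  # OBJ is 1-indexed
        for branch in model.branches:
            fh.write(f"usemtl order{branch.order}\n")
            for cyl in branch.cylinders:
                v_offset += _write_capped_cylinder(fh, cyl, sections, v_offset)
    return path


def _write_capped_cylinder(fh, cyl, sections, v0) -> int:
    d = cyl.axis
    probe = np.array([1.0, 0.0, 0.0])
    if abs(d @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, probe)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    ring = cyl.radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    verts = np.vstack(
        [cyl.start + ring, cyl.end + ring, cyl.start[None, :], cyl.end[None, :]]
    )
    for v in verts:
        fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
    bot, top = v0 + 2 * sections, v0 + 2 * sections + 1
    for i in range(sections):
        j = (i + 1) % sections
        a, b = v0 + i, v0 + j
        c, e = v0 + sections + i, v0 + sections + j
        fh.write(f"f {a} {b} {e} {c}\n")       # side quad
        fh.write(f"f {b} {a} {bot}\n")          # bottom cap
        fh.write(f"f {c} {e} {top}\n")          # top cap
    return 2 * sections + 2
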