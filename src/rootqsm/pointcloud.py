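"""Point-cloud container, standard-format I/O, and coordinate conventions.

The pipeline works on a single merged scan of one excavated root system,
coordinates in meters, right-handed, Z-up.  Because excavated root systems
are scanned collar-up but modeled collar-down (reconstruction proceeds
bottom-up from the root collar, exactly like stem-up tree QSMs), clouds are
inverted along z before skeletonization.

Supported formats: ASCII / binary-little-endian PLY, whitespace-delimited
XYZ text, and LAS 1.2 point format 0.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "PointCloud",
    "RigidTransform",
    "EmptyCloudError",
    "PointCloudFormatError",
    "read_point_cloud",
    "write_point_cloud",
    "invert_axis",
    "crop_box",
]


class EmptyCloudError(ValueError):
    """Raised when an operation would produce or consume a cloud with no points."""


class PointCloudFormatError(ValueError):
    """Raised when a file does not parse under the named standard."""


@dataclass
class PointCloud:
    """N x 3 coordinates in meters plus optional per-point attribute channels."""

    coords: np.ndarray
    attrs: dict[str, np.ndarray] = field(default_factory=dict)
    crs_note: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain NaN/Inf")
        for name, ch in self.attrs.items():
            ch = np.asarray(ch)
            if ch.shape[0] != len(self.coords):
                raise ValueError(
                    f"attribute {name!r} has {ch.shape[0]} values for "
                    f"{len(self.coords)} points"
                )
            self.attrs[name] = ch

    def __len__(self) -> int:
        return len(self.coords)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset/reorder by point index, carrying attributes along."""
        return PointCloud(
            self.coords[index],
            {k: v[index] for k, v in self.attrs.items()},
            self.crs_note,
        )


@dataclass
class RigidTransform:
    """Rotation + translation (+ optional z mirror applied first)."""

    rotation: np.ndarray
    translation: np.ndarray
    flip_z: bool = False

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal to 1e-9")
        if self.translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.float64)
        if self.flip_z:
            coords = coords * np.array([1.0, 1.0, -1.0])
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        if self.flip_z:
            # (R M x + t)^-1 = M R^T (y - t), with M = diag(1,1,-1);
            # fold M into the rotation so the inverse is again flip-free.
            rot = np.diag([1.0, 1.0, -1.0]) @ self.rotation.T
            return RigidTransform(rot, -rot @ self.translation, flip_z=False)
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# readers / writers


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise PointCloudFormatError(
                    f"{path}: line {lineno}: expected at least 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise PointCloudFormatError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise EmptyCloudError(f"{path}: no points")
    return PointCloud(np.array(rows), crs_note=f"xyz:{path.name}")


def _write_xyz(pc: PointCloud, path: Path) -> None:
    np.savetxt(path, pc.coords, fmt="%.9f")


def _read_ply(path: Path) -> PointCloud:
    try:
        mesh = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises assorted types on truncation
        raise PointCloudFormatError(f"{path}: unreadable PLY: {exc}") from exc
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    if verts.size == 0:
        raise EmptyCloudError(f"{path}: PLY contains no vertices")
    attrs: dict[str, np.ndarray] = {}
    colors = getattr(mesh, "colors", None)
    if colors is not None and len(colors) == len(verts):
        colors = np.asarray(colors)
        for i, name in enumerate(("red", "green", "blue")):
            attrs[name] = colors[:, i].copy()
    return PointCloud(verts, attrs, crs_note=f"ply:{path.name}")


def _write_ply(pc: PointCloud, path: Path) -> None:
    # ASCII with double-precision vertex properties: diffable fixtures and a
    # round-trip tight to 1e-6 m even at multi-meter coordinates.
    has_rgb = all(c in pc.attrs for c in ("red", "green", "blue"))
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pc)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if has_rgb:
            fh.write(
                "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            )
        fh.write("end_header\n")
        if has_rgb:
            rgb = np.stack(
                [np.asarray(pc.attrs[c], dtype=np.uint8) for c in ("red", "green", "blue")],
                axis=1,
            )
            for (x, y, z), (r, g, b) in zip(pc.coords, rgb):
                fh.write(f"{x:.9f} {y:.9f} {z:.9f} {r} {g} {b}\n")
        else:
            for x, y, z in pc.coords:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")


LAS_SCALE = 1e-4  # 0.1 mm grid: preserves mm-scale scanner noise structure

_LAS_HEADER_SIZE = 227  # LAS 1.2 public header block


def _read_las(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if len(raw) < _LAS_HEADER_SIZE or raw[:4] != b"LASF":
        raise PointCloudFormatError(f"{path}: not a LAS file (bad magic/short header)")
    ver_major, ver_minor = raw[24], raw[25]
    if (ver_major, ver_minor) != (1, 2):
        raise PointCloudFormatError(
            f"{path}: unsupported LAS version {ver_major}.{ver_minor}"
        )
    offset_to_points, = struct.unpack_from("<I", raw, 96)
    point_format = raw[104]
    record_len, = struct.unpack_from("<H", raw, 105)
    n_points, = struct.unpack_from("<I", raw, 107)
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", raw, 131)
    if point_format != 0:
        raise PointCloudFormatError(
            f"{path}: unsupported point format {point_format} (need 0)"
        )
    if n_points == 0:
        raise EmptyCloudError(f"{path}: LAS contains zero points")
    need = offset_to_points + n_points * record_len
    if len(raw) < need:
        raise PointCloudFormatError(
            f"{path}: truncated at byte {len(raw)} (need {need})"
        )
    body = np.frombuffer(
        raw, dtype=np.dtype("<i4"), count=3 * n_points, offset=offset_to_points
    ) if record_len == 12 else None
    if body is not None:
        xyz_int = body.reshape(n_points, 3)
    else:
        rec = np.frombuffer(
            raw,
            dtype=np.dtype([("xyz", "<i4", (3,)), ("rest", f"V{record_len - 12}")]),
            count=n_points,
            offset=offset_to_points,
        )
        xyz_int = rec["xyz"]
    coords = xyz_int.astype(np.float64) * np.array([sx, sy, sz]) + np.array(
        [ox, oy, oz]
    )
    return PointCloud(coords, crs_note=f"las:{path.name}")


def _write_las(pc: PointCloud, path: Path) -> None:
    coords = pc.coords
    offset = np.floor(coords.min(axis=0))
    scale = np.full(3, LAS_SCALE)
    xyz_int = np.round((coords - offset) / scale).astype("<i4")
    n = len(coords)
    record_len = 20  # point format 0
    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    header[24] = 1  # version major
    header[25] = 2  # version minor
    sysid = b"rootqsm"
    header[26 : 26 + len(sysid)] = sysid
    header[58 : 58 + len(sysid)] = sysid
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)  # header size
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)  # offset to points
    header[104] = 0  # point data format
    struct.pack_into("<H", header, 105, record_len)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<6d", header, 131, *scale, *offset)
    mx, my, mz = coords.max(axis=0)
    nx, ny, nz = coords.min(axis=0)
    struct.pack_into("<6d", header, 179, mx, nx, my, ny, mz, nz)
    records = np.zeros(n, dtype=np.dtype([("xyz", "<i4", 3), ("rest", "V8")]))
    records["xyz"] = xyz_int
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(records.tobytes())


_READERS = {"ply": _read_ply, "xyz": _read_xyz, "las": _read_las}
_WRITERS = {"ply": _write_ply, "xyz": _write_xyz, "las": _write_las}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lstrip(".").lower() or "xyz"
        if fmt == "txt":
            fmt = "xyz"
    if fmt not in _READERS:
        raise ValueError(f"unknown point-cloud format {fmt!r} (know: ply, xyz, las)")
    return fmt


def read_point_cloud(path, format: str | None = None) -> PointCloud:
    """Read a cloud from PLY, XYZ text, or LAS 1.2; format inferred from suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[_infer_format(path, format)](path)


def write_point_cloud(pc: PointCloud, path, format: str | None = None) -> Path:
    """Write a non-empty cloud; the file round-trips through read_point_cloud."""
    if len(pc) == 0:
        raise EmptyCloudError("refusing to write an empty cloud")
    path = Path(path)
    _WRITERS[_infer_format(path, format)](pc, path)
    return path


# ---------------------------------------------------------------------------
# coordinate conventions


def invert_axis(pc: PointCloud) -> PointCloud:
    """Flip the cloud upside down: z' = (z_min + z_max) - z, x/y unchanged.

    Excavated roots are typically scanned collar-up; reconstruction starts at
    the collar and walks outward, so the collar must be the lowest point.
    This choice of mirror keeps the z-range (and positivity) of the input and
    is an involution.
    """
    if len(pc) == 0:
        raise EmptyCloudError("cannot invert an empty cloud")
    z = pc.coords[:, 2]
    out = pc.coords.copy()
    out[:, 2] = (z.min() + z.max()) - z
    return PointCloud(out, dict(pc.attrs), pc.crs_note)


def crop_box(pc: PointCloud, lo, hi) -> PointCloud:
    """Keep exactly the points inside the closed axis-aligned box [lo, hi]."""
    lo = np.asarray(lo, dtype=np.float64)
    hi = np.asarray(hi, dtype=np.float64)
    if lo.shape != (3,) or hi.shape != (3,):
        raise ValueError("lo and hi must be 3-vectors")
    if (lo > hi).any():
        raise ValueError(f"invalid box: lo {lo} exceeds hi {hi}")
    mask = ((pc.coords >= lo) & (pc.coords <= hi)).all(axis=1)
    if not mask.any():
        raise EmptyCloudError(
            f"crop box retained 0 of {len(pc)} points (box {lo.tolist()}..{hi.tolist()})"
        )
    return pc.select(np.flatnonzero(mask))
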