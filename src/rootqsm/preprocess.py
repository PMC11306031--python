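"""Denoising and thinning of root point clouds.

Two knobs matter downstream: the statistical-outlier-removal parameters and
the cloud parameter CP, the voxel edge length (meters) used for thinning.
CP is the tunable the trait-extraction sweep varies; CP = 0 disables
thinning entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .pointcloud import PointCloud

__all__ = ["DenoiseParams", "DownsampleParams", "remove_outliers", "downsample_cp"]


@dataclass
class DenoiseParams:
    """Statistical outlier removal: keep a point iff its mean k-NN distance
    is within ``std_ratio`` standard deviations of the cloud-wide mean."""

    k_neighbors: int = 8
    std_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 3:
            raise ValueError("k_neighbors must be >= 3")
        if self.std_ratio <= 0:
            raise ValueError("std_ratio must be > 0")


@dataclass
class DownsampleParams:
    """Voxel-grid thinning with cubic voxel edge ``cp`` meters; 0 = no-op."""

    cp: float = 0.003

    def __post_init__(self) -> None:
        if self.cp < 0:
            raise ValueError(f"cp must be >= 0, got {self.cp}")


def remove_outliers(pc: PointCloud, params: DenoiseParams | None = None) -> PointCloud:
    """Statistical outlier removal (SOR).

    For each point compute the mean distance to its ``k_neighbors`` nearest
    neighbors; points whose statistic exceeds mean + std_ratio * std over the
    whole cloud are dropped.  Output points are a subset of the input.
    """
    params = params or DenoiseParams()
    if len(pc) <= params.k_neighbors:
        raise ValueError(
            f"cloud has {len(pc)} points; need more than k_neighbors={params.k_neighbors}"
        )
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(pc.coords)
    dist, _ = nn.kneighbors(pc.coords)
    mean_dist = dist[:, 1:].mean(axis=1)  # column 0 is the point itself
    # the epsilon keeps perfectly symmetric clouds (zero spread up to float
    # jitter) from losing points to rounding of the statistic
    cutoff = mean_dist.mean() + params.std_ratio * mean_dist.std() + 1e-12
    keep = np.flatnonzero(mean_dist <= cutoff)
    return pc.select(keep)


def downsample_cp(pc: PointCloud, params: DownsampleParams | float | None = None) -> PointCloud:
    """CP-controlled voxel thinning.

    Points are assigned to cubic voxels of edge ``cp`` anchored at the world
    origin; within each occupied voxel the single point nearest the voxel
    centroid survives (ties broken by lowest point index).  Keeping an
    original point rather than the centroid avoids pulling points off the
    scanned surface, which would bias later cylinder fits.
    """
    if params is None:
        params = DownsampleParams()
    elif not isinstance(params, DownsampleParams):
        params = DownsampleParams(cp=float(params))
    if params.cp == 0:
        return pc
    cp = params.cp
    # Fixed world-anchored grid: shrinking clouds monotonically under
    # increasing cp and reproducible voxel ids across runs.
    idx = np.floor(pc.coords / cp).astype(np.int64)
    centroids = (idx + 0.5) * cp
    d2 = ((pc.coords - centroids) ** 2).sum(axis=1)
    # Stable lexicographic pick: sort by (voxel, distance, index) and keep the
    # first point of each voxel run.
    order = np.lexsort((np.arange(len(pc)), d2, idx[:, 2], idx[:, 1], idx[:, 0]))
    sorted_idx = idx[order]
    new_voxel = np.ones(len(pc), dtype=bool)
    new_voxel[1:] = (sorted_idx[1:] != sorted_idx[:-1]).any(axis=1)
    keep = np.sort(order[new_voxel])
    return pc.select(keep)
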