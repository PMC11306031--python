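"""End-to-end reconstruction: cloud in, skeleton and cylinder model out."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .pointcloud import PointCloud, invert_axis
from .preprocess import DenoiseParams, DownsampleParams, downsample_cp, remove_outliers
from .qsm import RootModel, model_from_skeleton
from .skeleton import (
    Skeleton,
    build_neighbor_graph,
    collar_shortest_path_tree,
    extract_skeleton,
)

__all__ = ["PipelineParams", "reconstruct_cloud", "run_pipeline"]


@dataclass
class PipelineParams:
    """Resolved knobs of one reconstruction run.

    ``hs`` is the skeleton bin length (geodesic segmentation length, m) and
    ``cp`` the voxel thinning edge (m); both default to the conventional
    QSM settings of 0.5 and 0.003.  Note hs = 0.5 suits multi-meter field
    scans; desk-scale synthetic roots need 0.02-0.05 m bins.
    """

    hs: float = 0.5
    cp: float = 0.003
    knn_k: int = 10
    denoise_k: int = 8
    denoise_std: float = 2.0
    continuation: str = "radius"
    invert: bool = False
    denoise: bool = True
    prune_min_points: int = 5

    def as_manifest(self) -> dict:
        return asdict(self)


def reconstruct_cloud(
    pc: PointCloud,
    hs: float = 0.5,
    knn_k: int = 10,
    continuation: str = "radius",
    prune_min_points: int = 5,
) -> tuple[RootModel, Skeleton]:
    """Skeletonize and cylinder-fit an already-preprocessed, collar-down cloud."""
    graph = build_neighbor_graph(pc, k=knn_k)
    spt = collar_shortest_path_tree(graph, pc)
    skel = extract_skeleton(
        pc, spt, bin_length=hs, graph=graph, prune_min_points=prune_min_points
    )
    model = model_from_skeleton(
        pc, skel, continuation=continuation, min_branch_length=2.0 * hs
    )
    return model, skel


def run_pipeline(pc: PointCloud, params: PipelineParams) -> tuple[RootModel, Skeleton, PointCloud]:
    """Full pipeline: optional inversion, denoise, CP thinning, reconstruction.

    Returns the model, the skeleton, and the preprocessed cloud actually
    modeled (the one basal diameters should be measured on).
    """
    work = invert_axis(pc) if params.invert else pc
    if params.denoise and len(work) > params.denoise_k:
        work = remove_outliers(
            work, DenoiseParams(k_neighbors=params.denoise_k, std_ratio=params.denoise_std)
        )
    work = downsample_cp(work, DownsampleParams(cp=params.cp))
    model, skel = reconstruct_cloud(
        work,
        hs=params.hs,
        knn_k=params.knn_k,
        continuation=params.continuation,
        prune_min_points=params.prune_min_points,
    )
    return model, skel, work
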