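"""Comparing a reconstructed model against synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import ConfusionCounts, f1, match_roots, precision, recall
from .pointcloud import PointCloud
from .qsm import RootModel
from .synth import GroundTruth
from .traits import _branch_basal_diameter_cm, extract_traits

__all__ = ["RecoveryReport", "compare_to_ground_truth"]


@dataclass
class RecoveryReport:
    """How well a reconstruction recovered the generating root system."""

    counts_detected: dict[int, int]
    counts_truth: dict[int, int]
    confusion: ConfusionCounts
    detection_f1: float
    length_rel_error: float
    volume_rel_error: float
    area_rel_error: float
    basal_diameter_rel_errors: list[float] = field(default_factory=list)

    @property
    def mean_basal_diameter_rel_error(self) -> float:
        return float(np.mean(self.basal_diameter_rel_errors))

    @property
    def max_basal_diameter_rel_error(self) -> float:
        return float(np.max(self.basal_diameter_rel_errors))

    @property
    def counts_012_exact(self) -> bool:
        return all(
            self.counts_detected.get(o, 0) == self.counts_truth.get(o, 0)
            for o in (0, 1, 2)
        )


def compare_to_ground_truth(
    model: RootModel,
    pc: PointCloud,
    truth: GroundTruth,
    tol: float = 0.1,
) -> RecoveryReport:
    """Score a reconstruction against the generator's cylinder model.

    Detection runs over (order, basal position) with one-to-one matching
    within ``tol`` meters; basal-diameter errors are computed for each true
    root against the diameter measured from the cloud at its matched
    detected branch.
    """
    traits = extract_traits(model, pc)
    tt = truth.traits
    detected = [(b.order, b.base_position) for b in model.branches]
    reference = truth.reference_roots()
    confusion = match_roots(detected, reference, tol=tol)

    rd_errors = []
    for tb in truth.model.branches:
        cands = [
            b
            for b in model.branches
            if b.order == tb.order
            and np.linalg.norm(b.base_position - tb.base_position) < tol
        ]
        if not cands:
            continue
        best = min(
            cands, key=lambda b: np.linalg.norm(b.base_position - tb.base_position)
        )
        truth_d = 2.0 * tb.basal_radius * 100.0
        measured = _branch_basal_diameter_cm(best, pc, model)
        rd_errors.append(abs(measured - truth_d) / truth_d)

    return RecoveryReport(
        counts_detected=dict(traits.per_order_counts),
        counts_truth=dict(tt.per_order_counts),
        confusion=confusion,
        detection_f1=f1(recall(confusion), precision(confusion)),
        length_rel_error=(traits.root_length - tt.root_length) / tt.root_length,
        volume_rel_error=(traits.root_volume - tt.root_volume) / tt.root_volume,
        area_rel_error=(traits.root_surface_area - tt.root_surface_area)
        / tt.root_surface_area,
        basal_diameter_rel_errors=rd_errors,
    )
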