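"""Accuracy-evaluation statistics for root phenotypes.

Regression-style agreement between measured and estimated root diameters
(R^2, RMSE, rRMSE, MAE, Pearson r) and detection-style agreement for lateral
root counts (recall, precision, F1, accuracy over TP/TN/FP/FN), plus the
greedy position matcher that produces the confusion counts from detected vs
reference root lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "PairedSample",
    "ConfusionCounts",
    "UndefinedMetricError",
    "r_squared",
    "rmse",
    "rrmse",
    "mae",
    "pearson_r",
    "pearson_r_pvalue",
    "recall",
    "precision",
    "f1",
    "accuracy",
    "match_roots",
    "round_half_up",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (constant sample, empty counts, ...)."""


@dataclass
class PairedSample:
    """Measured values x_i paired with estimates x_hat_i (or references y_i)."""

    x: np.ndarray
    x_hat: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.x_hat = np.asarray(self.x_hat, dtype=np.float64)
        if self.x.shape != self.x_hat.shape or self.x.ndim != 1:
            raise ValueError("x and x_hat must be equal-length 1D arrays")
        if not (np.isfinite(self.x).all() and np.isfinite(self.x_hat).all()):
            raise ValueError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def x_bar(self) -> float:
        return float(self.x.mean())


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Table rounding: 0.785 -> 0.79 (banker's rounding would give 0.78)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# regression agreement


def r_squared(s: PairedSample) -> float:
    """Coefficient of determination 1 - SSE/SST (can be negative)."""
    if s.n < 2:
        raise ValueError("need n >= 2 for R^2")
    sst = float(((s.x - s.x_bar) ** 2).sum())
    if sst == 0:
        raise UndefinedMetricError("R^2 undefined: measured values are constant")
    sse = float(((s.x - s.x_hat) ** 2).sum())
    return 1.0 - sse / sst


def rmse(s: PairedSample) -> float:
    if s.n < 1:
        raise ValueError("need n >= 1 for RMSE")
    return float(np.sqrt(np.mean((s.x - s.x_hat) ** 2)))


def rrmse(s: PairedSample) -> float:
    """RMSE relative to the mean measured value, in percent."""
    if s.x_bar == 0:
        raise UndefinedMetricError("rRMSE undefined: mean measured value is 0")
    return rmse(s) / s.x_bar * 100.0


def mae(s: PairedSample) -> float:
    if s.n < 1:
        raise ValueError("need n >= 1 for MAE")
    return float(np.mean(np.abs(s.x_hat - s.x)))


def pearson_r(s: PairedSample) -> float:
    """Pearson correlation between the two columns of the sample, in [-1, 1]."""
    if s.n < 2:
        raise ValueError("need n >= 2 for Pearson r")
    dx = s.x - s.x.mean()
    dy = s.x_hat - s.x_hat.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        raise UndefinedMetricError("Pearson r undefined: a sample is constant")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def pearson_r_pvalue(s: PairedSample) -> float:
    """Two-sided p-value for r via the t-distribution approximation."""
    r = pearson_r(s)
    if s.n < 3:
        return float("nan")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((s.n - 2) / (1 - r**2))
    return float(2 * stats.t.sf(abs(t), df=s.n - 2))


# ---------------------------------------------------------------------------
# detection agreement


def recall(c: ConfusionCounts) -> float:
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return c.TP / (c.TP + c.FN)


def precision(c: ConfusionCounts) -> float:
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    return c.TP / (c.TP + c.FP)


def f1(recall_value: float, precision_value: float) -> float:
    """Harmonic mean of recall and precision."""
    if recall_value + precision_value == 0:
        raise UndefinedMetricError("F1 undefined: recall + precision = 0")
    return 2.0 * recall_value * precision_value / (recall_value + precision_value)


def accuracy(c: ConfusionCounts) -> float:
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise UndefinedMetricError("accuracy undefined: no counts")
    return (c.TP + c.TN) / total


def match_roots(detected, reference, tol: float, optimal: bool = False) -> ConfusionCounts:
    """Confusion counts from detected vs reference (order, basal position) lists.

    Same-order roots are matched one-to-one when their basal positions lie
    within ``tol`` meters — greedily, closest pairs first (``optimal=True``
    switches to Hungarian minimum-cost assignment).  Matched pairs are TP,
    unmatched detections FP, unmatched references FN.  TN stays 0: there is
    no candidate universe of non-roots in open-world detection.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    detected = [(int(o), np.asarray(p, dtype=np.float64)) for o, p in detected]
    reference = [(int(o), np.asarray(p, dtype=np.float64)) for o, p in reference]
    tp = 0
    orders = sorted({o for o, _ in detected} | {o for o, _ in reference})
    for order in orders:
        det = np.array([p for o, p in detected if o == order]).reshape(-1, 3)
        ref = np.array([p for o, p in reference if o == order]).reshape(-1, 3)
        if len(det) == 0 or len(ref) == 0:
            continue
        dist = cdist(det, ref)
        if optimal:
            rows, cols = linear_sum_assignment(dist)
            tp += int((dist[rows, cols] <= tol).sum())
        else:
            dist = dist.copy()
            while np.isfinite(dist).any() and dist.min() <= tol:
                i, j = np.unravel_index(np.argmin(dist), dist.shape)
                tp += 1
                dist[i, :] = np.inf
                dist[:, j] = np.inf
    return ConfusionCounts(TP=tp, FP=len(detected) - tp, FN=len(reference) - tp)
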