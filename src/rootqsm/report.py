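"""Human-readable evaluation reports for detection and diameter agreement."""

from __future__ import annotations

import pandas as pd

from .metrics import (
    ConfusionCounts,
    PairedSample,
    UndefinedMetricError,
    accuracy,
    f1,
    mae,
    pearson_r,
    pearson_r_pvalue,
    precision,
    r_squared,
    recall,
    rmse,
    round_half_up,
    rrmse,
)

__all__ = ["detection_report", "regression_report"]


def _safe(fn, *args):
    try:
        return fn(*args)
    except UndefinedMetricError:
        return float("nan")


def _row(name: str, c: ConfusionCounts) -> dict:
    rec = _safe(recall, c)
    prec = _safe(precision, c)
    return {
        "stratum": name,
        "TP": c.TP,
        "TN": c.TN,
        "FP": c.FP,
        "FN": c.FN,
        "recall": round_half_up(rec) if rec == rec else rec,
        "precision": round_half_up(prec) if prec == prec else prec,
        "f1": round_half_up(_safe(f1, rec, prec)) if rec == rec and prec == prec else float("nan"),
        # accuracy needs TN, which open-world detection lacks; report only
        # when a candidate universe supplied TN > 0
        "accuracy": round_half_up(_safe(accuracy, c)) if c.TN > 0 else float("nan"),
    }


def detection_report(per_order: dict[int, ConfusionCounts]) -> pd.DataFrame:
    """Per-order detection metrics plus two overall aggregations.

    ``overall_pooled`` sums the confusion counts before computing metrics;
    ``overall_mean`` averages the per-order metric values.  The two differ
    when orders have unequal sample sizes, so both are reported.
    """
    rows = [_row(f"order_{order}", c) for order, c in sorted(per_order.items())]
    pooled = sum(per_order.values(), ConfusionCounts())
    rows.append(_row("overall_pooled", pooled))
    if rows[:-1]:
        frame = pd.DataFrame(rows[:-1])
        mean_row = {
            "stratum": "overall_mean",
            "TP": pooled.TP, "TN": pooled.TN, "FP": pooled.FP, "FN": pooled.FN,
            "recall": round_half_up(float(frame["recall"].mean())),
            "precision": round_half_up(float(frame["precision"].mean())),
            "f1": round_half_up(float(frame["f1"].mean())),
            "accuracy": round_half_up(float(frame["accuracy"].mean()))
            if frame["accuracy"].notna().all() else float("nan"),
        }
        rows.append(mean_row)
    return pd.DataFrame(rows)


def regression_report(s: PairedSample, label: str = "RD") -> pd.DataFrame:
    """R^2 / RMSE / rRMSE / MAE / Pearson r block for paired measurements."""
    return pd.DataFrame(
        [
            {
                "quantity": label,
                "n": s.n,
                "r2": r_squared(s),
                "rmse": rmse(s),
                "rrmse_percent": _safe(rrmse, s),
                "mae": mae(s),
                "pearson_r": _safe(pearson_r, s),
                "pearson_p_two_sided_t_approx": pearson_r_pvalue(s),
            }
        ]
    )
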