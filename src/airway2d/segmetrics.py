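"""Pixel-level segmentation accuracy metrics.

Per class: precision, recall, IoU, Dice similarity coefficient and size
difference (pixel-count gap between prediction and ground truth).  The
"overall" row is the unweighted macro mean over the three airway classes;
background is excluded.  Ratios with empty denominators (class absent from
both maps) are reported as undefined rather than imputed as zero, and are
excluded from macro means with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imgio import LabelMap, SEGMENT_NAMES

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "class_metrics",
           "macro_report"]

RATIO_KEYS = ("precision", "recall", "iou", "dsc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _grids(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    p = pred.grid if isinstance(pred, LabelMap) else np.asarray(pred)
    g = gt.grid if isinstance(gt, LabelMap) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return p, g


def confusion(pred, gt, class_id: int) -> ConfusionCounts:
    """Per-class pixel confusion counts between two label maps."""
    p, g = _grids(pred, gt)
    pm, gm = p == class_id, g == class_id
    tp = int(np.count_nonzero(pm & gm))
    fp = int(np.count_nonzero(pm & ~gm))
    fn = int(np.count_nonzero(~pm & gm))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def class_metrics(pred, gt, class_id: int, signed_size: bool = False) -> dict:
    """Precision/recall/IoU/DSC and size difference for one class.

    Undefined ratios (0/0) come back as ``None``.  ``size_difference`` is
    the absolute pixel-count gap by default; with ``signed_size`` the ground
    truth count is subtracted from the predicted count.
    """
    c = confusion(pred, gt, class_id)
    tp, fp, fn = c.tp, c.fp, c.fn

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    size = (tp + fp) - (tp + fn)
    return {
        "precision": ratio(tp, tp + fp),
        "recall": ratio(tp, tp + fn),
        "iou": ratio(tp, tp + fp + fn),
        "dsc": ratio(2 * tp, 2 * tp + fp + fn),
        "size_difference": size if signed_size else abs(size),
        "counts": c,
    }


@dataclass(frozen=True)
class MetricReport:
    """Per-class metrics plus the unweighted macro mean ('overall')."""

    per_class: dict
    overall: dict


def macro_report(pred, gt, classes=(1, 2, 3),
                 signed_size: bool = False) -> MetricReport:
    """Per-class metrics for the airway classes and their macro average.

    Classes whose ratio is undefined in a given metric are dropped from
    that metric's mean (with a warning); the overall size difference
    averages over all requested classes.
    """
    per_class = {SEGMENT_NAMES.get(c, str(c)): class_metrics(
        pred, gt, c, signed_size=signed_size) for c in classes}
    overall: dict = {}
    for key in RATIO_KEYS:
        vals = [m[key] for m in per_class.values() if m[key] is not None]
        if len(vals) < len(per_class):
            warnings.warn(
                f"{key}: {len(per_class) - len(vals)} class(es) undefined, "
                "excluded from the macro mean", stacklevel=2)
        overall[key] = float(np.mean(vals)) if vals else None
    overall["size_difference"] = float(
        np.mean([m["size_difference"] for m in per_class.values()]))
    return MetricReport(per_class=per_class, overall=overall)


def macro_iou(pred, gt, classes=(1, 2, 3)) -> float:
    """Convenience: macro-averaged IoU over the airway classes."""
    rep = macro_report(pred, gt, classes=classes)
    return rep.overall["iou"] if rep.overall["iou"] is not None else 0.0
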