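"""Pixel-level segmentation evaluation: confusion counts and the four scores.

Given a predicted mask R_seg and a ground-truth mask R_gt, with the positive
class = foreground:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1 (Dice) = 2 TP / (2 TP + FP + FN)
    IoU       = TP / (TP + FP + FN) = |R_seg ∩ R_gt| / |R_seg ∪ R_gt|

F1 and IoU are linked by IoU = F1 / (2 − F1), so IoU ≤ F1 always.  A metric
whose denominator is zero is reported as None (undefined) — except that two
empty masks agree perfectly, so F1 = IoU = 1.0 when TP = FP = FN = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_core import BinaryMask

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "score", "evaluate_bundle"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    recall: float | None
    precision: float | None
    f1: float | None
    iou: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "iou": self.iou,
        }


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-pixel confusion tally of a prediction against ground truth."""
    if pred.values.shape != truth.values.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.values.shape} vs truth {truth.values.shape}"
        )
    p, t = pred.values, truth.values
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def score(counts: ConfusionCounts) -> MetricsReport:
    """Recall, precision, F1 and IoU from confusion counts.

    Zero denominators yield None; empty-vs-empty (TP=FP=FN=0) scores
    F1 = IoU = 1.0 by the perfect-agreement convention.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn

    def frac(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    recall = frac(tp, tp + fn)
    precision = frac(tp, tp + fp)
    if tp + fp + fn == 0:
        f1: float | None = 1.0
        iou: float | None = 1.0
    else:
        f1 = 2 * tp / (2 * tp + fp + fn)
        iou = tp / (tp + fp + fn)
    return MetricsReport(counts=counts, recall=recall, precision=precision, f1=f1, iou=iou)


def evaluate_bundle(bundle, truth: BinaryMask) -> dict[str, MetricsReport]:
    """Score each mask in a :class:`~flowerseg.pipeline.PredictionBundle`.

    Returns one report per provenance: 'binarization', 'cnn', 'combined'.
    """
    return {
        "binarization": score(confusion(bundle.bin_mask, truth)),
        "cnn": score(confusion(bundle.cnn_mask, truth)),
        "combined": score(confusion(bundle.combined_mask, truth)),
    }


def reports_to_json(reports: dict[str, MetricsReport], path: str | Path) -> Path:
    """Serialize a provenance→report map as JSON (None → null)."""
    path = Path(path)
    path.write_text(
        json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2) + "\n"
    )
    return path
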