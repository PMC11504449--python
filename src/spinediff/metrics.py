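"""Segmentation evaluation: Dice, IoU, and per-dataset mean +/- sd summaries.

Dice = 2|X n Y| / (|X| + |Y|); IoU = TP / (TP + FP + FN).  Probability maps
are binarised at 0.5 before scoring.  When both masks are empty, both metrics
return 1.0 (perfect agreement on absence).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "confusion_counts", "dice", "iou", "summarize",
           "binarize", "evaluate_pairs", "write_metrics_csv"]

THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def binarize(pred: np.ndarray, threshold: float = THRESHOLD) -> np.ndarray:
    return (np.asarray(pred) >= threshold).astype(np.uint8)


def _check(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    p, y = _check(pred, truth)
    tp = int(np.sum(p & y))
    fp = int(np.sum(p & ~y))
    fn = int(np.sum(~p & y))
    tn = int(np.sum(~p & ~y))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    p, y = _check(pred, truth)
    denom = int(p.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & y)) / denom


def iou(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def summarize(scores) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (0 for a single score)."""
    scores = np.asarray(list(scores), dtype=np.float64)
    if scores.size == 0:
        raise ValueError("summarize needs at least one score")
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    return float(scores.mean()), sd


def evaluate_pairs(preds, truths, ids=None, threshold: float = THRESHOLD):
    """Score a list of (probability or binary) predictions against truths.

    Returns a list of row dicts (id, dice, iou) plus a summary dict with
    mean/sd for both metrics.
    """
    if ids is None:
        ids = [str(i) for i in range(len(preds))]
    rows = []
    for pid, p, y in zip(ids, preds, truths):
        pb = binarize(p, threshold)
        c = confusion_counts(pb, y)
        rows.append({"id": pid, "dice": dice(pb, y), "iou": iou(c)})
    d_mean, d_sd = summarize([r["dice"] for r in rows])
    i_mean, i_sd = summarize([r["iou"] for r in rows])
    summary = {"dice_mean": d_mean, "dice_sd": d_sd,
               "iou_mean": i_mean, "iou_sd": i_sd}
    return rows, summary


def write_metrics_csv(path, rows, summary) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "dice", "iou"])
        for r in rows:
            w.writerow([r["id"], f"{r['dice']:.6f}", f"{r['iou']:.6f}"])
        w.writerow(["mean", f"{summary['dice_mean']:.6f}", f"{summary['iou_mean']:.6f}"])
        w.writerow(["sd", f"{summary['dice_sd']:.6f}", f"{summary['iou_sd']:.6f}"])
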