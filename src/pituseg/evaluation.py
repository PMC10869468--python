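"""Voxel-wise segmentation evaluation: overlap scores, confusion-matrix
metrics and a subject-averaged ROC curve.

All metrics are computed inside the atlas patch, not the full head volume:
on a whole 256x256x192 grid the overwhelming background would pin accuracy
near 1 regardless of segmentation quality, so the gland-enriched ROI is the
informative evaluation region.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .roi import PatchSpec, extract_patch

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "dice_iou",
    "classification_metrics",
    "averaged_roc",
    "evaluate_test_set",
]

ROC_GRID_POINTS = 201


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """Voxel-wise (tp, fp, fn, tn); sums to the total voxel count."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return tp, fp, fn, tn


def dice_iou(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """DICE ``2|A∩B|/(|A|+|B|)`` and Jaccard ``|A∩B|/|A∪B|``.

    Both defined as 1.0 when both masks are empty (correct absence).
    """
    tp, fp, fn, _ = confusion_counts(pred, truth)
    if tp + fp + fn == 0:
        return 1.0, 1.0
    dice = 2.0 * tp / (2.0 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    return float(dice), float(iou)


def classification_metrics(counts: tuple[int, int, int, int]) -> dict:
    """Accuracy, precision, recall, F1 from (tp, fp, fn, tn).

    0/0 ratios are reported as 0.0 with ``"undefined"`` listing which.
    """
    tp, fp, fn, tn = counts
    if min(counts) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, total, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "undefined": undefined,
    }


def averaged_roc(
    per_subject: list[tuple[np.ndarray, np.ndarray]],
    n_grid: int = ROC_GRID_POINTS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertically averaged ROC over subjects.

    Each subject's voxel probabilities vs truth yields an ROC; true-positive
    rates are interpolated onto a common false-positive-rate grid and
    averaged, and the area is the trapezoid integral of the mean curve.
    Subjects whose truth contains a single class are skipped with a warning.
    """
    if not per_subject:
        raise ValueError("need at least one subject")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for i, (probs, truth) in enumerate(per_subject):
        truth = np.asarray(truth).ravel().astype(int)
        probs = np.asarray(probs, dtype=float).ravel()
        if truth.min() == truth.max():
            warnings.warn(f"subject {i}: single-class truth, skipped in ROC averaging")
            continue
        fpr, tpr, _ = roc_curve(truth, probs)
        tprs.append(np.interp(grid, fpr, tpr))
    if not tprs:
        raise ValueError("no subject had both classes present")
    mean_tpr = np.mean(tprs, axis=0)
    area = float(np.trapezoid(mean_tpr, grid))
    return grid, mean_tpr, area


@dataclass
class MetricsReport:
    """Per-subject and subject-averaged voxel-wise evaluation scores."""

    per_subject: list[dict]
    averaged: dict
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    roc_area: float | None = None

    def to_dict(self) -> dict:
        d = {
            "per_subject": self.per_subject,
            "averaged": self.averaged,
            "roc_area": self.roc_area,
        }
        if self.roc_fpr is not None:
            d["roc"] = {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _subject_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    tp, fp, fn, tn = confusion_counts(pred, truth)
    dice, iou = dice_iou(pred, truth)
    cls = classification_metrics((tp, fp, fn, tn))
    cls.pop("undefined")
    return {"dice": dice, "iou": iou, "tp": tp, "fp": fp, "fn": fn, "tn": tn, **cls}


def evaluate_test_set(model, test_pairs, spec: PatchSpec, with_roc: bool = True) -> MetricsReport:
    """Evaluate a fitted segmenter on held-out (Volume, LabelMask) pairs.

    For each subject the atlas patch is extracted, predicted, and all
    voxel-wise metrics are computed within that patch.
    """
    if not test_pairs:
        raise ValueError("empty test set")
    per_subject = []
    roc_inputs = []
    for vol, mask in test_pairs:
        patch = extract_patch(vol, spec)
        truth = extract_patch(mask, spec)
        probs = model.predict_proba(patch[None])[0]
        pred = (probs > model.threshold).astype(np.uint8)
        per_subject.append(_subject_metrics(pred, truth))
        roc_inputs.append((probs, truth))
    keys = [k for k in per_subject[0] if k != "undefined"]
    averaged = {k: float(np.mean([s[k] for s in per_subject])) for k in keys}
    report = MetricsReport(per_subject=per_subject, averaged=averaged)
    if with_roc:
        fpr, tpr, area = averaged_roc(roc_inputs)
        report.roc_fpr, report.roc_tpr, report.roc_area = fpr, tpr, area
    return report
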