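"""Mask post-processing, the image-level detection rule, and evaluation.

Segmentation quality is scored per image with the Dice similarity
coefficient ``DSC = 2|X∩Y| / (|X|+|Y|)`` and the Jaccard index
``IoU = |X∩Y| / |X∪Y|``; image-level detection derives from a pixel-count
rule (a 512x512 predicted mask with >= 3,500 activated pixels, i.e. 1.34%
of its area, is called positive), summarised by sensitivity, specificity,
precision, F1, F2 and accuracy. Ratios with zero denominators are reported
as explicitly undefined (NaN plus a flag list), never silently zeroed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "binarize", "detect", "resize_mask_nearest", "segmentation_metrics",
    "iou_to_dsc", "classification_metrics", "evaluate_dataset",
    "ConfusionCounts", "EvalReport", "DETECTION_MIN_PIXELS", "DETECTION_MASK_SIZE",
]

DETECTION_MASK_SIZE = 512
DETECTION_MIN_PIXELS = 3500


def _as_binary(mask, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(np.uint8)


def binarize(prob_map, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a {0,1} mask (inclusive: p >= t -> 1)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    probs = np.asarray(prob_map, dtype=np.float64)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    return (probs >= threshold).astype(np.uint8)


def resize_mask_nearest(mask, size: int) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (preserves binarity)."""
    arr = _as_binary(mask)
    h, w = arr.shape
    rows = (np.arange(size) * h // size)
    cols = (np.arange(size) * w // size)
    return arr[np.ix_(rows, cols)]


def detect(mask, min_pixels: int = DETECTION_MIN_PIXELS) -> bool:
    """Image-level call: positive iff the 512x512 mask has >= ``min_pixels``
    activated pixels. Masks at other sizes are resized to 512 first."""
    arr = _as_binary(mask)
    if arr.shape != (DETECTION_MASK_SIZE, DETECTION_MASK_SIZE):
        arr = resize_mask_nearest(arr, DETECTION_MASK_SIZE)
    return int(arr.sum()) >= min_pixels


def segmentation_metrics(pred, truth) -> tuple[float, float]:
    """Per-image (DSC, IoU). Both-empty pairs score (1, 1) by convention;
    one-empty pairs score (0, 0)."""
    x = _as_binary(pred, "pred")
    y = _as_binary(truth, "truth")
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    inter = int(np.logical_and(x, y).sum())
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        return 1.0, 1.0
    dsc = 2.0 * inter / (nx + ny)
    iou = inter / (nx + ny - inter)
    return dsc, iou


def iou_to_dsc(iou: float) -> float:
    """Exact algebraic relation DSC = 2*IoU / (1 + IoU)."""
    if not 0.0 <= iou <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {iou}")
    return 2.0 * iou / (1.0 + iou)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Image-level metrics from confusion counts; zero-denominator ratios
    come back as NaN."""
    if min(counts.tp, counts.fp, counts.fn, counts.tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    sens = _safe_div(counts.tp, counts.tp + counts.fn)
    spec = _safe_div(counts.tn, counts.fp + counts.tn)
    prec = _safe_div(counts.tp, counts.tp + counts.fp)
    f1 = _safe_div(2.0 * prec * sens, prec + sens) if not (
        math.isnan(prec) or math.isnan(sens)) else math.nan
    f2 = _safe_div(5.0 * prec * sens, 4.0 * prec + sens) if not (
        math.isnan(prec) or math.isnan(sens)) else math.nan
    acc = _safe_div(counts.tp + counts.tn, counts.total)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1, "f2": f2, "accuracy": acc}


@dataclass
class EvalReport:
    """Dataset-level evaluation summary.

    ``mdsc``/``miou`` average per-image scores over *all* images (true
    negatives included, scoring 1 via the both-empty convention);
    ``mdsc_positive``/``miou_positive`` restrict to images whose ground
    truth is nonempty. ``undefined`` lists metrics whose denominator was
    zero.
    """

    mdsc: float
    miou: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    f2: float
    accuracy: float
    n_images: int
    confusion: ConfusionCounts
    mdsc_positive: float = math.nan
    miou_positive: float = math.nan
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def table(self) -> str:
        """Fixed-order metric table (percent) for console output."""
        order = ["mdsc", "miou", "f1", "f2", "sensitivity", "specificity",
                 "precision", "accuracy"]
        lines = [f"{'metric':<12} {'value (%)':>10}"]
        for key in order:
            v = getattr(self, key)
            val = "undef" if math.isnan(v) else f"{100.0 * v:10.1f}"
            lines.append(f"{key:<12} {val:>10}")
        return "\n".join(lines)


def evaluate_dataset(prob_maps, truth_masks, *, threshold: float = 0.5,
                     min_pixels: int = DETECTION_MIN_PIXELS) -> EvalReport:
    """Score a collection of per-pixel probability maps against truth masks.

    Predicted image-level labels come from ``detect`` on the binarised
    prediction; ground-truth labels are simply "mask has any positive pixel"
    (the pixel-count rule applies only to predictions).
    """
    prob_maps = list(prob_maps)
    truth_masks = list(truth_masks)
    if not prob_maps:
        raise ValueError("cannot evaluate an empty collection")
    if len(prob_maps) != len(truth_masks):
        raise ValueError("predictions and truths differ in length")
    dscs, ious, pos_dscs, pos_ious = [], [], [], []
    counts = ConfusionCounts()
    for probs, truth in zip(prob_maps, truth_masks):
        pred = binarize(probs, threshold)
        truth = _as_binary(truth, "truth")
        dsc, iou = segmentation_metrics(pred, truth)
        dscs.append(dsc)
        ious.append(iou)
        truth_pos = bool(truth.any())
        if truth_pos:
            pos_dscs.append(dsc)
            pos_ious.append(iou)
        pred_pos = detect(pred, min_pixels)
        if pred_pos and truth_pos:
            counts.tp += 1
        elif pred_pos:
            counts.fp += 1
        elif truth_pos:
            counts.fn += 1
        else:
            counts.tn += 1
    cls = classification_metrics(counts)
    undefined = sorted(k for k, v in cls.items() if math.isnan(v))
    return EvalReport(
        mdsc=float(np.mean(dscs)), miou=float(np.mean(ious)),
        n_images=len(dscs), confusion=counts,
        mdsc_positive=float(np.mean(pos_dscs)) if pos_dscs else math.nan,
        miou_positive=float(np.mean(pos_ious)) if pos_ious else math.nan,
        undefined=undefined, **cls)
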