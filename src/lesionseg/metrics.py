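"""Pixel-level segmentation metrics and per-dataset reporting.

Five metrics are computed between a predicted binary mask and the
ground truth, lesion = positive class:

* DSC  = 2TP / (2TP + FP + FN)      (Dice similarity coefficient, %)
* IoU  = TP / (TP + FP + FN)        (always ≤ DSC, %)
* Pre  = TP / (TP + FP)             (%)
* Rec  = TP / (TP + FN)             (%)
* HDist: max-min Euclidean distance between the two mask contours, in
  pixels.  Contours are foreground pixels with a 4-neighbourhood
  background pixel, the image border counting as background.

Zero-denominator conventions (logged per image): both masks empty →
all overlap metrics 100%; empty prediction against non-empty GT →
Pre = 0; empty GT against non-empty prediction → Rec = 0.  A Hausdorff
distance against an empty contour is undefined: it is recorded as NaN
and excluded from aggregates.

Aggregates are mean ± sample SD (n−1 denominator; SD of a single image
is 0 by convention), matching the usual "DSC (%) ± SD" table layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .networks import PredictionMap

__all__ = ["ConfusionCounts", "ContourSet", "MetricsReport", "confusion",
           "overlap_metrics", "extract_contour", "hausdorff", "evaluate"]

METRIC_NAMES = ("dsc", "iou", "pre", "rec", "hdist")


def _check_binary(mask, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {mask.shape}")
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValidationError(f"{name} must be binary (values in {{0,1}})")
    return mask.astype(bool)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ContourSet:
    """Boundary pixel coordinates (row, col) of a binary mask."""

    points: np.ndarray                  # (K, 2) int array, possibly empty

    @property
    def is_empty(self) -> bool:
        return self.points.shape[0] == 0


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN tallies, lesion = positive."""
    p = _check_binary(pred_mask, "pred_mask")
    g = _check_binary(gt_mask, "gt_mask")
    if p.shape != g.shape:
        raise ValidationError(
            f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return ConfusionCounts(tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
                           fn=int(np.sum(~p & g)), tn=int(np.sum(~p & ~g)))


def overlap_metrics(c: ConfusionCounts) -> tuple:
    """(dsc, iou, pre, rec) as percentages, with degenerate conventions."""
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp + fp + fn == 0:                       # both masks empty
        return (100.0, 100.0, 100.0, 100.0)
    dsc = 100.0 * 2 * tp / (2 * tp + fp + fn)
    iou = 100.0 * tp / (tp + fp + fn)
    pre = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    return (dsc, iou, pre, rec)


def extract_contour(mask) -> ContourSet:
    """Foreground pixels with a background 4-neighbour (border = background)."""
    m = _check_binary(mask, "mask")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1] &
                padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    pts = np.argwhere(boundary)
    return ContourSet(points=pts)


def hausdorff(a: ContourSet, b: ContourSet, symmetric: bool = True) -> float:
    """Hausdorff distance between two contours in pixels.

    Directed: HD(A→B) = max_a min_b ||a − b||.  The symmetric variant
    (default, the one reported in tables) is max(HD(A→B), HD(B→A)).
    Returns NaN if either contour is empty (undefined distance).
    """
    if a.is_empty or b.is_empty:
        return float("nan")
    d = cdist(a.points.astype(float), b.points.astype(float))
    fwd = d.min(axis=1).max()
    if not symmetric:
        return float(fwd)
    return float(max(fwd, d.min(axis=0).max()))


@dataclass
class MetricsReport:
    """Per-image metric rows plus mean ± SD aggregates."""

    per_image: list = field(default_factory=list)   # dicts with source_id + metrics
    notes: list = field(default_factory=list)       # degenerate-case log lines

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_image,
                            columns=("source_id",) + METRIC_NAMES)

    @property
    def aggregate(self) -> dict:
        """{metric: (mean, sd)}; NaN Hausdorff rows are excluded there."""
        df = self.to_dataframe()
        out = {}
        for name in METRIC_NAMES:
            col = df[name].to_numpy(dtype=float)
            col = col[~np.isnan(col)]
            if col.size == 0:
                out[name] = (float("nan"), float("nan"))
            else:
                sd = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
                out[name] = (float(np.mean(col)), sd)
        return out

    def summary(self) -> str:
        agg = self.aggregate
        parts = [f"{name.upper()} = {m:.2f} ± {s:.2f}"
                 for name, (m, s) in agg.items()]
        return ", ".join(parts)

    def write(self, csv_path, json_path=None):
        """Per-image rows as CSV; aggregates as JSON alongside."""
        self.to_dataframe().to_csv(Path(csv_path), index=False)
        if json_path is not None:
            agg = {k: {"mean": v[0], "sd": v[1]}
                   for k, v in self.aggregate.items()}
            Path(json_path).write_text(json.dumps(agg, indent=2))


def evaluate(preds, gts, ids=None) -> MetricsReport:
    """Score a batch of predictions against ground-truth masks.

    ``preds`` may be :class:`PredictionMap` objects (binarized by
    argmax) or binary masks.  Returns per-image rows plus aggregates.
    """
    preds, gts = list(preds), list(gts)
    if len(preds) != len(gts):
        raise ValidationError(
            f"got {len(preds)} predictions but {len(gts)} ground truths")
    if ids is None:
        ids = [f"img_{i:04d}" for i in range(len(preds))]
    if len(ids) != len(preds):
        raise ValidationError("ids length does not match predictions")

    report = MetricsReport()
    for pid, pred, gt in zip(ids, preds, gts):
        pmask = pred.hard_mask if isinstance(pred, PredictionMap) else pred
        c = confusion(pmask, gt)
        dsc, iou, pre, rec = overlap_metrics(c)
        if c.tp + c.fp + c.fn == 0:
            report.notes.append(f"{pid}: both masks empty, overlap = 100%")
        elif c.tp + c.fp == 0:
            report.notes.append(f"{pid}: empty prediction, pre = 0")
        elif c.tp + c.fn == 0:
            report.notes.append(f"{pid}: empty ground truth, rec = 0")
        hd = hausdorff(extract_contour(pmask), extract_contour(gt))
        if np.isnan(hd):
            report.notes.append(f"{pid}: empty contour, hdist undefined")
        report.per_image.append({"source_id": pid, "dsc": dsc, "iou": iou,
                                 "pre": pre, "rec": rec, "hdist": hd})
    return report
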