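"""Detection-quality metrics: IoU, precision/recall/F1, AP, mAP sweeps.

AP uses all-points (continuous) interpolation: the precision envelope is made
monotone non-increasing in recall and integrated over recall increments,
which is the direct discretisation of AP = ∫ P(R) dR.  Confidence ties are
broken by input order.  Zero-denominator precision/recall are defined as 0.0
(standard detector-evaluation convention) with a warning, so threshold
sweeps stay total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mot_io import BoundingBox, Detection, FrameStream, GroundTruthObject

__all__ = [
    "ConfusionCounts",
    "iou",
    "precision",
    "recall",
    "f1",
    "match_frame",
    "average_precision",
    "pr_curve",
    "mean_ap",
    "map_sweep",
    "MAP_SWEEP_THRESHOLDS",
]

#: IoU thresholds of the mAP@.5:.95 sweep: 0.50, 0.55, ..., 0.95.
MAP_SWEEP_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.right, b.right) - max(a.left, b.left)
    iy = min(a.bottom, b.bottom) - max(a.top, b.top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (tp+fp=0); returning 0.0", stacklevel=2)
        return 0.0
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined (tp+fn=0); returning 0.0", stacklevel=2)
        return 0.0
    return c.tp / (c.tp + c.fn)


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def match_frame(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthObject],
    iou_threshold: float = 0.5,
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy single-frame matching of detections to ground truth.

    Detections are taken in descending confidence (input order on ties); each
    claims the still-unmatched gt with the highest IoU >= threshold.  Returns
    confusion counts and matched (det_index, gt_index) pairs.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    unmatched_gt = set(range(len(gts)))
    matches: list[tuple[int, int]] = []
    for di in order:
        best_j, best_iou = -1, iou_threshold
        for gj in sorted(unmatched_gt):
            v = iou(dets[di].box, gts[gj].box)
            if v > best_iou or (v == best_iou and v >= iou_threshold and best_j == -1):
                best_j, best_iou = gj, v
        if best_j >= 0:
            unmatched_gt.discard(best_j)
            matches.append((di, best_j))
    tp = len(matches)
    return ConfusionCounts(tp=tp, fp=len(dets) - tp, fn=len(unmatched_gt)), matches


def _score_detections(
    detections: FrameStream, gts: FrameStream, iou_threshold: float
) -> tuple[np.ndarray, int]:
    """Label every detection TP/FP by greedy per-frame matching in global
    confidence order; returns (tp flags sorted by confidence, n_gt)."""
    n_gt = len(gts)
    all_dets: list[tuple[float, int, Detection]] = []
    for pos, d in enumerate(detections.all_objects()):
        all_dets.append((d.confidence, pos, d))
    # stable sort: descending confidence, input order on ties
    all_dets.sort(key=lambda t: (-t[0], t[1]))
    claimed: dict[int, set[int]] = {}
    gt_by_frame: dict[int, list[GroundTruthObject]] = {
        i: objs for i, objs in gts.frames()
    }
    flags = np.zeros(len(all_dets), dtype=bool)
    for k, (_, _, det) in enumerate(all_dets):
        frame_gts = gt_by_frame.get(det.frame_index, [])
        taken = claimed.setdefault(det.frame_index, set())
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(frame_gts):
            if j in taken:
                continue
            v = iou(det.box, g.box)
            if v > best_iou or (v == best_iou and best_j == -1 and v >= iou_threshold):
                best_j, best_iou = j, v
        if best_j >= 0:
            taken.add(best_j)
            flags[k] = True
    return flags, n_gt


def pr_curve(
    detections: FrameStream, gts: FrameStream, iou_threshold: float = 0.5
) -> list[tuple[float, float]]:
    """(recall, precision) points as the confidence threshold decreases."""
    flags, n_gt = _score_detections(detections, gts, iou_threshold)
    if n_gt == 0:
        raise ValueError("PR curve undefined without ground-truth objects")
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    rec = tp_cum / n_gt
    prec = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return list(zip(rec.tolist(), prec.tolist()))


def average_precision(
    detections: FrameStream, gts: FrameStream, iou_threshold: float = 0.5
) -> float:
    """AP by all-points interpolation of the confidence-swept PR curve."""
    flags, n_gt = _score_detections(detections, gts, iou_threshold)
    if n_gt == 0:
        raise ValueError("AP undefined without ground-truth objects")
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    rec = tp_cum / n_gt
    prec = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then sum precision over recall increments
    mrec = np.concatenate(([0.0], rec, [1.0]))
    mpre = np.concatenate(([0.0], prec, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_ap(per_class_ap: Iterable[float]) -> float:
    """Arithmetic mean AP over classes."""
    aps = list(per_class_ap)
    if not aps:
        raise ValueError("mean_ap requires at least one class AP")
    return float(np.mean(aps))


def map_sweep(
    detections_per_class: Sequence[FrameStream],
    gts_per_class: Sequence[FrameStream],
) -> tuple[float, float]:
    """(mAP@.5, mAP@.5:.95) over the 10-threshold IoU sweep."""
    if len(detections_per_class) != len(gts_per_class) or not gts_per_class:
        raise ValueError("need matching, non-empty per-class streams")
    maps = []
    for thr in MAP_SWEEP_THRESHOLDS:
        maps.append(
            mean_ap(
                average_precision(d, g, thr)
                for d, g in zip(detections_per_class, gts_per_class)
            )
        )
    return maps[0], float(np.mean(maps))
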