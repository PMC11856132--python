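"""CLEAR-MOT tracking metrics: MOTA, MOTP, identity switches, counting.

MOTA = (1 − (ΣFN + ΣFP + ΣIDS) / ΣGT) × 100 aggregates misses, false
alarms and identity switches over all frames; it can go negative when the
error total exceeds the ground-truth total.

MOTP is reported, by default, as the mean IoU overlap of correct matches
× 100 (higher is better), consistent with tracking accuracies in the 90%
range being quoted alongside it; a center-distance mode (mean pixel
distance of matched pairs, lower is better) is also available since the
classical definition reads as a distance ratio.

Correspondence follows the standard CLEAR continuity rule: pairings from
the previous frame are kept while they still overlap at least the IoU
threshold, remaining objects are matched by minimum (1 − IoU) assignment,
and a ground-truth object whose matched hypothesis identity differs from
its previously matched one counts one identity switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .association import INFEASIBLE_COST, solve_assignment
from .detection_eval import iou
from .mot_io import FrameStream

__all__ = [
    "MotFrameTally",
    "TrackingReport",
    "correspond",
    "mota",
    "motp",
    "counting_accuracy",
    "relative_change",
    "absolute_change",
    "evaluate_tracking",
]


@dataclass
class MotFrameTally:
    """Per-frame correspondence outcome."""

    frame_index: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)  # (gt_id, hyp_id, iou)
    fn: int = 0
    fp: int = 0
    ids: int = 0
    gt_count: int = 0

    # center distances of matched pairs, for the distance MOTP mode
    distances: list[float] = field(default_factory=list)


@dataclass
class TrackingReport:
    mota: float
    motp: float
    ids_total: int
    fp_total: int
    fn_total: int
    gt_total: int
    count_pred: Optional[int] = None
    count_true: Optional[int] = None
    counting_accuracy: Optional[float] = None

    def as_dict(self) -> dict:
        d = {
            "MOTA": round(self.mota, 1),
            "MOTP": round(self.motp, 2),
            "IDS": self.ids_total,
            "FP": self.fp_total,
            "FN": self.fn_total,
            "GT": self.gt_total,
        }
        if self.count_pred is not None:
            d["count_pred"] = self.count_pred
            d["count_true"] = self.count_true
            d["counting_accuracy"] = self.counting_accuracy
        return d

    def as_table(self) -> str:
        head = f"{'MOTA':>8} {'MOTP':>8} {'IDS':>6} {'FP':>6} {'FN':>6}"
        row = (f"{self.mota:7.1f}% {self.motp:7.2f}% {self.ids_total:6d} "
               f"{self.fp_total:6d} {self.fn_total:6d}")
        return head + "\n" + row


def correspond(gt: FrameStream, hyp: FrameStream,
               iou_threshold: float = 0.5) -> list[MotFrameTally]:
    """Frame-by-frame gt↔hypothesis correspondence with continuity."""
    if gt.n_frames != hyp.n_frames:
        raise ValueError(
            f"frame ranges differ: gt has {gt.n_frames}, hyp has {hyp.n_frames}"
        )
    tallies: list[MotFrameTally] = []
    pair_prev: dict[int, int] = {}   # gt_id -> hyp_id matched in previous frame
    last_match: dict[int, int] = {}  # gt_id -> hyp_id at last match ever
    for frame_index in range(1, gt.n_frames + 1):
        gt_objs = gt.frame(frame_index)
        hyp_objs = hyp.frame(frame_index)
        tally = MotFrameTally(frame_index=frame_index, gt_count=len(gt_objs))
        gt_left = list(range(len(gt_objs)))
        hyp_left = list(range(len(hyp_objs)))
        matched: list[tuple[int, int, float]] = []

        # continuity: keep previous pairs still overlapping enough
        hyp_by_id = {h.identity: j for j, h in enumerate(hyp_objs)}
        for gi in list(gt_left):
            g = gt_objs[gi]
            hj = hyp_by_id.get(pair_prev.get(g.identity))
            if hj is None or hj not in hyp_left:
                continue
            v = iou(g.box, hyp_objs[hj].box)
            if v >= iou_threshold:
                matched.append((gi, hj, v))
                gt_left.remove(gi)
                hyp_left.remove(hj)

        # minimum (1 - IoU) assignment for the rest; sub-threshold overlaps
        # are masked out up front so feasible matches are never sacrificed
        if gt_left and hyp_left:
            cost = np.ones((len(gt_left), len(hyp_left)))
            for a, gi in enumerate(gt_left):
                for b, hj in enumerate(hyp_left):
                    v = iou(gt_objs[gi].box, hyp_objs[hj].box)
                    cost[a, b] = 1.0 - v if v >= iou_threshold else INFEASIBLE_COST
            sub = solve_assignment(cost, max_cost=1.0)
            for a, b in sub.matches:
                gi, hj = gt_left[a], hyp_left[b]
                matched.append((gi, hj, 1.0 - cost[a, b]))
            for gi, hj, _ in matched:
                if gi in gt_left:
                    gt_left.remove(gi)
                if hj in hyp_left:
                    hyp_left.remove(hj)

        new_pairs: dict[int, int] = {}
        for gi, hj, v in matched:
            g_id = gt_objs[gi].identity
            h_id = hyp_objs[hj].identity
            if g_id in last_match and last_match[g_id] != h_id:
                tally.ids += 1
            last_match[g_id] = h_id
            new_pairs[g_id] = h_id
            tally.matches.append((g_id, h_id, v))
            tally.distances.append(
                math.dist(gt_objs[gi].box.center, hyp_objs[hj].box.center)
            )
        tally.fn = len(gt_left)
        tally.fp = len(hyp_left)
        pair_prev = new_pairs
        tallies.append(tally)
    return tallies


def mota(tallies: Sequence[MotFrameTally]) -> float:
    """Multi-object tracking accuracy, percent; may be negative."""
    gt_total = sum(t.gt_count for t in tallies)
    if gt_total == 0:
        raise ValueError("MOTA undefined: no ground-truth objects")
    err = sum(t.fn + t.fp + t.ids for t in tallies)
    return (1.0 - err / gt_total) * 100.0


def motp(tallies: Sequence[MotFrameTally], mode: str = "overlap") -> float:
    """Multi-object tracking precision.

    ``mode="overlap"`` (default): mean IoU of correct matches × 100,
    higher-better.  ``mode="distance"``: mean center distance in pixels of
    correct matches, lower-better.
    """
    n_matches = sum(len(t.matches) for t in tallies)
    if n_matches == 0:
        raise ValueError("MOTP undefined: no correct matches")
    if mode == "overlap":
        total = sum(v for t in tallies for (_, _, v) in t.matches)
        return total / n_matches * 100.0
    if mode == "distance":
        total = sum(d for t in tallies for d in t.distances)
        return total / n_matches
    raise ValueError(f"unknown MOTP mode {mode!r}")


def counting_accuracy(count_pred: int, count_true: int) -> float:
    """Percent agreement of the tracker count with the reference count.

    (1 − |pred − true| / true) × 100, one decimal; symmetric, so over- and
    under-counts are penalised alike.
    """
    if count_true <= 0:
        raise ValueError("counting accuracy undefined for count_true <= 0")
    return round((1.0 - abs(count_pred - count_true) / count_true) * 100.0, 1)


def relative_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``: (before−after)/before×100."""
    if before == 0:
        raise ValueError("relative change undefined for before == 0")
    return round((before - after) / before * 100.0, 1)


def absolute_change(before: float, after: float) -> float:
    """Difference ``after − before`` in percentage points, one decimal —
    the right scale for comparing two quantities that are already percents
    (e.g. two tracking accuracies)."""
    return round(after - before, 1)


def evaluate_tracking(
    gt: FrameStream,
    hyp: FrameStream,
    iou_threshold: float = 0.5,
    motp_mode: str = "overlap",
    count_pred: Optional[int] = None,
    count_true: Optional[int] = None,
) -> TrackingReport:
    """Full CLEAR-MOT report for a gt/result stream pair."""
    tallies = correspond(gt, hyp, iou_threshold)
    report = TrackingReport(
        mota=mota(tallies),
        motp=motp(tallies, motp_mode),
        ids_total=sum(t.ids for t in tallies),
        fp_total=sum(t.fp for t in tallies),
        fn_total=sum(t.fn for t in tallies),
        gt_total=sum(t.gt_count for t in tallies),
    )
    if count_true is None:
        count_true = len({o.identity for o in gt.all_objects()})
    if count_pred is None:
        count_pred = len({o.identity for o in hyp.all_objects()})
    report.count_pred = count_pred
    report.count_true = count_true
    if count_true > 0:
        report.counting_accuracy = counting_accuracy(count_pred, count_true)
    return report
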