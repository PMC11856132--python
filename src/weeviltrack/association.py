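"""Cost matrices, linear assignment, and the matching cascade.

Costs live in [0, 1] for both the IoU metric (1 − IoU) and the appearance
metric (min cosine distance over a track's gallery).  Entries ruled out by
the Mahalanobis gate are set to a sentinel above any feasible cost so that
the assignment solver never selects them.  The solver is the Hungarian
method (scipy's linear_sum_assignment); any match costing more than
``max_cost`` is demoted to unmatched on both sides.

The matching cascade visits confirmed tracks in order of increasing
time-since-last-update so recently seen tracks get first claim on the
detections — the mechanism that curbs identity drift when targets reappear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection_eval import iou
from .mot_io import BoundingBox

__all__ = [
    "INFEASIBLE_COST",
    "AssignmentResult",
    "iou_cost",
    "appearance_cost",
    "gate",
    "solve_assignment",
    "matching_cascade",
]

#: sentinel cost marking an infeasible (gated-out) pairing; above any real cost.
INFEASIBLE_COST = 1e5


@dataclass
class AssignmentResult:
    """Partition of track rows and detection columns into matches and leftovers."""

    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)


def iou_cost(
    track_boxes: Sequence[BoundingBox], det_boxes: Sequence[BoundingBox]
) -> np.ndarray:
    """Cost matrix with entry (i, j) = 1 − IoU(track_i, det_j)."""
    cost = np.ones((len(track_boxes), len(det_boxes)))
    for i, tb in enumerate(track_boxes):
        for j, db in enumerate(det_boxes):
            cost[i, j] = 1.0 - iou(tb, db)
    return cost


def appearance_cost(
    galleries: Sequence[Sequence[np.ndarray]],
    det_features: Sequence[np.ndarray],
) -> np.ndarray:
    """Entry (i, j) = min over track i's gallery of (1 − cos similarity with det j).

    All vectors must be unit-norm and share one dimension.
    """
    n_t, n_d = len(galleries), len(det_features)
    cost = np.ones((n_t, n_d))
    if n_t == 0 or n_d == 0:
        return cost
    D = np.stack([np.asarray(f, dtype=float) for f in det_features])
    dim = D.shape[1]
    for i, gallery in enumerate(galleries):
        if not len(gallery):
            continue
        G = np.stack([np.asarray(g, dtype=float) for g in gallery])
        if G.shape[1] != dim:
            raise ValueError(
                f"feature dimension mismatch: gallery {G.shape[1]} vs detections {dim}"
            )
        cost[i, :] = np.min(1.0 - G @ D.T, axis=0)
    return cost


def gate(
    cost: np.ndarray,
    gating_distances: Sequence[Sequence[float]],
    threshold: float,
) -> np.ndarray:
    """Mask out entries whose squared Mahalanobis distance exceeds threshold."""
    cost = np.array(cost, dtype=float, copy=True)
    gd = np.asarray(gating_distances, dtype=float)
    if gd.shape != cost.shape:
        raise ValueError(f"shape mismatch: cost {cost.shape} vs gating {gd.shape}")
    cost[gd > threshold] = INFEASIBLE_COST
    return cost


def solve_assignment(cost: np.ndarray, max_cost: float) -> AssignmentResult:
    """Minimum-total-cost one-to-one assignment; costly matches demoted.

    Matches whose entry exceeds ``max_cost`` (or the infeasible sentinel) are
    returned as unmatched on both sides.  Empty matrices yield all-unmatched.
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    n_rows, n_cols = cost.shape
    if n_rows == 0 or n_cols == 0:
        return AssignmentResult(
            matches=[],
            unmatched_tracks=list(range(n_rows)),
            unmatched_detections=list(range(n_cols)),
        )
    rows, cols = linear_sum_assignment(np.minimum(cost, INFEASIBLE_COST))
    result = AssignmentResult()
    matched_rows, matched_cols = set(), set()
    for r, c in sorted(zip(rows.tolist(), cols.tolist())):
        if cost[r, c] > max_cost or cost[r, c] >= INFEASIBLE_COST:
            continue
        result.matches.append((r, c))
        matched_rows.add(r)
        matched_cols.add(c)
    result.unmatched_tracks = [r for r in range(n_rows) if r not in matched_rows]
    result.unmatched_detections = [c for c in range(n_cols) if c not in matched_cols]
    return result


def matching_cascade(
    track_indices_by_depth: Callable[[int], Sequence[int]] | dict[int, Sequence[int]],
    n_detections: int,
    cost_fn: Callable[[Sequence[int], Sequence[int]], np.ndarray],
    max_cost: float,
    max_depth: int,
) -> AssignmentResult:
    """Depth-prioritised matching: depth d = tracks unseen for d frames.

    ``track_indices_by_depth`` maps a depth (time_since_update, 1-based) to
    the global track indices at that staleness; ``cost_fn(track_idx,
    det_idx)`` builds the (sub-)cost matrix on demand.  Fresh tracks are
    matched first against all still-unmatched detections.
    """
    if isinstance(track_indices_by_depth, dict):
        by_depth = track_indices_by_depth
        depth_fn = lambda d: by_depth.get(d, [])
    else:
        depth_fn = track_indices_by_depth
    result = AssignmentResult()
    remaining = list(range(n_detections))
    all_tracks: list[int] = []
    for depth in range(1, max_depth + 1):
        tracks = list(depth_fn(depth))
        all_tracks.extend(tracks)
        if not tracks or not remaining:
            continue
        sub = solve_assignment(cost_fn(tracks, remaining), max_cost)
        for ti, dj in sub.matches:
            result.matches.append((tracks[ti], remaining[dj]))
        remaining = [remaining[dj] for dj in sub.unmatched_detections]
    matched_tracks = {t for t, _ in result.matches}
    result.unmatched_tracks = [t for t in all_tracks if t not in matched_tracks]
    result.unmatched_detections = remaining
    return result
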