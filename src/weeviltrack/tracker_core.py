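"""The improved tracking-by-detection loop.

This module implements a DeepSort-style online tracker — cascade matching on
appearance with Mahalanobis gating, an IoU fallback stage, Kalman motion
prediction, and the tentative/confirmed/deleted track lifecycle — extended
with a persistent per-identity history store ("Target_dict").  The store
maps every identity ever issued to its recorded (frame, center, box)
trajectory and outlives track deletion, which enables three behaviours a
plain tracker lacks:

* **ID validation** — each matched observation is checked against the
  identity's history (frame gap and implied speed); an implausible jump
  forces a fresh identity instead of silently corrupting the trajectory.
* **max-ID+1 issuing** — new identities are always one above the maximum
  identity ever recorded, so no identity is ever reused.
* **identity recovery** — a newly spawned track first looks for a dormant
  identity whose last recorded position it plausibly continues (within the
  gap/speed limits), resuming it rather than minting a new one.  This is
  what reduces identity switches when a target reappears after an occlusion
  long enough to have killed its track.

Unique-target counting reads the store: an identity counts if its recorded
trajectory is at least ``min_track_length`` frames long, so short-lived
false-positive flickers do not inflate the count.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .association import (
    INFEASIBLE_COST,
    appearance_cost,
    gate,
    iou_cost,
    matching_cascade,
    solve_assignment,
)
from .motion_model import KalmanBoxTracker, MotionState
from .mot_io import BoundingBox, Detection, FrameStream, GroundTruthObject

__all__ = [
    "TrackStatus",
    "Track",
    "TrackSnapshot",
    "TrackerConfig",
    "TargetHistoryStore",
    "HistoryRecord",
    "Tracker",
    "new_identity",
    "update_history",
    "validate_id",
    "count_targets",
]


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackerConfig:
    """Tunable tracker parameters.

    Defaults assume 30 fps video: ``max_age=30`` keeps a lost track alive for
    one second, and ``validation_max_gap=2*max_age`` lets the history store
    bridge occlusions up to twice as long as the motion filter itself — a
    store that cannot outlast track deletion could never recover an
    identity, which is its purpose.  ``validation_max_speed`` defaults to a
    tenth of the image diagonal per frame (scale-free); use ``for_arena`` to
    derive it from the frame size.
    """

    n_init: int = 3
    max_age: int = 30
    max_iou_cost: float = 0.7
    max_appearance_cost: float = 0.25
    gating_threshold: float = 9.4877  # chi-square 0.95 quantile, 4 dof
    appearance_budget: int = 100
    validation_max_speed: float = 150.0
    validation_max_gap: int = 60
    history_enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.n_init, self.max_age, self.appearance_budget,
               self.validation_max_gap) < 1:
            raise ValueError("count parameters must be positive")
        if min(self.max_iou_cost, self.max_appearance_cost,
               self.gating_threshold, self.validation_max_speed) <= 0:
            raise ValueError("threshold parameters must be positive")

    @classmethod
    def for_arena(cls, width: float, height: float, **overrides) -> "TrackerConfig":
        """Config with validation_max_speed = image diagonal / 10."""
        overrides.setdefault(
            "validation_max_speed", math.hypot(width, height) / 10.0
        )
        return cls(**overrides)

    @classmethod
    def from_dict(cls, d: dict) -> "TrackerConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown tracker config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass(frozen=True)
class HistoryRecord:
    frame_index: int
    center: tuple[float, float]
    box: BoundingBox


class TargetHistoryStore:
    """Persistent identity → trajectory map; survives track deletion."""

    def __init__(self) -> None:
        self._records: dict[int, list[HistoryRecord]] = {}

    def __contains__(self, identity: int) -> bool:
        return identity in self._records

    def identities(self) -> list[int]:
        return sorted(self._records)

    def records(self, identity: int) -> list[HistoryRecord]:
        return list(self._records[identity])

    def last(self, identity: int) -> HistoryRecord:
        return self._records[identity][-1]

    def length(self, identity: int) -> int:
        return len(self._records[identity])

    def max_identity(self) -> int:
        return max(self._records, default=0)

    def add(self, identity: int, frame_index: int, center: tuple[float, float],
            box: BoundingBox) -> None:
        recs = self._records.setdefault(identity, [])
        if recs and frame_index <= recs[-1].frame_index:
            raise ValueError(
                f"frame {frame_index} not after last recorded frame "
                f"{recs[-1].frame_index} for identity {identity}"
            )
        recs.append(HistoryRecord(frame_index, center, box))


@dataclass
class Track:
    """One tracked identity with motion state, appearance gallery and lifecycle."""

    identity: int
    motion: MotionState
    status: TrackStatus = TrackStatus.TENTATIVE
    hits: int = 1
    time_since_update: int = 0
    age: int = 1
    gallery: deque = field(default_factory=lambda: deque(maxlen=100))

    @property
    def box(self) -> BoundingBox:
        return self.motion.to_box()

    def is_confirmed(self) -> bool:
        return self.status is TrackStatus.CONFIRMED


@dataclass(frozen=True)
class TrackSnapshot:
    identity: int
    box: BoundingBox
    status: TrackStatus
    hits: int
    age: int
    time_since_update: int


def new_identity(store: TargetHistoryStore, live_tracks: Sequence[Track]) -> int:
    """Next identity: 1 + max over everything ever recorded and everything live."""
    live_max = max((t.identity for t in live_tracks), default=0)
    return 1 + max(store.max_identity(), live_max, 0)


def validate_id(
    history: Sequence[HistoryRecord],
    candidate: tuple[int, tuple[float, float]],
    max_speed: float,
    max_gap: int,
) -> bool:
    """Is continuing this identity with the candidate observation plausible?

    True iff the frame gap is at most ``max_gap`` and the implied speed
    (Euclidean center displacement / gap) is at most ``max_speed`` — both
    bounds inclusive.
    """
    if not history:
        raise ValueError("validate_id requires non-empty history")
    frame, center = candidate
    last = history[-1]
    gap = frame - last.frame_index
    if gap <= 0:
        raise ValueError(
            f"candidate frame {frame} not after last history frame {last.frame_index}"
        )
    if gap > max_gap:
        return False
    speed = math.dist(center, last.center) / gap
    return speed <= max_speed


def update_history(
    store: TargetHistoryStore,
    track: Track,
    frame_index: int,
    config: TrackerConfig,
    box: Optional[BoundingBox] = None,
) -> None:
    """Record a matched track's position, validating the identity first.

    ``box`` is the observation to record (the matched detection box); it
    defaults to the track's current filtered box.  An identity unknown to
    the store gets a new entry.  A known identity is validated; if the
    observation is implausible the track is reassigned the next fresh
    identity (max+1) and a new entry is started — the old entry is
    preserved untouched.
    """
    if box is None:
        box = track.box
    center = box.center
    if track.identity not in store:
        store.add(track.identity, frame_index, center, box)
        return
    if validate_id(store.records(track.identity), (frame_index, center),
                   config.validation_max_speed, config.validation_max_gap):
        store.add(track.identity, frame_index, center, box)
    else:
        track.identity = new_identity(store, [])
        store.add(track.identity, frame_index, center, box)


def count_targets(store: TargetHistoryStore,
                  min_track_length: int = TrackerConfig.n_init) -> int:
    """Number of identities with a recorded trajectory of at least
    ``min_track_length`` frames."""
    return sum(1 for i in store.identities() if store.length(i) >= min_track_length)


class Tracker:
    """Online multi-target tracker; call :meth:`step` once per frame.

    With ``config.history_enabled`` false the store still records
    trajectories (it is the bookkeeping behind output and counting) but the
    validation and identity-recovery behaviours are switched off, giving the
    plain DeepSort baseline for ablation.
    """

    def __init__(self, config: Optional[TrackerConfig] = None,
                 kalman: Optional[KalmanBoxTracker] = None):
        self.config = config or TrackerConfig()
        self.kf = kalman or KalmanBoxTracker()
        self.store = TargetHistoryStore()
        self.tracks: list[Track] = []
        self.last_frame: int = 0

    # -- matching stages -------------------------------------------------

    def _cascade_match(self, detections: Sequence[Detection]):
        confirmed_idx = [i for i, t in enumerate(self.tracks) if t.is_confirmed()]
        use_appearance = (
            len(detections) > 0
            and all(d.feature is not None for d in detections)
            and any(len(self.tracks[i].gallery) for i in confirmed_idx)
        )
        cfg = self.config

        def cost_fn(track_sub: Sequence[int], det_sub: Sequence[int]) -> np.ndarray:
            t_objs = [self.tracks[i] for i in track_sub]
            d_objs = [detections[j] for j in det_sub]
            boxes = [d.box for d in d_objs]
            if use_appearance:
                cost = appearance_cost([list(t.gallery) for t in t_objs],
                                       [d.feature for d in d_objs])
            else:
                cost = iou_cost([t.box for t in t_objs], boxes)
            gd = [self.kf.gating_distance(t.motion, boxes) for t in t_objs]
            return gate(cost, gd, cfg.gating_threshold)

        by_depth: dict[int, list[int]] = {}
        for i in confirmed_idx:
            by_depth.setdefault(self.tracks[i].time_since_update, []).append(i)
        max_cost = cfg.max_appearance_cost if use_appearance else cfg.max_iou_cost
        return matching_cascade(by_depth, len(detections), cost_fn, max_cost,
                                cfg.max_age + 1)

    def _iou_match(self, track_idx: Sequence[int], det_idx: Sequence[int],
                   detections: Sequence[Detection]):
        cost = iou_cost([self.tracks[i].box for i in track_idx],
                        [detections[j].box for j in det_idx])
        sub = solve_assignment(cost, self.config.max_iou_cost)
        matches = [(track_idx[a], det_idx[b]) for a, b in sub.matches]
        unmatched_t = [track_idx[a] for a in sub.unmatched_tracks]
        unmatched_d = [det_idx[b] for b in sub.unmatched_detections]
        return matches, unmatched_t, unmatched_d

    # -- lifecycle -------------------------------------------------------

    def _spawn(self, det: Detection, frame_index: int) -> Track:
        identity = None
        if self.config.history_enabled:
            identity = self._recover_identity(det, frame_index)
        if identity is None:
            identity = new_identity(self.store, self.tracks)
        track = Track(
            identity=identity,
            motion=self.kf.initiate(det.box),
            gallery=deque(maxlen=self.config.appearance_budget),
        )
        if det.feature is not None:
            track.gallery.append(det.feature)
        self.store.add(identity, frame_index, det.box.center, det.box)
        return track

    def _recover_identity(self, det: Detection, frame_index: int) -> Optional[int]:
        """Dormant identity whose history the detection plausibly continues."""
        live = {t.identity for t in self.tracks}
        cfg = self.config
        best, best_dist = None, float("inf")
        for ident in self.store.identities():
            if ident in live or self.store.length(ident) < cfg.n_init:
                continue
            last = self.store.last(ident)
            if last.frame_index >= frame_index:
                continue
            if not validate_id(self.store.records(ident),
                               (frame_index, det.box.center),
                               cfg.validation_max_speed, cfg.validation_max_gap):
                continue
            d = math.dist(det.box.center, last.center)
            if d < best_dist:
                best, best_dist = ident, d
        return best

    # -- main loop -------------------------------------------------------

    def step(self, frame_index: int, detections: Sequence[Detection]) -> list[TrackSnapshot]:
        """Advance one frame; returns snapshots of confirmed, currently
        detected tracks."""
        if frame_index <= self.last_frame:
            raise ValueError(
                f"frame_index must increase: got {frame_index} after {self.last_frame}"
            )
        self.last_frame = frame_index
        cfg = self.config

        for t in self.tracks:
            t.motion = self.kf.predict(t.motion)
            t.age += 1
            t.time_since_update += 1

        cascade = self._cascade_match(detections)
        matches = list(cascade.matches)

        # IoU stage: tentative tracks plus confirmed tracks missed exactly once
        iou_candidates = [
            i for i, t in enumerate(self.tracks)
            if (not t.is_confirmed() or t.time_since_update == 1)
            and i not in {m[0] for m in matches}
        ]
        iou_matches, _, unmatched_dets = self._iou_match(
            iou_candidates, cascade.unmatched_detections, detections
        )
        matches.extend(iou_matches)

        matched_track_idx = {m[0] for m in matches}
        for ti, dj in matches:
            track, det = self.tracks[ti], detections[dj]
            track.motion = self.kf.update(track.motion, det.box)
            track.hits += 1
            track.time_since_update = 0
            if det.feature is not None:
                track.gallery.append(det.feature)
            if track.status is TrackStatus.TENTATIVE and track.hits >= cfg.n_init:
                track.status = TrackStatus.CONFIRMED
            if cfg.history_enabled:
                update_history(self.store, track, frame_index, cfg, box=det.box)
            else:
                self.store.add(track.identity, frame_index,
                               det.box.center, det.box)

        for i, t in enumerate(self.tracks):
            if i in matched_track_idx:
                continue
            if t.status is TrackStatus.TENTATIVE or t.time_since_update > cfg.max_age:
                t.status = TrackStatus.DELETED
        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]

        for dj in unmatched_dets:
            self.tracks.append(self._spawn(detections[dj], frame_index))

        return [
            TrackSnapshot(t.identity, t.box, t.status, t.hits, t.age,
                          t.time_since_update)
            for t in self.tracks
            if t.is_confirmed() and t.time_since_update == 0
        ]

    def run(self, detections: FrameStream) -> None:
        """Feed every frame of a detection stream through :meth:`step`."""
        for frame_index, dets in detections.frames():
            self.step(frame_index, dets)

    def results(self, min_track_length: Optional[int] = None) -> FrameStream:
        """Tracker output as a result stream, rebuilt from the history store.

        Identities shorter than ``min_track_length`` (default ``n_init``) are
        dropped; this also restores the pre-confirmation frames of tracks
        that went on to be confirmed.
        """
        min_len = self.config.n_init if min_track_length is None else min_track_length
        out = FrameStream(self.last_frame)
        for ident in self.store.identities():
            recs = self.store.records(ident)
            if len(recs) < min_len:
                continue
            for r in recs:
                out.add(GroundTruthObject(r.frame_index, ident, r.box))
        return out

    def count(self, min_track_length: Optional[int] = None) -> int:
        min_len = self.config.n_init if min_track_length is None else min_track_length
        return count_targets(self.store, min_len)
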