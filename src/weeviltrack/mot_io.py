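"""MOT-16 text-file I/O, run configuration, and the core data types.

The MOT-16 dialects handled here are the plain comma-separated files used by
the MOTChallenge benchmarks::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

For detection files (``kind="det"``) the id column is ``-1`` and the last
three columns are placeholders; for ground-truth and tracker-result files the
id column carries the object identity.  Ground-truth files may carry the
extended MOT-16 columns (class, visibility) in place of ``x,y,z``; they are
accepted and ignored.

Frame indices are 1-based (MOT convention).  Box coordinates are 0-based
pixel positions of the top-left corner with width/height in pixels; boxes are
treated as continuous regions for area computation.

Note: a MOT text file cannot encode trailing all-empty frames — on read,
``n_frames`` is inferred from the maximum frame index present — so the
write→read round trip is lossless for any stream whose final frame is
non-empty.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "BoundingBox",
    "Detection",
    "GroundTruthObject",
    "FrameStream",
    "MotFormatError",
    "read_mot_file",
    "write_mot_file",
    "read_feature_file",
    "write_feature_file",
    "load_config",
    "setup_logging",
]

log = logging.getLogger("weeviltrack")

_FEATURE_NORM_TOL = 1e-6


class MotFormatError(ValueError):
    """Raised on malformed or invalid MOT-format input."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle: top-left corner plus width/height."""

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        vals = (self.left, self.top, self.width, self.height)
        if not all(math.isfinite(v) for v in vals):
            raise MotFormatError(f"non-finite bounding box {vals}")
        if self.width <= 0 or self.height <= 0:
            raise MotFormatError(
                f"bounding box must have positive size, got w={self.width} h={self.height}"
            )

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    def to_xyah(self) -> np.ndarray:
        """(center_x, center_y, aspect w/h, height) — the tracking observation."""
        cx, cy = self.center
        return np.array([cx, cy, self.width / self.height, self.height])

    @staticmethod
    def from_xyah(xyah: Sequence[float]) -> "BoundingBox":
        cx, cy, a, h = map(float, xyah)
        w = a * h
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass(frozen=True)
class Detection:
    """One detector output on one frame."""

    frame_index: int
    box: BoundingBox
    confidence: float
    feature: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise MotFormatError(f"frame_index must be >= 1, got {self.frame_index}")
        if not 0.0 <= self.confidence <= 1.0:
            raise MotFormatError(f"confidence must lie in [0,1], got {self.confidence}")
        if self.feature is not None:
            f = np.asarray(self.feature, dtype=float)
            norm = float(np.linalg.norm(f))
            if abs(norm - 1.0) > _FEATURE_NORM_TOL:
                raise MotFormatError(f"feature vector must be unit-norm, got |f|={norm}")
            object.__setattr__(self, "feature", f)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Detection):
            return NotImplemented
        if (self.frame_index, self.box, self.confidence) != (
            other.frame_index,
            other.box,
            other.confidence,
        ):
            return False
        if (self.feature is None) != (other.feature is None):
            return False
        return self.feature is None or bool(np.array_equal(self.feature, other.feature))


@dataclass(frozen=True)
class GroundTruthObject:
    """One annotated (or tracker-output) object: frame, identity, box."""

    frame_index: int
    identity: int
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise MotFormatError(f"frame_index must be >= 1, got {self.frame_index}")
        if self.identity < 1:
            raise MotFormatError(f"identity must be >= 1, got {self.identity}")


class FrameStream:
    """Ordered per-frame collection of Detection or GroundTruthObject.

    Frames are indexed 1..n_frames; frames with no objects are empty lists.
    """

    def __init__(self, n_frames: int = 0):
        if n_frames < 0:
            raise MotFormatError("n_frames must be >= 0")
        self._frames: dict[int, list] = {i: [] for i in range(1, n_frames + 1)}

    @property
    def n_frames(self) -> int:
        return len(self._frames)

    def add(self, obj: Union[Detection, GroundTruthObject]) -> None:
        """Append an object, extending the stream to cover its frame."""
        idx = obj.frame_index
        for i in range(self.n_frames + 1, idx + 1):
            self._frames[i] = []
        if isinstance(obj, GroundTruthObject):
            if any(o.identity == obj.identity for o in self._frames[idx]):
                raise MotFormatError(
                    f"duplicate identity {obj.identity} in frame {idx}"
                )
        self._frames[idx].append(obj)

    def pad_to(self, n_frames: int) -> None:
        """Extend the stream with empty frames up to ``n_frames``."""
        for i in range(self.n_frames + 1, n_frames + 1):
            self._frames[i] = []

    def frame(self, index: int) -> list:
        if not 1 <= index <= self.n_frames:
            raise KeyError(f"frame {index} outside 1..{self.n_frames}")
        return list(self._frames[index])

    def frames(self) -> Iterator[tuple[int, list]]:
        for i in range(1, self.n_frames + 1):
            yield i, list(self._frames[i])

    def __iter__(self) -> Iterator[tuple[int, list]]:
        return self.frames()

    def __len__(self) -> int:
        return sum(len(v) for v in self._frames.values())

    def all_objects(self) -> list:
        return [o for _, objs in self.frames() for o in objs]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameStream):
            return NotImplemented
        if self.n_frames != other.n_frames:
            return False
        return all(self._frames[i] == other._frames[i] for i in self._frames)

    def __repr__(self) -> str:
        return f"FrameStream(n_frames={self.n_frames}, n_objects={len(self)})"


_KINDS = ("det", "gt", "result")


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise MotFormatError(
            f"{path}:{lineno}: non-numeric field {token!r}"
        ) from None


def read_mot_file(path: Union[str, Path], kind: str) -> FrameStream:
    """Read a MOT-16 text file into a FrameStream.

    ``kind="det"`` yields Detections (identities discarded, confidence kept);
    ``kind="gt"`` / ``"result"`` yield GroundTruthObjects (identities kept).
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    stream = FrameStream()
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MotFormatError(
                    f"{path}:{lineno}: expected >=7 comma-separated fields, got {len(parts)}"
                )
            vals = [_parse_float(p, str(path), lineno) for p in parts[:7]]
            frame = int(vals[0])
            ident = int(vals[1])
            box_vals = vals[2:6]
            conf = vals[6]
            if frame < 1:
                raise MotFormatError(f"{path}:{lineno}: frame index must be >= 1")
            try:
                box = BoundingBox(*box_vals)
            except MotFormatError as e:
                raise MotFormatError(f"{path}:{lineno}: {e}") from None
            if kind == "det":
                stream.add(Detection(frame, box, min(max(conf, 0.0), 1.0)))
            else:
                stream.add(GroundTruthObject(frame, ident, box))
    return stream


def write_mot_file(stream: FrameStream, path: Union[str, Path], kind: str) -> None:
    """Write a FrameStream as a MOT-16 text file (readable by read_mot_file).

    Coordinates are written with 2 decimals; gt/result confidence is 1.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        for frame, objs in stream.frames():
            for obj in objs:
                b = obj.box
                if kind == "det":
                    ident, conf = -1, getattr(obj, "confidence", 1.0)
                else:
                    ident, conf = obj.identity, 1.0
                fh.write(
                    f"{frame},{ident},{b.left:.2f},{b.top:.2f},"
                    f"{b.width:.2f},{b.height:.2f},{conf:.6f},-1,-1,-1\n"
                )


def write_feature_file(stream: FrameStream, path: Union[str, Path]) -> None:
    """Write a feature sidecar: one whitespace-separated vector per detection
    line, in the same order as the detection file."""
    with open(path, "w", encoding="ascii") as fh:
        for _, dets in stream.frames():
            for d in dets:
                if d.feature is None:
                    raise MotFormatError("detection without feature in feature sidecar write")
                fh.write(" ".join(f"{x:.8f}" for x in d.feature) + "\n")


def read_feature_file(path: Union[str, Path], stream: FrameStream) -> FrameStream:
    """Attach sidecar feature vectors to the detections of ``stream``.

    Line *i* of the sidecar corresponds to detection *i* in frame-then-input
    order.  Returns a new FrameStream; vectors are re-normalised to unit norm.
    """
    with open(path, "r", encoding="ascii") as fh:
        rows = [line.split() for line in fh if line.strip()]
    dets = stream.all_objects()
    if len(rows) != len(dets):
        raise MotFormatError(
            f"feature file has {len(rows)} vectors but stream has {len(dets)} detections"
        )
    out = FrameStream(stream.n_frames)
    for det, row in zip(dets, rows):
        vec = np.array([float(x) for x in row])
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise MotFormatError("zero-norm feature vector in sidecar")
        out.add(Detection(det.frame_index, det.box, det.confidence, vec / norm))
    return out


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise MotFormatError(f"configuration root must be a mapping, got {type(cfg).__name__}")
    return cfg


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with level prefixes."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
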