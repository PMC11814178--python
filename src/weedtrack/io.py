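"""Reading and writing detection / ground-truth / localization files.

The on-disk dialect is the MOT-challenge CSV layout::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

Frames are 1-based.  Detection files carry ``id = -1``; ground-truth
files carry positive identities.  Boxes are converted to corner form
(``x2 = left + width``, ``y2 = top + height``) on read.

The localization log is the per-frame text record of every confirmed
track: identity, box corners, and the box centroid — eight
comma-separated columns per line.

:func:`filter_detections` applies the detector post-processing the
tracker expects: a confidence floor followed by per-frame greedy
non-maximum suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .geometry import BoundingBox, Centroid, centroid, iou

__all__ = [
    "Detection",
    "GTRecord",
    "LocalizationRecord",
    "MotParseError",
    "read_mot_file",
    "write_mot_file",
    "write_localization_log",
    "read_localization_log",
    "filter_detections",
]


class MotParseError(ValueError):
    """Raised when a MOT-dialect row cannot be parsed."""


@dataclass(frozen=True)
class Detection:
    """One detector output: frame, box, confidence, optional appearance vector."""

    frame: int
    box: BoundingBox
    confidence: float = 1.0
    feature: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.feature is not None:
            feat = np.asarray(self.feature, dtype=float)
            norm = float(np.linalg.norm(feat))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"appearance feature must be unit-norm, |f| = {norm}")
            object.__setattr__(self, "feature", feat)


@dataclass(frozen=True)
class GTRecord:
    """Ground-truth annotation: frame, identity, box."""

    frame: int
    identity: int
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        if self.identity < 1:
            raise ValueError(f"ground-truth identity must be positive, got {self.identity}")


@dataclass(frozen=True)
class LocalizationRecord:
    """Per-frame localization of one confirmed track: box plus centroid."""

    frame: int
    identity: int
    box: BoundingBox
    centroid: Centroid

    def __post_init__(self) -> None:
        c = centroid(self.box)
        if abs(c.x0 - self.centroid.x0) > 1e-9 or abs(c.y0 - self.centroid.y0) > 1e-9:
            raise ValueError("centroid does not match box centre")


def _parse_row(line: str, lineno: int) -> tuple[int, int, float, float, float, float, float]:
    parts = [p.strip() for p in line.split(",")]
    if len(parts) < 6:
        raise MotParseError(f"line {lineno}: expected >= 6 comma-separated fields, got {len(parts)}")
    try:
        frame = int(float(parts[0]))
        ident = int(float(parts[1]))
        left, top, w, h = (float(p) for p in parts[2:6])
        conf = float(parts[6]) if len(parts) > 6 else -1.0
    except ValueError as exc:
        raise MotParseError(f"line {lineno}: malformed field ({exc})") from None
    if w <= 0 or h <= 0:
        raise MotParseError(f"line {lineno}: non-positive box size w={w}, h={h}")
    if not all(math.isfinite(v) for v in (left, top, w, h)):
        raise MotParseError(f"line {lineno}: non-finite coordinates")
    return frame, ident, left, top, w, h, conf


def read_mot_file(
    path: str | Path, kind: Literal["detections", "groundtruth"]
) -> list[Detection] | list[GTRecord]:
    """Read a MOT-dialect CSV file.

    Rows are returned sorted by frame (stable, so within-frame order is
    preserved).  For ``kind="detections"`` a missing or ``-1``
    confidence is treated as 1.0.
    """
    if kind not in ("detections", "groundtruth"):
        raise ValueError(f"kind must be 'detections' or 'groundtruth', got {kind!r}")
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(_parse_row(line, lineno))
    rows.sort(key=lambda r: r[0])  # stable: keeps within-frame order
    if kind == "detections":
        out_d: list[Detection] = []
        for frame, _ident, left, top, w, h, conf in rows:
            if conf < 0:
                conf = 1.0
            out_d.append(Detection(frame, BoundingBox.from_ltwh(left, top, w, h), conf))
        return out_d
    out_g: list[GTRecord] = []
    seen: set[tuple[int, int]] = set()
    for frame, ident, left, top, w, h, _conf in rows:
        if (frame, ident) in seen:
            raise MotParseError(f"duplicate (frame, identity) pair ({frame}, {ident})")
        seen.add((frame, ident))
        out_g.append(GTRecord(frame, ident, BoundingBox.from_ltwh(left, top, w, h)))
    return out_g


def write_mot_file(records: Iterable[Detection | GTRecord], path: str | Path) -> None:
    """Write detections or ground-truth records in the MOT dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            left, top, w, h = rec.box.to_ltwh()
            if isinstance(rec, GTRecord):
                ident, conf = rec.identity, 1.0
            else:
                ident, conf = -1, rec.confidence
            fh.write(
                f"{rec.frame},{ident},{left:.6f},{top:.6f},{w:.6f},{h:.6f},{conf:.6f},-1,-1,-1\n"
            )


def write_localization_log(records: Sequence[LocalizationRecord], path: str | Path) -> None:
    """Write the per-frame localization log.

    One line per record: ``frame, identity, x1, y1, x2, y2, x0, y0``
    with fixed 6-decimal formatting.  Records must be sorted by
    (frame, identity).
    """
    key = [(r.frame, r.identity) for r in records]
    if key != sorted(key):
        raise ValueError("localization records must be sorted by (frame, identity)")
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            b, c = r.box, r.centroid
            fh.write(
                f"{r.frame},{r.identity},{b.x1:.6f},{b.y1:.6f},{b.x2:.6f},{b.y2:.6f},"
                f"{c.x0:.6f},{c.y0:.6f}\n"
            )


def read_localization_log(path: str | Path) -> list[LocalizationRecord]:
    """Read a localization log written by :func:`write_localization_log`."""
    out: list[LocalizationRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 8:
                raise MotParseError(f"line {lineno}: expected 8 fields, got {len(parts)}")
            try:
                frame, ident = int(parts[0]), int(parts[1])
                x1, y1, x2, y2, x0, y0 = (float(p) for p in parts[2:])
            except ValueError as exc:
                raise MotParseError(f"line {lineno}: malformed field ({exc})") from None
            out.append(
                LocalizationRecord(frame, ident, BoundingBox(x1, y1, x2, y2), Centroid(x0, y0))
            )
    return out


def filter_detections(
    dets: Sequence[Detection], min_confidence: float = 0.2, nms_max_overlap: float = 0.5
) -> list[Detection]:
    """Confidence filter + per-frame greedy non-maximum suppression.

    Detections below ``min_confidence`` are dropped.  Within each frame,
    boxes are visited in descending confidence (ties keep input order)
    and a box is suppressed if its IoU with an already-kept box exceeds
    ``nms_max_overlap``.  Output is ordered by frame, then descending
    confidence within the frame.
    """
    for name, v in (("min_confidence", min_confidence), ("nms_max_overlap", nms_max_overlap)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    by_frame: dict[int, list[Detection]] = {}
    for d in dets:
        if d.confidence >= min_confidence:
            by_frame.setdefault(d.frame, []).append(d)
    out: list[Detection] = []
    for frame in sorted(by_frame):
        cand = sorted(
            enumerate(by_frame[frame]), key=lambda t: (-t[1].confidence, t[0])
        )
        kept: list[Detection] = []
        for _i, d in cand:
            if all(iou(d.box, k.box) <= nms_max_overlap for k in kept):
                kept.append(d)
        out.extend(kept)
    return out
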