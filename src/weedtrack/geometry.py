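"""Axis-aligned bounding-box arithmetic.

Boxes live in pixel coordinates with the image origin at the top-left
corner and y increasing downward.  A box is stored as its two corners
``(x1, y1)`` (upper-left) and ``(x2, y2)`` (lower-right) with
``x1 < x2`` and ``y1 < y2``; corners are real-valued, not integer pixel
indices.

Three similarity/location primitives are provided:

* :func:`centroid` — the geometric centre ``((x1+x2)/2, (y1+y2)/2)``,
  used to localize a plant from its detection box;
* :func:`iou` — intersection over union, the classical overlap measure;
* :func:`nwd` — Normalized Wasserstein Distance similarity, which models
  each box as a 2-D Gaussian and stays strictly positive even when the
  boxes do not overlap, making it better behaved than IoU for small,
  well-separated objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BoundingBox", "Centroid", "centroid", "iou", "nwd"]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: upper-left corner (x1, y1), lower-right (x2, y2)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite box coordinates: {vals}")
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"degenerate box: need x1 < x2 and y1 < y2, got {vals}"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def from_ltwh(cls, left: float, top: float, width: float, height: float) -> "BoundingBox":
        """Build from MOT-style (left, top, width, height)."""
        return cls(left, top, left + width, top + height)

    def to_ltwh(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.width, self.height)

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy)


@dataclass(frozen=True)
class Centroid:
    """Geometric centre of a bounding box, in pixels."""

    x0: float
    y0: float


def centroid(box: BoundingBox) -> Centroid:
    """Geometric centre of ``box``: x0 = (x1+x2)/2, y0 = (y1+y2)/2."""
    return Centroid((box.x1 + box.x2) / 2.0, (box.y1 + box.y2) / 2.0)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nwd(a: BoundingBox, b: BoundingBox, C: float = 12.8) -> float:
    """Normalized Wasserstein Distance similarity between two boxes.

    Each box is modelled as a 2-D Gaussian with mean at its centroid and
    diagonal covariance ``diag((w/2)^2, (h/2)^2)``.  The squared
    2-Wasserstein distance between two such Gaussians has the closed form

        W2 = (cx_a-cx_b)^2 + (cy_a-cy_b)^2 + (w_a/2-w_b/2)^2 + (h_a/2-h_b/2)^2

    and the similarity returned is ``exp(-sqrt(W2)/C)``.  It is 1 for
    identical boxes and strictly positive for any pair, overlapping or
    not.  ``C`` is a scale constant in pixels; 12.8 is the standard
    published default.
    """
    if C <= 0:
        raise ValueError(f"NWD constant C must be positive, got {C}")
    ca, cb = centroid(a), centroid(b)
    w2 = (
        (ca.x0 - cb.x0) ** 2
        + (ca.y0 - cb.y0) ** 2
        + (a.width / 2.0 - b.width / 2.0) ** 2
        + (a.height / 2.0 - b.height / 2.0) ** 2
    )
    return math.exp(-math.sqrt(w2) / C)
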