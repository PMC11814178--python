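"""Multi-object tracking: Kalman prediction + gated cascade association.

The tracker follows the DeepSort recipe.  Every frame it

1. predicts each live track one frame forward (constant velocity);
2. associates detections to tracks — confirmed tracks first, in tiers
   of ascending ``time_since_update``, by minimum-cost assignment on a
   blend of appearance (cosine distance to the track's feature gallery)
   and motion (chi-square-gated Mahalanobis distance); any tracks and
   detections still unmatched are then associated on plain IoU cost;
3. updates matched tracks (confirming a tentative track after
   ``n_init`` consecutive hits), ages unmatched ones (deleting a
   tentative track on its first miss and a confirmed track after
   ``max_age`` misses), and starts a fresh tentative track, with a
   never-reused identity, for every unmatched detection.

Only confirmed tracks that were matched in the current frame are
reported, so the output stream carries one (identity, box) pair per
visible, established object.

When no appearance features are available (``cost_mode="iou_only"`` or
``"nwd"``), the cascade collapses to a single assignment round on
IoU (or NWD) cost — i.e. SORT-style association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2

from . import kalman
from .geometry import BoundingBox, iou, nwd
from .io import Detection

__all__ = ["TrackerConfig", "Track", "Tracker", "matching_cascade"]

_INFEASIBLE = 1e5


@dataclass(frozen=True)
class TrackerConfig:
    """Runtime parameters of the tracker.

    ``min_confidence``, ``max_iou_distance`` and ``nms_max_overlap``
    are the detector-interface thresholds (defaults 0.2, 0.3, 0.5);
    the remainder are standard DeepSort lifecycle and association
    parameters, all exposed so the association behaviour can be studied.
    """

    min_confidence: float = 0.2
    max_iou_distance: float = 0.3
    nms_max_overlap: float = 0.5
    max_age: int = 30
    n_init: int = 3
    gallery_size: int = 100
    appearance_weight: float = 0.98
    gating_quantile: float = 0.95
    max_cost: float = 0.7
    cost_mode: Literal["appearance_cascade", "iou_only", "nwd"] = "iou_only"
    nwd_constant: float = 12.8

    def __post_init__(self) -> None:
        for name in ("min_confidence", "max_iou_distance", "nms_max_overlap",
                     "appearance_weight", "gating_quantile"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.cost_mode not in ("appearance_cascade", "iou_only", "nwd"):
            raise ValueError(f"unknown cost_mode {self.cost_mode!r}")

    @property
    def gating_threshold(self) -> float:
        """Chi-square gate on the 4-dof squared Mahalanobis distance."""
        return float(chi2.ppf(self.gating_quantile, df=4))


@dataclass
class Track:
    """One tracked object: identity, Kalman state, lifecycle counters."""

    identity: int
    state: kalman.KalmanState
    status: Literal["tentative", "confirmed", "deleted"] = "tentative"
    hits: int = 1
    time_since_update: int = 0
    gallery: list[np.ndarray] = field(default_factory=list)

    def predict(self) -> None:
        self.state = kalman.predict(self.state)
        self.time_since_update += 1

    def mark_hit(self, det: Detection, n_init: int, gallery_size: int) -> None:
        self.state = kalman.update(self.state, det.box)
        self.hits += 1
        self.time_since_update = 0
        if det.feature is not None:
            self.gallery.append(det.feature)
            del self.gallery[:-gallery_size]
        if self.status == "tentative" and self.hits >= n_init:
            self.status = "confirmed"

    def mark_missed(self, max_age: int) -> None:
        if self.status == "tentative":
            self.status = "deleted"
        elif self.time_since_update > max_age:
            self.status = "deleted"

    @property
    def box(self) -> BoundingBox:
        return self.state.to_box()


def _appearance_cost(track: Track, det: Detection) -> float:
    """Minimum cosine distance between the detection feature and the gallery."""
    if det.feature is None or not track.gallery:
        return 1.0
    sims = np.array([float(f @ det.feature) for f in track.gallery])
    return float(1.0 - sims.max())


def _solve(cost: np.ndarray) -> list[tuple[int, int]]:
    """Hungarian assignment; infeasible (gated) pairs are discarded."""
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < _INFEASIBLE]


def _blended_cost(
    tracks: Sequence[Track], dets: Sequence[Detection], config: TrackerConfig
) -> np.ndarray:
    gate = config.gating_threshold
    lam = config.appearance_weight
    cost = np.full((len(tracks), len(dets)), _INFEASIBLE)
    boxes = [d.box for d in dets]
    for i, trk in enumerate(tracks):
        gd = kalman.gating_distance(trk.state, boxes)
        for j, det in enumerate(dets):
            if gd[j] > gate:
                continue
            c = lam * _appearance_cost(trk, det) + (1.0 - lam) * (gd[j] / gate)
            if c <= config.max_cost:
                cost[i, j] = c
    return cost


def _overlap_cost(
    tracks: Sequence[Track], dets: Sequence[Detection], config: TrackerConfig
) -> np.ndarray:
    cost = np.full((len(tracks), len(dets)), _INFEASIBLE)
    for i, trk in enumerate(tracks):
        tb = trk.box
        for j, det in enumerate(dets):
            if config.cost_mode == "nwd":
                c = 1.0 - nwd(tb, det.box, config.nwd_constant)
            else:
                c = 1.0 - iou(tb, det.box)
            if c <= config.max_iou_distance:
                cost[i, j] = c
    return cost


def matching_cascade(
    tracks: Sequence[Track], detections: Sequence[Detection], config: TrackerConfig
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Associate one frame's detections to tracks.

    Returns ``(matches, unmatched_tracks, unmatched_detections)`` where
    matches are (track index, detection index) pairs into the input
    sequences.
    """
    n_t, n_d = len(tracks), len(detections)
    if n_t == 0 or n_d == 0:
        return [], list(range(n_t)), list(range(n_d))

    matches: list[tuple[int, int]] = []
    free_dets = list(range(n_d))

    if config.cost_mode == "appearance_cascade":
        confirmed = [i for i, t in enumerate(tracks) if t.status == "confirmed"]
        others = [i for i, t in enumerate(tracks) if t.status != "confirmed"]
        # tiers of ascending staleness: recently seen tracks claim detections first
        for age in range(1, config.max_age + 2):
            tier = [i for i in confirmed if tracks[i].time_since_update == age]
            if not tier or not free_dets:
                continue
            cost = _blended_cost([tracks[i] for i in tier], [detections[j] for j in free_dets], config)
            solved = _solve(cost)
            for r, c in solved:
                matches.append((tier[r], free_dets[c]))
            taken = {free_dets[c] for _r, c in solved}
            free_dets = [j for j in free_dets if j not in taken]
        matched_t = {t for t, _d in matches}
        iou_tracks = others + [i for i in confirmed if i not in matched_t]
    else:
        iou_tracks = list(range(n_t))

    if iou_tracks and free_dets:
        cost = _overlap_cost([tracks[i] for i in iou_tracks], [detections[j] for j in free_dets], config)
        solved = _solve(cost)
        for r, c in solved:
            matches.append((iou_tracks[r], free_dets[c]))
        taken = {free_dets[c] for _r, c in solved}
        free_dets = [j for j in free_dets if j not in taken]

    matched_t = {t for t, _d in matches}
    unmatched_tracks = [i for i in range(n_t) if i not in matched_t]
    return matches, unmatched_tracks, free_dets


class Tracker:
    """Stateful frame-by-frame tracker.

    Feed frames in strictly increasing order through :meth:`step`; each
    call returns the confirmed (identity, box) pairs for that frame.
    """

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame = 0

    def step(self, frame: int, detections: Sequence[Detection]) -> list[tuple[int, BoundingBox]]:
        if frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing: got {frame} after {self._last_frame}"
            )
        self._last_frame = frame

        for trk in self.tracks:
            trk.predict()

        matches, unmatched_tracks, unmatched_dets = matching_cascade(
            self.tracks, detections, self.config
        )
        for ti, di in matches:
            self.tracks[ti].mark_hit(
                detections[di], self.config.n_init, self.config.gallery_size
            )
        for ti in unmatched_tracks:
            self.tracks[ti].mark_missed(self.config.max_age)
        for di in unmatched_dets:
            det = detections[di]
            trk = Track(self._next_id, kalman.initiate(det.box))
            if det.feature is not None:
                trk.gallery.append(det.feature)
            if self.config.n_init <= 1:
                trk.status = "confirmed"
            self._next_id += 1
            self.tracks.append(trk)

        self.tracks = [t for t in self.tracks if t.status != "deleted"]
        return [
            (t.identity, t.box)
            for t in self.tracks
            if t.status == "confirmed" and t.time_since_update == 0
        ]

    def run(
        self, detections: Sequence[Detection], n_frames: Optional[int] = None
    ) -> dict[int, list[tuple[int, BoundingBox]]]:
        """Track a whole detection stream; returns frame -> (id, box) pairs.

        Frames up to ``n_frames`` (or the last detection's frame) with no
        detections are stepped through as empty frames so track ageing
        behaves as in a real video.
        """
        by_frame: dict[int, list[Detection]] = {}
        for d in detections:
            by_frame.setdefault(d.frame, []).append(d)
        last = n_frames if n_frames is not None else (max(by_frame) if by_frame else 0)
        out: dict[int, list[tuple[int, BoundingBox]]] = {}
        for frame in range(1, last + 1):
            out[frame] = self.step(frame, by_frame.get(frame, []))
        return out
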