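"""Line-crossing counting with counted-ID invalidation, and centroid logging.

A horizontal detection line is fixed at pixel row ``line_y``.  A track
is counted the first time its box straddles the line
(``y1 <= line_y <= y2``); its identity is then added to a persistent
counted-ID set and never counted again, so a plant that lingers on the
line — or re-crosses it when the platform speed varies — contributes
exactly once.  The cumulative count Z is the sum of per-frame
increments, and equals the size of the counted-ID set at all times.

The known failure mode is an identity switch at the line: if tracking
assigns a second identity to a plant while it still straddles the line,
that identity is counted too.  Counting accuracy therefore inherits the
tracker's identity stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .geometry import BoundingBox, Centroid, centroid
from .io import LocalizationRecord

__all__ = ["CountState", "CountEvent", "crossing_check", "count_update", "localize_frame", "LineCounter"]


@dataclass(frozen=True)
class CountEvent:
    """A track being counted: the frame, identity, and centroid at crossing."""

    frame: int
    identity: int
    centroid: Centroid


@dataclass
class CountState:
    """Running count Z plus the persistent set of already-counted identities."""

    line_y: float
    total: int = 0
    counted_ids: set[int] = field(default_factory=set)
    per_frame_increments: list[int] = field(default_factory=list)
    _last_frame: int = 0

    def __post_init__(self) -> None:
        if self.total != len(self.counted_ids):
            raise ValueError("total must equal the number of counted identities")


def crossing_check(box: BoundingBox, line_y: float) -> bool:
    """True iff the detection line straddles the box: y1 <= line_y <= y2."""
    return box.y1 <= line_y <= box.y2


def count_update(
    state: CountState,
    frame_result: Sequence[tuple[int, BoundingBox]],
    frame: int,
) -> tuple[CountState, list[CountEvent]]:
    """Process one frame of confirmed tracks; count first-time line crossings.

    Mutates and returns ``state``.  Each identity straddling the line
    that is not yet in ``counted_ids`` increments Z by one and emits a
    :class:`CountEvent`; already-counted identities are ignored.
    """
    if frame <= state._last_frame:
        raise ValueError(f"frames must be strictly increasing: {frame} after {state._last_frame}")
    idents = [i for i, _b in frame_result]
    if len(idents) != len(set(idents)):
        raise ValueError("duplicate identity within one frame")
    state._last_frame = frame
    events: list[CountEvent] = []
    increment = 0
    for identity, box in frame_result:
        if identity in state.counted_ids:
            continue
        if crossing_check(box, state.line_y):
            state.counted_ids.add(identity)
            increment += 1
            events.append(CountEvent(frame, identity, centroid(box)))
    state.total += increment
    state.per_frame_increments.append(increment)
    return state, events


def localize_frame(
    frame_result: Sequence[tuple[int, BoundingBox]], frame: int
) -> list[LocalizationRecord]:
    """One localization record (identity, box, centroid) per confirmed track."""
    return [
        LocalizationRecord(frame, identity, box, centroid(box))
        for identity, box in sorted(frame_result, key=lambda t: t[0])
    ]


class LineCounter:
    """Convenience wrapper: feed frames, accumulate count and localization log."""

    def __init__(self, line_y: float):
        self.state = CountState(line_y=line_y)
        self.events: list[CountEvent] = []
        self.log: list[LocalizationRecord] = []

    def step(self, frame: int, frame_result: Sequence[tuple[int, BoundingBox]]) -> list[CountEvent]:
        self.log.extend(localize_frame(frame_result, frame))
        _state, events = count_update(self.state, frame_result, frame)
        self.events.extend(events)
        return events

    @property
    def total(self) -> int:
        return self.state.total
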