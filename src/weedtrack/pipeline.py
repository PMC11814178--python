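"""End-to-end pipeline: filter -> track -> localize -> count -> evaluate.

This is the library entry point the CLI wraps.  Given a detection
stream it runs the tracker frame by frame, logs per-frame centroid
localizations, accumulates the line-crossing count, and — when ground
truth is supplied — computes the full metric report (P, R, AP, MOTA,
IDF1, IDSW, ER).

Because a track must survive ``n_init`` consecutive frames before it is
confirmed and reported, the first ``n_init - 1`` frames of every
ground-truth trajectory are unobservable by construction.
:func:`warmup_aligned_gt` drops them so tracking metrics measure
association quality rather than the confirmation delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .counting import LineCounter
from .geometry import BoundingBox
from .io import (
    Detection,
    GTRecord,
    filter_detections,
    read_mot_file,
    write_localization_log,
    write_mot_file,
)
from .metrics import CountEvalResult, clear_mot, error_rate, evaluate_detections
from .tracker import Tracker, TrackerConfig

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "track_stream", "warmup_aligned_gt"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    det_path: str | Path
    out_dir: str | Path
    gt_path: Optional[str | Path] = None
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    line_y: Optional[float] = None
    iou_threshold: float = 0.5
    n_frames: Optional[int] = None
    ground_truth_count: Optional[int] = None


@dataclass
class PipelineResult:
    """Outputs of one run; numeric report mirrors the written files."""

    frames: dict[int, list[tuple[int, BoundingBox]]]
    count: int
    count_events: int
    metrics: dict[str, float] = field(default_factory=dict)


def warmup_aligned_gt(gt: Sequence[GTRecord], n_init: int) -> list[GTRecord]:
    """Drop each identity's first ``n_init - 1`` frames of ground truth."""
    first: dict[int, int] = {}
    for g in gt:
        first[g.identity] = min(first.get(g.identity, g.frame), g.frame)
    return [g for g in gt if g.frame >= first[g.identity] + n_init - 1]


def track_stream(
    detections: Sequence[Detection],
    config: TrackerConfig,
    line_y: float,
    n_frames: Optional[int] = None,
) -> tuple[dict[int, list[tuple[int, BoundingBox]]], LineCounter]:
    """Filter + track + localize + count a detection stream in one pass."""
    filtered = filter_detections(detections, config.min_confidence, config.nms_max_overlap)
    by_frame: dict[int, list[Detection]] = {}
    for d in filtered:
        by_frame.setdefault(d.frame, []).append(d)
    last = n_frames if n_frames is not None else (max(by_frame) if by_frame else 0)
    tracker = Tracker(config)
    counter = LineCounter(line_y)
    frames: dict[int, list[tuple[int, BoundingBox]]] = {}
    for frame in range(1, last + 1):
        result = tracker.step(frame, by_frame.get(frame, []))
        counter.step(frame, result)
        frames[frame] = result
    return frames, counter


def _infer_line_y(detections: Sequence[Detection]) -> float:
    """Default counting line: mid-height of the observed extent."""
    if not detections:
        return 0.0
    return max(d.box.y2 for d in detections) / 2.0


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write all reports to ``out_dir``.

    Writes ``track.txt`` (MOT dialect), ``localization.txt``,
    ``count_report.txt`` and, when ground truth is available,
    ``metrics.txt`` as ``key value`` lines.
    """
    det_path = Path(config.det_path)
    if not det_path.exists():
        raise FileNotFoundError(f"detection file not found: {det_path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    detections = read_mot_file(det_path, "detections")
    line_y = config.line_y if config.line_y is not None else _infer_line_y(detections)
    frames, counter = track_stream(detections, config.tracker, line_y, config.n_frames)

    track_records = [
        GTRecord(frame, ident, box)
        for frame in sorted(frames)
        for ident, box in sorted(frames[frame])
    ]
    write_mot_file(track_records, out_dir / "track.txt")
    write_localization_log(counter.log, out_dir / "localization.txt")

    with open(out_dir / "count_report.txt", "w", encoding="utf-8") as fh:
        fh.write(f"line_y {line_y:.3f}\n")
        fh.write(f"count {counter.total}\n")
        for ev in counter.events:
            fh.write(
                f"event frame={ev.frame} id={ev.identity} "
                f"x0={ev.centroid.x0:.3f} y0={ev.centroid.y0:.3f}\n"
            )

    result = PipelineResult(frames, counter.total, len(counter.events))
    result.metrics["count"] = float(counter.total)
    result.metrics["line_y"] = float(line_y)

    if config.gt_path is not None:
        gt = read_mot_file(Path(config.gt_path), "groundtruth")
        det_eval = evaluate_detections(detections, gt, config.iou_threshold)
        aligned = warmup_aligned_gt(gt, config.tracker.n_init)
        mot = clear_mot(track_records, aligned, config.iou_threshold)
        m = result.metrics
        m.update(
            P=det_eval.P, R=det_eval.R, AP=det_eval.AP,
            TP=float(det_eval.TP), FP=float(det_eval.FP), FN=float(det_eval.FN),
            MOTA=mot.MOTA, IDF1=mot.IDF1, IDSW=float(mot.IDSW),
        )
        if config.ground_truth_count is not None:
            ce = CountEvalResult(
                counter.total,
                config.ground_truth_count,
                error_rate(counter.total, config.ground_truth_count),
            )
            m["ground_truth_count"] = float(ce.ground_truth)
            m["ER"] = ce.ER
        with open(out_dir / "metrics.txt", "w", encoding="utf-8") as fh:
            for key, val in result.metrics.items():
                fh.write(f"{key} {val:.6f}\n")

    return result
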