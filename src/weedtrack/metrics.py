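"""Detection, tracking and counting evaluation.

Three metric families, matching how UAV plant-survey pipelines are
scored:

* **Detection**: per-frame one-to-one IoU matching gives TP/FP/FN;
  precision P = TP/(TP+FP), recall R = TP/(TP+FN), and AP the area
  under the precision–recall curve swept over the confidence ranking.
* **Tracking** (CLEAR-MOT + identity metrics):
  MOTA = 1 − Σ_t(FN_t + FP_t + IDSW_t) / Σ_t GT_t, with per-frame
  correspondences carried over between frames while still within the
  IoU gate; IDF1 = 2·IDTP / (2·IDTP + IDFN + IDFP) under the globally
  optimal one-to-one pairing of ground-truth and hypothesis identities.
* **Counting**: error rate ER = |Count − GroundTruth| / GroundTruth × 100.

All matching is IoU-gated; the gate defaults to 0.5 and is an explicit
argument everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BoundingBox, iou
from .io import Detection, GTRecord

__all__ = [
    "UndefinedMetricError",
    "DetectionEvalResult",
    "MotEvalResult",
    "CountEvalResult",
    "match_frame",
    "precision_recall",
    "average_precision",
    "evaluate_detections",
    "clear_mot",
    "id_metrics",
    "error_rate",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not 0."""


@dataclass(frozen=True)
class DetectionEvalResult:
    TP: int
    FP: int
    FN: int
    P: float
    R: float
    AP: float


@dataclass
class MotEvalResult:
    MOTA: float
    IDF1: float
    IDSW: int
    IDTP: int
    IDFP: int
    IDFN: int
    per_frame_FN: dict[int, int] = field(default_factory=dict)
    per_frame_FP: dict[int, int] = field(default_factory=dict)
    per_frame_IDSW: dict[int, int] = field(default_factory=dict)
    per_frame_GT: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CountEvalResult:
    count: int
    ground_truth: int
    ER: float


def _check_threshold(iou_threshold: float) -> None:
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1), got {iou_threshold}")


def match_frame(
    preds: Sequence[tuple[BoundingBox, float]],
    gts: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One frame's detection matching.

    Predictions, visited in descending confidence, claim the unmatched
    ground truth of highest IoU at or above the gate.  Returns
    ``(tp_pairs, fp_pred_indices, fn_gt_indices)`` with indices into the
    input sequences.
    """
    _check_threshold(iou_threshold)
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][1], i))
    taken: set[int] = set()
    tp: list[tuple[int, int]] = []
    fp: list[int] = []
    for i in order:
        box = preds[i][0]
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(gts):
            if j in taken:
                continue
            v = iou(box, gt)
            if v >= best_iou and (best_j < 0 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            taken.add(best_j)
            tp.append((i, best_j))
        else:
            fp.append(i)
    fn = [j for j in range(len(gts)) if j not in taken]
    return tp, fp, fn


def precision_recall(TP: int, FP: int, FN: int) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); undefined denominators raise."""
    if TP < 0 or FP < 0 or FN < 0:
        raise ValueError("counts must be non-negative")
    if TP + FP == 0 or TP + FN == 0:
        raise UndefinedMetricError("precision/recall undefined: zero denominator")
    return TP / (TP + FP), TP / (TP + FN)


def average_precision(
    detections: Sequence[Detection],
    gts: Sequence[GTRecord],
    iou_threshold: float = 0.5,
    interpolation: str = "step",
) -> float:
    """Area under the precision–recall curve over the confidence ranking.

    Detections are ranked by confidence across all frames; each, in rank
    order, matches the best remaining ground truth of its frame
    (IoU >= gate).  ``interpolation="step"`` integrates the exact step
    curve Σ (R_k − R_{k−1})·P_k; ``"envelope"`` applies the
    monotone-precision envelope first (VOC all-point style).
    """
    _check_threshold(iou_threshold)
    if interpolation not in ("step", "envelope"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    n_gt = len(gts)
    if n_gt == 0:
        raise UndefinedMetricError("AP undefined: no ground truths")
    gt_by_frame: dict[int, list[GTRecord]] = {}
    for g in gts:
        gt_by_frame.setdefault(g.frame, []).append(g)
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    taken: set[tuple[int, int]] = set()  # (frame, gt index within frame)
    is_tp = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        det = detections[i]
        frame_gts = gt_by_frame.get(det.frame, [])
        best_j, best_v = -1, iou_threshold
        for j, g in enumerate(frame_gts):
            if (det.frame, j) in taken:
                continue
            v = iou(det.box, g.box)
            if v >= best_v and (best_j < 0 or v > best_v):
                best_j, best_v = j, v
        if best_j >= 0:
            taken.add((det.frame, best_j))
            is_tp[rank] = True
    tp_cum = np.cumsum(is_tp)
    k = np.arange(1, len(order) + 1)
    precision = tp_cum / k
    recall = tp_cum / n_gt
    if interpolation == "envelope":
        precision = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(precision, recall):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate_detections(
    detections: Sequence[Detection],
    gts: Sequence[GTRecord],
    iou_threshold: float = 0.5,
) -> DetectionEvalResult:
    """Aggregate TP/FP/FN, P, R and AP over a whole sequence."""
    frames = sorted({d.frame for d in detections} | {g.frame for g in gts})
    tp = fp = fn = 0
    det_by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        det_by_frame.setdefault(d.frame, []).append(d)
    gt_by_frame: dict[int, list[GTRecord]] = {}
    for g in gts:
        gt_by_frame.setdefault(g.frame, []).append(g)
    for f in frames:
        preds = [(d.box, d.confidence) for d in det_by_frame.get(f, [])]
        boxes = [g.box for g in gt_by_frame.get(f, [])]
        t, p_, n_ = match_frame(preds, boxes, iou_threshold)
        tp += len(t)
        fp += len(p_)
        fn += len(n_)
    P, R = precision_recall(tp, fp, fn)
    ap = average_precision(detections, gts, iou_threshold)
    return DetectionEvalResult(tp, fp, fn, P, R, ap)


FrameStream = Mapping[int, Sequence[tuple[int, BoundingBox]]]


def _as_stream(records: Sequence[GTRecord] | FrameStream) -> dict[int, list[tuple[int, BoundingBox]]]:
    if isinstance(records, Mapping):
        return {f: list(v) for f, v in records.items()}
    out: dict[int, list[tuple[int, BoundingBox]]] = {}
    for r in records:
        out.setdefault(r.frame, []).append((r.identity, r.box))
    return out


def clear_mot(
    hypotheses: Sequence[GTRecord] | FrameStream,
    gt: Sequence[GTRecord] | FrameStream,
    iou_threshold: float = 0.5,
) -> MotEvalResult:
    """CLEAR-MOT accumulation plus identity metrics over a sequence.

    Per frame, correspondences from the previous frame are kept while
    both members persist and their IoU stays at or above the gate;
    remaining objects are matched by Hungarian assignment on 1−IoU.
    An identity switch is charged when a ground-truth object's matched
    hypothesis ID differs from the last hypothesis ID it was ever
    matched to.
    """
    _check_threshold(iou_threshold)
    hyp_stream = _as_stream(hypotheses)
    gt_stream = _as_stream(gt)
    if not gt_stream:
        raise UndefinedMetricError("MOTA undefined: empty ground truth")

    frames = sorted(set(hyp_stream) | set(gt_stream))
    last_match: dict[int, int] = {}  # gt id -> last matched hyp id (ever)
    prev_pairs: dict[int, int] = {}  # gt id -> hyp id matched in previous frame
    res = MotEvalResult(0.0, 0.0, 0, 0, 0, 0)
    tot_fn = tot_fp = tot_idsw = tot_gt = 0

    for f in frames:
        gts_f = gt_stream.get(f, [])
        hyps_f = hyp_stream.get(f, [])
        gt_ids = [i for i, _b in gts_f]
        if len(gt_ids) != len(set(gt_ids)):
            raise ValueError(f"duplicate ground-truth identity in frame {f}")
        hyp_ids = [i for i, _b in hyps_f]
        if len(hyp_ids) != len(set(hyp_ids)):
            raise ValueError(f"duplicate hypothesis identity in frame {f}")
        gt_box = dict(gts_f)
        hyp_box = dict(hyps_f)

        pairs: dict[int, int] = {}
        # carry-over: keep last frame's correspondence while still within gate
        for g, h in prev_pairs.items():
            if g in gt_box and h in hyp_box and iou(gt_box[g], hyp_box[h]) >= iou_threshold:
                pairs[g] = h
        free_g = [g for g in gt_box if g not in pairs]
        free_h = [h for h in hyp_box if h not in pairs.values()]
        if free_g and free_h:
            cost = np.full((len(free_g), len(free_h)), 1e5)
            for a, g in enumerate(free_g):
                for b, h in enumerate(free_h):
                    v = iou(gt_box[g], hyp_box[h])
                    if v >= iou_threshold:
                        cost[a, b] = 1.0 - v
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] < 1e5:
                    pairs[free_g[a]] = free_h[b]

        fn = len(gt_box) - len(pairs)
        fp = len(hyp_box) - len(pairs)
        idsw = 0
        for g, h in pairs.items():
            if g in last_match and last_match[g] != h:
                idsw += 1
            last_match[g] = h
        res.per_frame_FN[f] = fn
        res.per_frame_FP[f] = fp
        res.per_frame_IDSW[f] = idsw
        res.per_frame_GT[f] = len(gt_box)
        tot_fn += fn
        tot_fp += fp
        tot_idsw += idsw
        tot_gt += len(gt_box)
        prev_pairs = pairs

    if tot_gt == 0:
        raise UndefinedMetricError("MOTA undefined: no ground-truth objects")
    res.MOTA = 1.0 - (tot_fn + tot_fp + tot_idsw) / tot_gt
    res.IDSW = tot_idsw
    idf1, idtp, idfp, idfn = id_metrics(hyp_stream, gt_stream, iou_threshold)
    res.IDF1, res.IDTP, res.IDFP, res.IDFN = idf1, idtp, idfp, idfn
    return res


def id_metrics(
    hypotheses: Sequence[GTRecord] | FrameStream,
    gt: Sequence[GTRecord] | FrameStream,
    iou_threshold: float = 0.5,
) -> tuple[float, int, int, int]:
    """Identity metrics: (IDF1, IDTP, IDFP, IDFN).

    Ground-truth and hypothesis identities are paired one-to-one over
    whole trajectories so that the number of frames where the paired
    identities coincide spatially (IoU >= gate) — IDTP — is maximal.
    """
    _check_threshold(iou_threshold)
    hyp_stream = _as_stream(hypotheses)
    gt_stream = _as_stream(gt)
    if not gt_stream:
        raise UndefinedMetricError("IDF1 undefined: empty ground truth")

    gt_ids = sorted({i for recs in gt_stream.values() for i, _b in recs})
    hyp_ids = sorted({i for recs in hyp_stream.values() for i, _b in recs})
    n_gt_boxes = sum(len(v) for v in gt_stream.values())
    n_hyp_boxes = sum(len(v) for v in hyp_stream.values())
    if not hyp_ids:
        return 0.0, 0, 0, n_gt_boxes

    overlap = np.zeros((len(gt_ids), len(hyp_ids)), dtype=int)
    g_index = {g: a for a, g in enumerate(gt_ids)}
    h_index = {h: b for b, h in enumerate(hyp_ids)}
    frames = set(gt_stream) & set(hyp_stream)
    for f in frames:
        for g, gb in gt_stream[f]:
            for h, hb in hyp_stream[f]:
                if iou(gb, hb) >= iou_threshold:
                    overlap[g_index[g], h_index[h]] += 1
    rows, cols = linear_sum_assignment(-overlap)
    idtp = int(overlap[rows, cols].sum())
    idfn = n_gt_boxes - idtp
    idfp = n_hyp_boxes - idtp
    denom = 2 * idtp + idfn + idfp
    idf1 = (2 * idtp / denom) if denom > 0 else 0.0
    return idf1, idtp, idfp, idfn


def error_rate(count: int, ground_truth: int) -> float:
    """Counting error rate |Count − GroundTruth| / GroundTruth, in percent."""
    if ground_truth <= 0:
        raise ValueError(f"ground truth count must be positive, got {ground_truth}")
    return abs(count - ground_truth) / ground_truth * 100.0
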