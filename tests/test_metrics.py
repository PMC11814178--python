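"""Detection/tracking/counting metrics vs worked examples and oracles."""

import itertools

import numpy as np
import pytest

from weedtrack.geometry import BoundingBox, iou
from weedtrack.io import Detection, GTRecord
from weedtrack.metrics import (
    UndefinedMetricError,
    average_precision,
    clear_mot,
    error_rate,
    evaluate_detections,
    id_metrics,
    match_frame,
    precision_recall,
)

from conftest import random_box


def box_at(x, y, s=10.0):
    return BoundingBox(x, y, x + s, y + s)


class TestMatchFrame:
    def test_perfect_predictions(self, rng):
        gts = [random_box(rng, span=200) for _ in range(8)]
        preds = [(b, 0.9) for b in gts]
        tp, fp, fn = match_frame(preds, gts)
        assert len(tp) == 8 and fp == [] and fn == []

    def test_no_predictions(self, rng):
        gts = [random_box(rng) for _ in range(5)]
        tp, fp, fn = match_frame([], gts)
        assert tp == [] and fp == [] and len(fn) == 5

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            match_frame([], [], iou_threshold=0.0)

    def test_tp_count_equals_exhaustive_maximum(self, rng):
        """Confidence-ordered one-to-one matching attains the maximum
        TP count on 6-pred/5-gt instances with separated ground truths
        (the regime where the greedy protocol is provably optimal)."""
        for _ in range(20):
            # grid placement: no prediction can reach two ground truths
            gts = [
                BoundingBox(60.0 * k, 0.0, 60.0 * k + s, s)
                for k, s in enumerate(rng.uniform(12, 20, size=5))
            ]
            preds = []
            for k in range(6):
                src = gts[k % 5]
                preds.append(
                    (src.shifted(float(rng.uniform(-6, 6)), float(rng.uniform(-6, 6))),
                     float(rng.uniform(0.5, 1.0)))
                )
            tp, _fp, _fn = match_frame(preds, gts, 0.5)
            # oracle: exhaustive over injective pred->gt maps
            feasible = {
                (i, j)
                for i in range(6)
                for j in range(5)
                if iou(preds[i][0], gts[j]) >= 0.5
            }
            best = 0
            for r in range(min(6, 5), 0, -1):
                for pred_sub in itertools.combinations(range(6), r):
                    for gt_perm in itertools.permutations(range(5), r):
                        pairs = list(zip(pred_sub, gt_perm))
                        if all(p in feasible for p in pairs):
                            best = max(best, r)
                if best == r:
                    break
            assert len(tp) == best


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,fn,p3,r3",
        [
            (5543, 308, 328, 0.947, 0.944),  # strongest detector variant
            (5109, 626, 762, 0.891, 0.870),  # SSD baseline comparison
        ],
    )
    def test_published_confusion_counts(self, tp, fp, fn, p3, r3):
        P, R = precision_recall(tp, fp, fn)
        assert round(P, 3) == p3
        assert round(R, 3) == r3

    def test_perfect_detector(self):
        assert precision_recall(10, 0, 0) == (1.0, 1.0)

    def test_zero_denominator_flagged(self):
        with pytest.raises(UndefinedMetricError):
            precision_recall(0, 0, 5)
        with pytest.raises(UndefinedMetricError):
            precision_recall(0, 5, 0)


class TestAveragePrecision:
    def test_single_correct_prediction(self):
        gt = [GTRecord(1, 1, box_at(0, 0))]
        det = [Detection(1, box_at(0, 0), 0.9)]
        assert average_precision(det, gt) == pytest.approx(1.0)

    def test_zero_correct_predictions(self):
        gt = [GTRecord(1, 1, box_at(0, 0))]
        det = [Detection(1, box_at(500, 500), 0.9)]
        assert average_precision(det, gt) == pytest.approx(0.0)

    def test_no_ground_truth_flagged(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([Detection(1, box_at(0, 0), 0.9)], [])

    def test_matches_rank_cut_integration_oracle(self, rng):
        """AP equals brute-force integration over every rank cut on a
        20-detection instance."""
        gts, dets = [], []
        gid = 1
        for frame in range(1, 5):
            for _ in range(3):
                b = random_box(rng, span=150, min_size=12, max_size=20)
                gts.append(GTRecord(frame, gid, b))
                gid += 1
        for frame in range(1, 5):
            frame_gts = [g for g in gts if g.frame == frame]
            for k in range(5):
                if k < 3:
                    src = frame_gts[k].box
                    b = src.shifted(float(rng.uniform(-4, 4)), float(rng.uniform(-4, 4)))
                else:
                    b = random_box(rng, span=150, min_size=12, max_size=20)
                dets.append(Detection(frame, b, float(rng.uniform(0.2, 1.0))))
        got = average_precision(dets, gts, 0.5)

        # oracle: independent TP labelling + explicit step-sum over cuts
        order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
        used: set[int] = set()
        labels = []
        for i in order:
            d = dets[i]
            best, best_v = -1, 0.5
            for j, g in enumerate(gts):
                if j in used or g.frame != d.frame:
                    continue
                v = iou(d.box, g.box)
                if v >= best_v and (best < 0 or v > best_v):
                    best, best_v = j, v
            if best >= 0:
                used.add(best)
                labels.append(1)
            else:
                labels.append(0)
        ap = 0.0
        prev_recall = 0.0
        tp = 0
        for k, lab in enumerate(labels, start=1):
            tp += lab
            recall = tp / len(gts)
            ap += (recall - prev_recall) * (tp / k)
            prev_recall = recall
        assert got == pytest.approx(ap, abs=1e-9)

    def test_invariant_to_rank_preserving_rescale_and_frame_order(self, rng):
        gts = [GTRecord(f, f, random_box(rng, span=100)) for f in range(1, 9)]
        dets = [
            Detection(g.frame, g.box.shifted(1.0, 1.0), 0.1 + 0.1 * i)
            for i, g in enumerate(gts)
        ]
        base = average_precision(dets, gts)
        rescaled = [Detection(d.frame, d.box, d.confidence / 2.0) for d in dets]
        assert average_precision(rescaled, gts) == pytest.approx(base)
        shuffled = list(reversed(dets))
        assert average_precision(shuffled, gts) == pytest.approx(base)


class TestClearMot:
    def test_perfect_tracking(self, rng):
        gt = [
            GTRecord(f, i, box_at(50.0 * i, 10.0 * f))
            for f in range(1, 6)
            for i in (1, 2, 3)
        ]
        res = clear_mot(gt, gt)
        assert res.MOTA == 1.0 and res.IDSW == 0 and res.IDF1 == 1.0

    def test_empty_output_gives_zero_mota(self):
        gt = [GTRecord(f, 1, box_at(0, 10.0 * f)) for f in range(1, 6)]
        res = clear_mot([], gt)
        assert res.MOTA == 0.0
        assert res.IDF1 == 0.0

    def test_empty_gt_flagged(self):
        with pytest.raises(UndefinedMetricError):
            clear_mot([], [])

    def test_scripted_mid_sequence_id_swap(self):
        """3 objects, 10 frames; object 3's hypothesis switches identity
        at frame 6.  Hand computation: FN=FP=0, IDSW=1,
        MOTA = 1 - 1/30; IDTP = 10+10+5 = 25 of 30 boxes each side."""
        gt = [
            GTRecord(f, i, box_at(60.0 * i, 5.0 * f))
            for f in range(1, 11)
            for i in (1, 2, 3)
        ]
        hyp = []
        for f in range(1, 11):
            for i in (1, 2, 3):
                hyp_id = i if (i != 3 or f <= 5) else 9
                hyp.append(GTRecord(f, hyp_id, box_at(60.0 * i, 5.0 * f)))
        res = clear_mot(hyp, gt)
        assert res.IDSW == 1
        assert res.MOTA == pytest.approx(1.0 - 1.0 / 30.0)
        assert res.IDTP == 25
        assert res.IDF1 == pytest.approx(2 * 25 / (2 * 25 + 5 + 5))

    def test_carry_over_prefers_previous_hypothesis(self):
        """Two overlapping hypotheses: the GT keeps its old partner even
        when the newcomer overlaps slightly better, so no IDSW."""
        gt = [GTRecord(f, 1, box_at(0, 0, 20)) for f in range(1, 4)]
        hyp = [GTRecord(1, 5, box_at(1, 1, 20))]
        for f in (2, 3):
            hyp.append(GTRecord(f, 5, box_at(1, 1, 20)))
            hyp.append(GTRecord(f, 6, box_at(0.5, 0.5, 20)))
        res = clear_mot(hyp, gt)
        assert res.IDSW == 0

    def test_mota_degrades_with_misses(self, rng):
        gt = [
            GTRecord(f, i, box_at(40.0 * i, 3.0 * f))
            for f in range(1, 21)
            for i in range(1, 6)
        ]
        motas = []
        for drop in (0, 10, 25, 40):
            keep = [g for k, g in enumerate(gt) if k % 100 >= drop]
            motas.append(clear_mot(keep, gt).MOTA)
        assert all(a >= b for a, b in zip(motas, motas[1:]))


class TestIdMetrics:
    def test_perfect(self):
        gt = [GTRecord(f, 1, box_at(0, 2.0 * f)) for f in range(1, 6)]
        idf1, idtp, idfp, idfn = id_metrics(gt, gt)
        assert idf1 == 1.0 and idtp == 5 and idfp == 0 and idfn == 0

    def test_no_output(self):
        gt = [GTRecord(f, 1, box_at(0, 2.0 * f)) for f in range(1, 6)]
        idf1, idtp, idfp, idfn = id_metrics([], gt)
        assert idf1 == 0.0 and idfn == 5

    def test_half_covered_trajectories(self):
        """Each GT trajectory covered half by one hyp ID, half by another
        (no FPs): IDTP = T/2, IDFN = IDFP = T/2, so IDF1 = 1/2."""
        gt = [GTRecord(f, 1, box_at(0, 2.0 * f)) for f in range(1, 11)]
        hyp = [
            GTRecord(f, 1 if f <= 5 else 2, box_at(0, 2.0 * f)) for f in range(1, 11)
        ]
        idf1, idtp, idfp, idfn = id_metrics(hyp, gt)
        assert (idtp, idfp, idfn) == (5, 5, 5)
        assert idf1 == pytest.approx(0.5)

    def test_equals_exhaustive_bijection_optimum(self, rng):
        """IDTP equals brute force over all identity bijections on random
        scenes with <= 4 GT and <= 4 hypothesis identities."""
        for trial in range(15):
            n_g = int(rng.integers(1, 5))
            n_h = int(rng.integers(1, 5))
            gt, hyp = [], []
            for f in range(1, 9):
                for g in range(1, n_g + 1):
                    if rng.uniform() < 0.8:
                        gt.append(GTRecord(f, g, box_at(50.0 * g, 4.0 * f)))
                for h in range(1, n_h + 1):
                    if rng.uniform() < 0.8:
                        src = ((h - 1) % n_g) + 1
                        hyp.append(GTRecord(f, 100 + h, box_at(50.0 * src, 4.0 * f)))
            if not gt:
                continue
            _idf1, idtp, _idfp, _idfn = id_metrics(hyp, gt)

            def overlap(gid, hid):
                gf = {g.frame: g.box for g in gt if g.identity == gid}
                hf = {h.frame: h.box for h in hyp if h.identity == hid}
                return sum(
                    1 for f in gf.keys() & hf.keys() if iou(gf[f], hf[f]) >= 0.5
                )

            g_ids = sorted({g.identity for g in gt})
            h_ids = sorted({h.identity for h in hyp})
            best = 0
            r = min(len(g_ids), len(h_ids))
            for g_sub in itertools.combinations(g_ids, r):
                for h_perm in itertools.permutations(h_ids, r):
                    best = max(best, sum(overlap(g, h) for g, h in zip(g_sub, h_perm)))
            assert idtp == best


class TestErrorRate:
    @pytest.mark.parametrize(
        "count,gt,er3",
        [(222, 229, 3.057), (75, 71, 5.634), (229, 229, 0.0)],
    )
    def test_published_count_pairs(self, count, gt, er3):
        assert round(error_rate(count, gt), 3) == er3

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            error_rate(5, 0)


class TestEvaluateDetections:
    def test_aggregate_consistent_with_per_frame_matches(self, rng):
        gts, dets = [], []
        gid = 1
        for f in range(1, 11):
            for _ in range(4):
                b = random_box(rng, span=200, min_size=12, max_size=20)
                gts.append(GTRecord(f, gid, b))
                gid += 1
                if rng.uniform() < 0.8:
                    dets.append(
                        Detection(f, b.shifted(float(rng.uniform(-2, 2)),
                                               float(rng.uniform(-2, 2))),
                                  float(rng.uniform(0.3, 1.0)))
                    )
            if rng.uniform() < 0.5:
                dets.append(Detection(f, random_box(rng, span=200), 0.5))
        res = evaluate_detections(dets, gts)
        tp = fp = fn = 0
        for f in range(1, 11):
            t, p_, n_ = match_frame(
                [(d.box, d.confidence) for d in dets if d.frame == f],
                [g.box for g in gts if g.frame == f],
            )
            tp, fp, fn = tp + len(t), fp + len(p_), fn + len(n_)
        assert (res.TP, res.FP, res.FN) == (tp, fp, fn)
        assert res.P == pytest.approx(tp / (tp + fp))
        assert res.R == pytest.approx(tp / (tp + fn))
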