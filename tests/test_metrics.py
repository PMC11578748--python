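"""Evaluation metrics against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pytest

from sproutnet.metrics import (
    MatchCounts,
    TimingBreakdown,
    average_precision,
    confusion_matrix,
    evaluate_detections,
    fps,
    match_detections,
    mean_ap,
    pr_curve,
    precision_recall_f1,
)
from sproutnet.model import Detection, GroundTruth


def det(x1, y1, x2, y2, cls=0, score=0.9):
    return Detection(np.array([x1, y1, x2, y2], float), cls, score)


def gt(x1, y1, x2, y2, cls=0):
    return GroundTruth(np.array([x1, y1, x2, y2], float), cls)


class TestPRF1:
    def test_simple_counts(self):
        assert precision_recall_f1(MatchCounts(90, 10, 10)) == \
            pytest.approx((0.9, 0.9, 0.9))

    def test_zero_everything(self):
        assert precision_recall_f1(MatchCounts(0, 0, 0)) == (0, 0, 0)

    def test_f1_equals_harmonic_mean(self, rng):
        for _ in range(1000):
            tp, fp, fn = rng.integers(0, 50, 3)
            p, r, f1 = precision_recall_f1(MatchCounts(int(tp), int(fp), int(fn)))
            if p + r > 0:
                assert f1 == pytest.approx(2 * p * r / (p + r))
            else:
                assert f1 == 0

    def test_published_headline_f1(self):
        """P = 91.6%, R = 94.8% combine to F1 = 93.2% (harmonic mean)."""
        p, r = 0.916, 0.948
        f1 = 2 * p * r / (p + r)
        assert round(100 * f1, 1) == 93.2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MatchCounts(-1, 0, 0)


class TestMatching:
    def test_perfect_matching(self):
        gts = [gt(0, 0, 10, 10), gt(20, 20, 30, 30)]
        dets = [det(0, 0, 10, 10, score=0.9), det(20, 20, 30, 30, score=0.8)]
        counts, flags, order = match_detections(dets, gts, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)
        assert flags.all()

    def test_duplicate_detection(self):
        gts = [gt(0, 0, 10, 10)]
        dets = [det(0, 0, 10, 10, score=0.9), det(0, 0, 10, 10, score=0.8)]
        counts, flags, _ = match_detections(dets, gts, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)
        assert flags.tolist() == [True, False]

    def test_matches_exhaustive_assignment(self, rng):
        """Greedy score-ordered matching equals the best assignment found
        by brute force over all det→gt injections on small cases (same
        TP total; greedy is optimal here because IoU ≥ thr is binary per
        pair and each det claims its best available gt in score order)."""
        for trial in range(50):
            n_d, n_g = (int(v) for v in rng.integers(1, 4, 2))
            dets = [det(*sorted(rng.uniform(0, 20, 2)),
                        *sorted(rng.uniform(0, 20, 2)), score=float(s))
                    for s in rng.uniform(0.1, 1, n_d)]
            dets = [Detection(np.array([d.box[0], d.box[2], d.box[1], d.box[3]]),
                              0, d.score) for d in dets]
            gts = [gt(*sorted(rng.uniform(0, 20, 2)), *sorted(rng.uniform(0, 20, 2)))
                   for _ in range(n_g)]
            gts = [GroundTruth(np.array([g.box[0], g.box[2], g.box[1], g.box[3]]), 0)
                   for g in gts]
            counts, _, _ = match_detections(dets, gts, 0.3)

            from sproutnet.boxes import iou
            best_tp = 0
            for perm in itertools.permutations(range(n_g), min(n_d, n_g)):
                chosen = list(perm)
                for d_subset in itertools.combinations(range(n_d), len(chosen)):
                    tp = sum(iou(dets[di].box, gts[gi].box) >= 0.3
                             for di, gi in zip(d_subset, chosen))
                    best_tp = max(best_tp, tp)
            assert counts.tp == best_tp


class TestAveragePrecision:
    def test_all_tp_full_recall(self):
        assert average_precision(np.array([1, 1, 1], bool),
                                 np.array([0.9, 0.8, 0.7]), 3) == 1.0

    def test_all_fp(self):
        assert average_precision(np.array([0, 0], bool),
                                 np.array([0.9, 0.8]), 2) == 0.0

    def test_worked_three_detection_case(self):
        """Scores (.9,.8,.7), flags (TP,FP,TP), 2 gts: envelope integral =
        0.5·1 + 0.5·(2/3) = 5/6."""
        ap = average_precision(np.array([1, 0, 1], bool),
                               np.array([0.9, 0.8, 0.7]), 2)
        assert ap == pytest.approx(5 / 6, abs=1e-9)

    def test_no_gts_is_zero(self):
        assert average_precision(np.array([0], bool), np.array([0.5]), 0) == 0.0

    def test_invariant_to_monotone_score_transform(self, rng):
        flags = rng.random(30) > 0.5
        scores = rng.random(30)
        a = average_precision(flags, scores, 12)
        b = average_precision(flags, scores ** 3 + 2, 12)
        assert a == pytest.approx(b)

    def test_low_score_fp_never_increases_ap(self, rng):
        flags = rng.random(20) > 0.4
        scores = rng.uniform(0.5, 1, 20)
        base = average_precision(flags, scores, 10)
        worse = average_precision(np.append(flags, False),
                                  np.append(scores, 0.01), 10)
        assert worse <= base + 1e-12

    def test_101_point_close_to_exact(self, rng):
        flags = rng.random(200) > 0.65
        scores = rng.random(200)
        n_gt = int(flags.sum()) + 10   # recall stays within [0, 1]
        exact = average_precision(flags, scores, n_gt)
        interp = average_precision(flags, scores, n_gt, interpolation="101")
        assert abs(exact - interp) < 0.05


class TestPRCurve:
    def test_recall_monotone(self, rng):
        flags = rng.random(50) > 0.5
        scores = rng.random(50)
        p, r = pr_curve(flags, scores, 20)
        assert np.all(np.diff(r) >= -1e-12)
        assert np.all((p >= 0) & (p <= 1))


class TestMeanAP:
    def test_published_class_aps_average(self):
        """Seedling AP 0.975 and weed AP 0.755 average to mAP 0.865."""
        assert mean_ap({"seedling": 0.975, "weed": 0.755}) == \
            pytest.approx(0.865, abs=1e-12)

    def test_single_class_identity(self):
        assert mean_ap({0: 0.42}) == pytest.approx(0.42)

    def test_identical_aps(self):
        assert mean_ap({0: 0.7, 1: 0.7, 2: 0.7}) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_ap({})


class TestConfusionMatrix:
    def test_perfect_detector_identity_block(self):
        gts = [[gt(0, 0, 10, 10, 0), gt(20, 20, 30, 30, 1)]]
        dets = [[det(0, 0, 10, 10, 0), det(20, 20, 30, 30, 1)]]
        m = confusion_matrix(dets, gts, 2)
        np.testing.assert_array_equal(m, [[1, 0, 0], [0, 1, 0], [0, 0, 0]])

    def test_no_detections_all_background(self):
        gts = [[gt(0, 0, 10, 10, 0), gt(20, 20, 30, 30, 1)]]
        m = confusion_matrix([[]], gts, 2)
        np.testing.assert_array_equal(m, [[0, 0, 1], [0, 0, 1], [0, 0, 0]])

    def test_hand_tally_five_objects(self):
        """2 correct seedlings, 1 weed detected as seedling, 1 missed weed,
        1 spurious weed detection."""
        gts = [[gt(0, 0, 10, 10, 0), gt(20, 0, 30, 10, 0),
                gt(40, 0, 50, 10, 1), gt(60, 0, 70, 10, 1)]]
        dets = [[det(0, 0, 10, 10, 0, 0.9), det(20, 0, 30, 10, 0, 0.85),
                 det(40, 0, 50, 10, 0, 0.8), det(80, 0, 90, 10, 1, 0.7)]]
        m = confusion_matrix(dets, gts, 2)
        np.testing.assert_array_equal(m, [[2, 0, 0],
                                          [1, 0, 1],
                                          [0, 1, 0]])

    def test_gt_cells_total_equals_gt_count(self, rng):
        gts = [[gt(*np.sort(rng.uniform(0, 50, 2)), *np.sort(rng.uniform(0, 50, 2)),
                   cls=int(rng.integers(0, 2)))
                for _ in range(rng.integers(0, 5))] for _ in range(6)]
        gts = [[GroundTruth(np.array([g.box[0], g.box[2], g.box[1], g.box[3]]),
                            g.cls) for g in img] for img in gts]
        dets = [[det(*g.box, cls=g.cls, score=0.9) for g in img[:2]] for img in gts]
        m = confusion_matrix(dets, gts, 2)
        n_gt = sum(len(img) for img in gts)
        assert m[:2, :].sum() == n_gt


class TestFPS:
    @pytest.mark.parametrize("t,expected", [
        ((1, 2, 1), 250.0),
        ((0, 10, 0), 100.0),
    ])
    def test_values(self, t, expected):
        assert fps(TimingBreakdown(*t)) == pytest.approx(expected)

    def test_scaling(self):
        assert fps(TimingBreakdown(2, 4, 2)) == \
            pytest.approx(fps(TimingBreakdown(1, 2, 1)) / 2)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fps(TimingBreakdown(0, 0, 0))


class TestEvaluate:
    def test_oracle_detector_perfect_map(self, small_scenes):
        """Replaying ground-truth labels as unit-score detections yields
        mAP 1 at IoU 0.5."""
        from sproutnet.train import records_to_xyxy

        dets_all, gts_all = [], []
        for img, labels in small_scenes:
            boxes, cls = records_to_xyxy(labels, 160)
            gts_all.append([GroundTruth(b, int(c)) for b, c in zip(boxes, cls)])
            dets_all.append([Detection(b, int(c), 1.0)
                             for b, c in zip(boxes, cls)])
        res = evaluate_detections(dets_all, gts_all, 2)
        assert res["map"] == pytest.approx(1.0)

    def test_empty_detector_zero_map(self, small_scenes):
        from sproutnet.train import records_to_xyxy

        gts_all = []
        for img, labels in small_scenes:
            boxes, cls = records_to_xyxy(labels, 160)
            gts_all.append([GroundTruth(b, int(c)) for b, c in zip(boxes, cls)])
        res = evaluate_detections([[] for _ in gts_all], gts_all, 2)
        assert res["map"] == 0.0
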