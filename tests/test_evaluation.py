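"""Precision/recall/AP/mAP/F1 against independent oracles; density strata."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloomdet.boxes import BoundingBox, Detection, LabeledImage
from bloomdet.evaluation import (
    MatchResult,
    average_precision,
    evaluate_detections,
    f1_score,
    match_detections,
    mean_ap,
    precision_recall,
    stratify_by_density,
)


def det(x0, y0, x1, y1, conf, cls="flower", img="i0"):
    return Detection(box=BoundingBox(x0, y0, x1, y1, cls, conf), image_id=img)


def brute_force_ap(tp_flags, n_gt):
    """Independent oracle for all-point-interpolated AP.

    Each true positive at rank i contributes max_{j>=i}(TP_j / j) / n_gt —
    the monotone precision envelope evaluated by brute force.
    """
    precisions = []
    tp = 0
    for i, f in enumerate(tp_flags, 1):
        if f:
            tp += 1
        precisions.append(tp / i)
    total = 0.0
    for i, f in enumerate(tp_flags):
        if f:
            total += max(precisions[i:])
    return total / n_gt if n_gt else 0.0


class TestMatching:
    def test_perfect_detections(self):
        gts = [BoundingBox(0, 0, 10, 10, "flower"), BoundingBox(20, 20, 40, 40, "flower")]
        dets = [det(0, 0, 10, 10, 1.0), det(20, 20, 40, 40, 1.0)]
        m = match_detections(dets, gts)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_no_detections(self):
        gts = [BoundingBox(0, 0, 10, 10, "flower")]
        m = match_detections([], gts)
        assert m.fn == 1 and m.tp == 0

    def test_double_detection_one_tp_one_fp(self):
        gts = [BoundingBox(0, 0, 10, 10, "flower")]
        dets = [det(0, 0, 10, 10, 0.9), det(1, 1, 10, 10, 0.8)]
        m = match_detections(dets, gts)
        assert m.tp_flags == [True, False]

    def test_tp_equals_matched_gt_count(self):
        rng = np.random.default_rng(1)
        gts = [BoundingBox(x, x, x + 10, x + 10, "flower") for x in range(0, 100, 20)]
        dets = [det(x + rng.uniform(-2, 2), x, x + 10, x + 10, float(rng.uniform(0.1, 1)))
                for x in range(0, 100, 10)]
        m = match_detections(dets, gts)
        assert m.tp <= len(gts)
        assert m.tp + m.fn == len(gts)


class TestPrecisionRecall:
    def test_final_point_arithmetic(self):
        m = MatchResult(tp_flags=[True, True, False], n_gt=3)
        pr = precision_recall(m)
        assert pr.final_precision == pytest.approx(2 / 3)
        assert pr.final_recall == pytest.approx(2 / 3)

    def test_zero_detections_convention(self):
        pr = precision_recall(MatchResult(tp_flags=[], n_gt=5))
        assert pr.final_recall == 0.0
        assert pr.final_precision == 1.0  # precision at zero recall

    def test_all_tp_precision_one(self):
        pr = precision_recall(MatchResult(tp_flags=[True] * 4, n_gt=4))
        assert np.allclose(pr.precision, 1.0)

    def test_recall_nondecreasing(self):
        rng = np.random.default_rng(2)
        flags = list(rng.uniform(size=30) < 0.5)
        pr = precision_recall(MatchResult(tp_flags=flags, n_gt=max(1, sum(flags))))
        assert np.all(np.diff(pr.recall) >= 0)


class TestAveragePrecision:
    def test_perfect_detector(self):
        pr = precision_recall(MatchResult(tp_flags=[True] * 5, n_gt=5))
        assert average_precision(pr) == pytest.approx(1.0)

    def test_rectangle_integration_by_hand(self):
        # flags (F, T, T): precision 0, 1/2, 2/3 -> monotone envelope is the
        # constant 2/3 up to recall 2/3, then 0: AP = 2/3 * 2/3 = 4/9
        m = MatchResult(tp_flags=[False, True, True], n_gt=3)
        pr = precision_recall(m)
        assert average_precision(pr) == pytest.approx(4 / 9, abs=1e-12)

    def test_interpolation_uses_envelope(self):
        # flags (T, F, T): the first TP sits at precision 1, the envelope on
        # (1/3, 2/3] is 2/3: AP = 1/3 * 1 + 1/3 * 2/3 = 5/9
        m = MatchResult(tp_flags=[True, False, True], n_gt=3)
        assert average_precision(precision_recall(m)) == pytest.approx(5 / 9)

    def test_empty_with_ground_truth(self):
        assert average_precision(precision_recall(MatchResult([], 3))) == 0.0

    @settings(deadline=None, max_examples=80)
    @given(st.lists(st.booleans(), min_size=1, max_size=12),
           st.integers(1, 12))
    def test_matches_step_integration_oracle(self, flags, extra_gt):
        n_gt = sum(flags) + (extra_gt - 1)
        if n_gt == 0:
            return
        pr = precision_recall(MatchResult(tp_flags=flags, n_gt=n_gt))
        assert average_precision(pr) == pytest.approx(
            brute_force_ap(flags, n_gt), abs=1e-12
        )

    def test_ap_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            flags = list(rng.uniform(size=10) < 0.4)
            n_gt = max(1, sum(flags) + int(rng.integers(0, 5)))
            ap = average_precision(precision_recall(MatchResult(flags, n_gt)))
            assert 0.0 <= ap <= 1.0


class TestAggregates:
    def test_mean_ap(self):
        assert mean_ap([1.0, 0.5]) == pytest.approx(0.75)

    def test_f1_of_equal_pr(self):
        for p in (0.2, 0.5, 0.9):
            assert f1_score(p, p) == pytest.approx(p)

    def test_f1_zero_when_degenerate(self):
        assert f1_score(0.0, 0.0) == 0.0

    def test_f1_two_printed_forms_agree(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            tp, fp, fn = rng.integers(0, 50, 3)
            if tp + fp == 0 or tp + fn == 0:
                continue
            p = tp / (tp + fp)
            r = tp / (tp + fn)
            assert f1_score(p, r) == pytest.approx(2 * tp / (2 * tp + fp + fn),
                                                   abs=1e-12)

    def test_hand_worked_example(self):
        # TP=2, FP=1, FN=1 -> P=R=2/3, F1=2/3
        assert f1_score(2 / 3, 2 / 3) == pytest.approx(2 / 3)


class TestStratification:
    def images_with_counts(self, counts):
        out = []
        for i, n in enumerate(counts):
            boxes = [BoundingBox(j * 3 + 1, 1, j * 3 + 3, 4, "flower")
                     for j in range(n)]
            out.append(LabeledImage(f"s{i}", 400, 400, None, boxes))
        return out

    def test_assignment(self):
        imgs = self.images_with_counts([5, 15, 40])
        strata = stratify_by_density(imgs, (10, 30))
        assert [len(v) for v in strata.values()] == [1, 1, 1]
        assert strata["few"][0].image_id == "s0"

    def test_exhaustive_disjoint(self):
        imgs = self.images_with_counts([0, 3, 10, 11, 30, 31, 99])
        strata = stratify_by_density(imgs, (10, 30))
        ids = [im.image_id for v in strata.values() for im in v]
        assert sorted(ids) == sorted(im.image_id for im in imgs)

    def test_pooled_counts_equal_whole_set(self):
        """Evaluating per stratum then pooling TP/FP/FN matches the whole set."""
        rng = np.random.default_rng(5)
        imgs = self.images_with_counts([4, 12, 35])
        dets = []
        for img in imgs:
            for b in img.boxes:
                if rng.uniform() < 0.7:  # detect most
                    dets.append(det(b.x_min, b.y_min, b.x_max, b.y_max,
                                    float(rng.uniform(0.5, 1)), img=img.image_id))
        whole = match_detections(
            dets, [(im.image_id, b) for im in imgs for b in im.boxes])
        strata = stratify_by_density(imgs, (10, 30))
        tp = fp = fn = 0
        for sub in strata.values():
            ids = {im.image_id for im in sub}
            sub_dets = [d for d in dets if d.image_id in ids]
            m = match_detections(
                sub_dets, [(im.image_id, b) for im in sub for b in im.boxes])
            tp += m.tp
            fp += m.fp
            fn += m.fn
        assert (tp, fp, fn) == (whole.tp, whole.fp, whole.fn)


class TestEndToEnd:
    def test_known_corruption_rates(self):
        """Dropping a fraction d of gts and adding spurious detections yields
        recall ~ 1-d and precision ~ TP/(TP+S)."""
        rng = np.random.default_rng(6)
        imgs = []
        dets = []
        d_rate, n_spurious = 0.3, 60
        n_total = 400
        for i in range(20):
            boxes = []
            for j in range(n_total // 20):
                x = 5 + (j % 5) * 70
                y = 5 + (j // 5) * 70
                b = BoundingBox(x, y, x + 40, y + 40, "flower")
                boxes.append(b)
                if rng.uniform() > d_rate:
                    dets.append(det(x, y, x + 40, y + 40,
                                    float(rng.uniform(0.6, 1.0)), img=f"e{i}"))
            imgs.append(LabeledImage(f"e{i}", 400, 400, None, boxes))
        for _ in range(n_spurious):  # spurious, far from grid alignment
            i = int(rng.integers(0, 20))
            x, y = rng.uniform(300, 350, 2)
            dets.append(det(x, y, x + 20, y + 20, float(rng.uniform(0, 0.5)),
                            img=f"e{i}"))
        m = match_detections(dets, [(im.image_id, b) for im in imgs for b in im.boxes])
        recall = m.tp / m.n_gt
        precision = m.tp / (m.tp + m.fp)
        binom_sd = np.sqrt(d_rate * (1 - d_rate) / n_total)
        assert abs(recall - (1 - d_rate)) < 4 * binom_sd
        assert precision == pytest.approx(m.tp / (m.tp + n_spurious), abs=0.02)

    def test_evaluate_detections_report(self):
        imgs = [LabeledImage("r0", 100, 100, None,
                             [BoundingBox(10, 10, 30, 30, "flower"),
                              BoundingBox(50, 50, 70, 70, "bud")])]
        dets = [det(10, 10, 30, 30, 0.9, "flower", "r0"),
                det(50, 50, 70, 70, 0.8, "bud", "r0")]
        rep = evaluate_detections(dets, imgs)
        assert rep.mAP == pytest.approx(1.0)
        assert rep.per_class_ap == {"bud": 1.0, "flower": 1.0}
        assert rep.mAP == pytest.approx(np.mean(list(rep.per_class_ap.values())))
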