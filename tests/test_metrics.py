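"""Evaluation metrics: matching, P/R/F1, AP envelope, pixel IoU, FPS.

Expected AP values are frozen from a brute-force Riemann-sum oracle over the
precision-recall staircase; matching counts are checked against exhaustive
greedy matching on small IoU tables.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smlsyolo.metrics import (ConfusionCounts, average_precision, box_iou,
                              f1_score, fps, map50, match_instances,
                              pixel_iou, pr_curve, precision_recall_f1)
from smlsyolo.postprocess import PredictionInstance


def brute_force_ap(flags, scores, n_gt, n_points=10001):
    """Riemann sum over the monotone precision envelope."""
    if n_gt == 0 or not flags:
        return 0.0
    order = np.argsort(-np.asarray(scores), kind="stable")
    f = np.asarray(flags, dtype=float)[order]
    tp = np.cumsum(f)
    fp = np.cumsum(1 - f)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    rs = np.linspace(0, 1, n_points)
    ps = np.zeros_like(rs)
    for i, r in enumerate(rs):
        sel = recall >= r
        ps[i] = precision[sel].max() if sel.any() else 0.0
    return float(np.trapezoid(ps, rs))


class TestPrecisionRecallF1:
    @pytest.mark.parametrize("tp,fp,fn,exp", [
        (2, 1, 2, (2 / 3, 0.5, 4 / 7)),
        (0, 0, 0, (0.0, 0.0, 0.0)),
        (5, 0, 0, (1.0, 1.0, 1.0)),
        (0, 3, 2, (0.0, 0.0, 0.0)),
    ])
    def test_closed_forms(self, tp, fp, fn, exp):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        assert (p, r, f1) == pytest.approx(exp)

    def test_reported_box_and_mask_f1_round_to_88(self):
        """F1 computed from the reported box (89.2/86.1) and mask
        (89.9/85.4) precision/recall pairs integer-rounds to 88%."""
        for p, r in [(0.892, 0.861), (0.899, 0.854)]:
            f1 = f1_score(p, r)
            assert round(100 * f1) == 88


class TestAveragePrecision:
    def test_single_tp(self):
        assert average_precision([True], [0.9], 1) == pytest.approx(1.0)

    def test_tp_fp_tp_staircase(self):
        # two GTs, predictions ordered TP, FP, TP:
        # AP = 0.5 * 1 + 0.5 * (2/3) = 0.8333...
        flags, scores = [True, False, True], [0.9, 0.8, 0.7]
        ap = average_precision(flags, scores, 2)
        assert ap == pytest.approx(5 / 6, abs=1e-9)
        assert ap == pytest.approx(brute_force_ap(flags, scores, 2), abs=1e-4)

    def test_all_fp(self):
        assert average_precision([False, False], [0.9, 0.8], 2) == 0.0

    def test_no_gt_returns_zero(self):
        assert average_precision([False], [0.5], 0) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_envelope_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 20))
        n_gt = int(rng.integers(1, 10))
        flags = rng.uniform(size=n) < 0.5
        # cap TPs at the number of ground truths
        flags = [bool(f) and sum(flags[:i]) < n_gt
                 for i, f in enumerate(flags)]
        scores = rng.uniform(size=n).tolist()
        ap = average_precision(flags, scores, n_gt)
        assert ap == pytest.approx(brute_force_ap(flags, scores, n_gt),
                                   abs=1e-4)

    @given(st.lists(st.tuples(st.booleans(),
                              st.floats(0.01, 0.99)), max_size=12),
           st.integers(1, 6))
    def test_monotonicity(self, items, n_gt):
        flags = [f for f, _ in items]
        if sum(flags) > n_gt:
            return
        scores = [s for _, s in items]
        base = average_precision(flags, scores, n_gt)
        # appending a lowest-score FP never increases AP
        worse = average_precision(flags + [False], scores + [0.001], n_gt)
        assert worse <= base + 1e-12
        # prepending a highest-score TP never decreases AP
        if sum(flags) < n_gt:
            better = average_precision([True] + flags, [1.0] + scores, n_gt)
            assert better >= base - 1e-12


class TestMap50:
    @pytest.mark.parametrize("aps,expected", [
        ([0.89], 0.89), ([1.0, 0.0], 0.5), ([0.8, 0.9, 1.0], 0.9)])
    def test_mean(self, aps, expected):
        assert map50(aps) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            map50([])


class TestMatching:
    def _pred(self, box, score, cls=0):
        return PredictionInstance(box=box, score=score, class_id=cls)

    def _gt(self, box, cls=0):
        class G:
            pass
        g = G()
        g.box = box
        g.class_id = cls
        return g

    def test_single_match(self):
        counts, flags, _ = match_instances(
            [self._pred((0, 0, 10, 10), 0.9)],
            [self._gt((0, 0, 10, 14))])  # IoU ~ 0.71 > 0.5
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert flags == [True]

    def test_iou_must_exceed_threshold_strictly(self):
        # IoU exactly 0.5 is NOT a match
        counts, _, _ = match_instances(
            [self._pred((0, 0, 10, 5), 0.9)], [self._gt((0, 0, 10, 10))])
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_one_to_one(self):
        preds = [self._pred((0, 0, 10, 10), 0.9),
                 self._pred((0, 0, 10, 11), 0.8)]
        counts, flags, _ = match_instances(preds, [self._gt((0, 0, 10, 10))])
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)
        assert flags == [True, False]

    def test_against_brute_force_oracle(self):
        """Greedy matcher agrees with an explicit re-implementation on
        exhaustive small configurations."""
        rng = np.random.default_rng(0)
        for _ in range(60):
            n_p, n_g = rng.integers(1, 4), rng.integers(1, 4)
            preds = [self._pred(tuple(sorted(rng.uniform(0, 10, 2))
                                      ) + tuple(sorted(rng.uniform(0, 10, 2))),
                                float(rng.uniform()))
                     for _ in range(n_p)]
            preds = [PredictionInstance(
                box=(p.box[0], p.box[2], p.box[1], p.box[3]),
                score=p.score, class_id=0) for p in preds]
            gts = [self._gt((0, 0, rng.uniform(1, 10), rng.uniform(1, 10)))
                   for _ in range(n_g)]
            counts, _, _ = match_instances(preds, gts)
            # oracle: walk predictions in score order, pick best unmatched
            order = sorted(range(n_p), key=lambda i: -preds[i].score)
            used, tp = set(), 0
            for i in order:
                best, bj = 0.5, -1
                for j in range(n_g):
                    if j in used:
                        continue
                    iou = box_iou(preds[i].box, gts[j].box)
                    if iou > best:
                        best, bj = iou, j
                if bj >= 0:
                    used.add(bj)
                    tp += 1
            assert counts.tp == tp
            assert counts.fp == n_p - tp
            assert counts.fn == n_g - tp
        assert counts.tp + counts.fn == n_g


class TestPixelIoUAndFps:
    def test_pixel_iou_cases(self):
        full = np.ones((10, 10), bool)
        half = full.copy()
        half[:, 5:] = False
        assert pixel_iou(full, full) == 1.0
        assert pixel_iou(~full, full) == 0.0
        assert pixel_iou(half, full) == pytest.approx(0.5)

    def test_pixel_iou_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_iou(np.ones((4, 4)), np.ones((5, 5)))

    @pytest.mark.parametrize("times,expected", [
        ([0.01], 100.0), ([1.0], 1.0), ([0.5, 1.5], 1.0)])
    def test_fps(self, times, expected):
        assert fps(times) == pytest.approx(expected)

    def test_fps_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fps([0.5, 0.0])


class TestPrCurve:
    def test_area_consistency(self, tmp_path):
        flags, scores = [True, False, True], [0.9, 0.8, 0.7]
        points, ap = pr_curve(flags, scores, 2, tmp_path / "pr.png")
        assert ap == pytest.approx(5 / 6, abs=1e-9)
        assert (tmp_path / "pr.png").exists()
        # exported staircase integrates (via the envelope) to the same AP
        assert ap == pytest.approx(brute_force_ap(flags, scores, 2), abs=1e-4)

    def test_single_tp_curve(self):
        points, ap = pr_curve([True], [0.9], 1)
        assert points == [(1.0, 1.0)]
        assert ap == 1.0

    def test_empty(self):
        points, ap = pr_curve([], [], 0)
        assert points == [] and ap == 0.0
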