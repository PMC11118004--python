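"""Mask metrics: IoU conventions, confusion counts, ROC, interval stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glottisqc.metrics import (
    ConfusionCounts,
    ScoredSample,
    classify_iou,
    compute_iou,
    confusion,
    interval_stats,
    regression_metrics,
    roc_sweep,
)
from glottisqc.metrics import roc_auc

from conftest import brute_force_iou, random_mask


def mask_from_pixels(pixels, shape=(4, 4)):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m


class TestComputeIoU:
    def test_identical_nonempty_masks_give_one(self):
        m = mask_from_pixels([(0, 0), (1, 2)])
        assert compute_iou(m, m) == 1.0

    def test_hand_counted_overlap(self):
        gt = mask_from_pixels([(0, 0), (0, 1), (1, 0), (1, 1)])
        cand = mask_from_pixels([(1, 0), (1, 1), (2, 0), (2, 1)])
        assert compute_iou(cand, gt) == pytest.approx(2 / 6)

    def test_empty_mask_conventions(self):
        empty = np.zeros((4, 4), dtype=bool)
        full = np.ones((4, 4), dtype=bool)
        assert compute_iou(empty, empty) == 1.0
        assert compute_iou(full, empty) == 0.0
        assert compute_iou(empty, full) == 0.0

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(3, 3\).*\(4, 4\)"):
            compute_iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    def test_matches_set_based_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a = random_mask(rng, p=rng.uniform(0, 1))
            b = random_mask(rng, p=rng.uniform(0, 1))
            assert compute_iou(a, b) == brute_force_iou(a, b)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask(rng), random_mask(rng)
        assert compute_iou(a, b) == compute_iou(b, a)


class TestClassify:
    @pytest.mark.parametrize(
        "score,t,expected",
        [(0.6, 0.6, "accepted"), (0.59, 0.6, "declined"), (1.0, 0.6, "accepted")],
    )
    def test_threshold_with_equality_accepting(self, score, t, expected):
        assert classify_iou(score, t) == expected

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_iou(0.5, 1.0)


class TestConfusion:
    def test_hand_enumerated_four_cases(self):
        cm = confusion([0.2, 0.7, 0.55, 0.9], [0.1, 0.8, 0.65, 0.3], 0.6)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 1, 1)
        assert cm.accuracy == 0.5
        assert cm.sensitivity == 0.5
        assert cm.specificity == 0.5

    def test_perfect_scores_have_no_errors(self):
        true = [0.1, 0.9, 0.55, 0.61]
        cm = confusion(true, true, 0.6)
        assert cm.fp == 0 and cm.fn == 0

    def test_all_low_scores_on_accepted_truths_are_false_positives(self):
        cm = confusion([0.0] * 5, [0.9] * 5, 0.6)
        assert (cm.tp, cm.tn, cm.fn, cm.fp) == (0, 0, 0, 5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [], 0.6)

    def test_rate_identities_on_arbitrary_counts(self):
        cm = ConfusionCounts(tp=3, fp=2, tn=7, fn=1)
        assert cm.accuracy == (3 + 7) / 13
        assert cm.sensitivity == 3 / 4
        assert cm.specificity == 7 / 9


class TestRegressionMetrics:
    def test_exact_predictions(self):
        assert regression_metrics([0.3, 0.7], [0.3, 0.7]) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        mse, mae = regression_metrics([0.5, 0.5], [0.4, 0.7])
        assert mse == pytest.approx(0.025)
        assert mae == pytest.approx(0.15)

    def test_single_extreme_pair(self):
        assert regression_metrics([1.0], [0.0]) == (1.0, 1.0)


class TestRocSweep:
    def test_oracle_predictor_hits_corner(self):
        rng = np.random.default_rng(1)
        true = rng.uniform(0, 1, 200)
        pts = roc_sweep(true, true, 0.6, [0.6])
        assert pts[0][:2] == (0.0, 1.0)

    def test_extreme_thresholds_close_the_curve(self):
        true = [0.2, 0.9]
        pts = roc_sweep([0.5, 0.5], true, 0.6, [-np.inf, np.inf])
        assert pts[0][:2] == (0.0, 0.0)
        assert pts[1][:2] == (1.0, 1.0)

    def test_rates_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        pred, true = rng.uniform(0, 1, 500), rng.uniform(0, 1, 500)
        pts = roc_sweep(pred, true, 0.6, np.linspace(0, 1, 21))
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert all(np.diff(fpr) >= 0) and all(np.diff(tpr) >= 0)

    def test_single_class_truth_reports_nan_not_zero(self):
        pts = roc_sweep([0.5, 0.5], [0.9, 0.8], 0.6, [0.5])
        assert np.isnan(pts[0][1])  # no positives -> TPR undefined
        assert pts[0][0] == 0.0

    def test_agrees_with_sklearn_roc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        true = rng.uniform(0, 1, 2000)
        pred = np.clip(true + rng.normal(0, 0.2, 2000), 0, 1)
        pts = roc_sweep(pred, true, 0.6, np.linspace(-0.001, 1.001, 400))
        ours = roc_auc(pts)
        # sklearn scores the "failed" class with inverted scores
        ref = roc_auc_score(true < 0.6, -pred)
        assert ours == pytest.approx(ref, abs=0.01)


class TestIntervalStats:
    def test_perfect_predictions(self):
        true = [0.05, 0.4, 0.95]
        rows = interval_stats(true, true, [0, 0.5, 1.0])
        assert all(r["mae"] == 0.0 and r["accuracy"] == 1.0 for r in rows)

    def test_two_bin_hand_example(self):
        rows = interval_stats([0.4, 0.9], [0.2, 0.8], [0, 0.5, 1.0])
        assert rows[0]["mae"] == pytest.approx(0.2)
        assert rows[1]["mae"] == pytest.approx(0.1)

    def test_empty_bin_flagged(self):
        rows = interval_stats([0.9], [0.9], [0, 0.5, 1.0])
        assert rows[0]["count"] == 0 and rows[0]["mae"] is None

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            interval_stats([0.5], [0.5], [0, 0.7, 0.3, 1.0])


class TestScoredSample:
    def test_label_must_match_recomputation(self):
        frame = np.zeros((4, 4))
        gt = mask_from_pixels([(0, 0)])
        with pytest.raises(ValueError, match="recomputed"):
            ScoredSample(frame=frame, gt_mask=gt, candidate_mask=gt, iou=0.5)

    def test_valid_sample_roundtrips_its_label(self):
        frame = np.zeros((4, 4))
        gt = mask_from_pixels([(0, 0), (0, 1)])
        cand = mask_from_pixels([(0, 1), (0, 2)])
        s = ScoredSample(frame=frame, gt_mask=gt, candidate_mask=cand, iou=1 / 3)
        assert s.iou == compute_iou(cand, gt)
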