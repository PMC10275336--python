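import numpy as np
import pytest

import _oracle as oracle
from conftest import random_mask_pair
from fasciseg.metrics import (
    MERGE_SPLIT_IOU,
    SizeClass,
    classify_fascicles,
    dice_coefficient,
    error_breakdown,
    evaluate_stack,
    f1_fascicle,
    fascicle_area_um2,
    iou_matrix,
    label_fascicles,
    pixel_precision_recall,
    pr_curve,
    size_class_of,
)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        t = np.zeros((8, 8), bool)
        p = np.zeros((8, 8), bool)
        t[0, 0] = p[7, 7] = True
        assert dice_coefficient(t, p) == 0.0

    def test_4_4_2_overlap_by_hand(self):
        t = np.zeros((4, 4), bool)
        p = np.zeros((4, 4), bool)
        t[0, 0:4] = True  # |T| = 4
        p[0, 2:4] = p[1, 0:2] = True  # |P| = 4, overlap = 2
        assert dice_coefficient(t, p) == 0.5

    def test_both_empty_convention(self):
        empty = np.zeros((4, 4), bool)
        assert dice_coefficient(empty, empty) == 1.0
        assert pixel_precision_recall(empty, empty) == (1.0, 1.0)

    def test_symmetry(self, rng):
        for _ in range(20):
            t, p = random_mask_pair(rng)
            assert dice_coefficient(t, p) == dice_coefficient(p, t)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_coefficient(np.zeros((4, 4), bool), np.zeros((4, 5), bool))


class TestPrecisionRecall:
    def test_subset_prediction(self):
        t = np.zeros((10, 10), bool)
        t[0:4, 0:4] = True  # 16 px
        p = np.zeros((10, 10), bool)
        p[0:2, 0:4] = True  # 8 px, all inside truth
        assert pixel_precision_recall(t, p) == (1.0, 0.5)

    def test_perfect_and_disjoint(self):
        t = np.zeros((6, 6), bool)
        t[1:3, 1:3] = True
        assert pixel_precision_recall(t, t) == (1.0, 1.0)
        p = np.zeros((6, 6), bool)
        p[4:6, 4:6] = True
        assert pixel_precision_recall(t, p) == (0.0, 0.0)


class TestLabeling:
    def test_diagonal_pixels_one_component_8conn(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert label_fascicles(m, connectivity=8).n_labels == 1
        assert label_fascicles(m, connectivity=4).n_labels == 2

    def test_two_separated_blobs(self):
        m = np.zeros((8, 8), bool)
        m[0:2, 0:2] = True
        m[5:7, 5:7] = True
        lm = label_fascicles(m)
        assert lm.n_labels == 2
        assert lm.labels[0, 0] == 1  # raster order of first pixel
        assert lm.labels[5, 5] == 2

    def test_empty_mask(self):
        assert label_fascicles(np.zeros((4, 4), bool)).n_labels == 0

    def test_matches_bfs_oracle(self, rng):
        for _ in range(30):
            t, _ = random_mask_pair(rng)
            lm = label_fascicles(t)
            comps = oracle.components(t.tolist())
            assert lm.n_labels == len(comps)
            for k, comp in enumerate(comps, start=1):
                got = set(zip(*np.nonzero(lm.labels == k)))
                assert got == comp


class TestIoUMatrix:
    def test_identical_single_fascicle(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        lm = label_fascicles(m)
        assert iou_matrix(lm, lm).tolist() == [[1.0]]

    def test_one_true_fascicle_against_two_partial_components(self):
        # one 8-px true fascicle; two predicted components inside it
        # (3 px and 4 px, separated by a gap): per-pair IoU = |∩| / |∪|
        t = np.zeros((6, 8), bool)
        t[2, 0:8] = True
        pred = np.zeros((6, 8), bool)
        pred[2, 0:3] = True  # ∩ = 3, ∪ = 8 -> 3/8
        pred[2, 4:8] = True  # ∩ = 4, ∪ = 8 -> 4/8
        m = iou_matrix(label_fascicles(t), label_fascicles(pred))
        assert m.shape == (1, 2)
        assert m[0, 0] == pytest.approx(3 / 8)
        assert m[0, 1] == pytest.approx(4 / 8)

    def test_disjoint_all_zero(self):
        t = np.zeros((6, 6), bool)
        t[0, 0] = True
        p = np.zeros((6, 6), bool)
        p[5, 5] = True
        assert (iou_matrix(label_fascicles(t), label_fascicles(p)) == 0).all()

    def test_at_most_one_entry_above_half_per_row_and_column(self, rng):
        for _ in range(50):
            t, p = random_mask_pair(rng)
            m = iou_matrix(label_fascicles(t), label_fascicles(p))
            if m.size:
                assert ((m > 0.5).sum(axis=1) <= 1).all()
                assert ((m > 0.5).sum(axis=0) <= 1).all()

    def test_dice_iou_identity_on_matched_pair(self, rng):
        for _ in range(20):
            yy, xx = np.mgrid[0:32, 0:32]
            cy, cx, r = rng.integers(10, 22), rng.integers(10, 22), rng.integers(4, 8)
            t = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            p = np.roll(t, rng.integers(-2, 3), axis=0)
            m = iou_matrix(label_fascicles(t), label_fascicles(p))
            iou = m[0, 0]
            assert dice_coefficient(t, p) == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


class TestClassify:
    def test_perfect_identity_matrix(self):
        res = classify_fascicles(np.eye(3), t=0.4)
        assert (res.tp, res.fp, res.fn) == (3, 0, 0)
        assert res.split_true_ids == [] and res.merged_pred_ids == []

    def test_split_row(self):
        res = classify_fascicles(np.array([[0.5, 0.5]]), t=0.4)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert res.split_true_ids == [1]

    def test_total_miss(self):
        res = classify_fascicles(np.zeros((2, 1)), t=0.4)
        assert (res.tp, res.fp, res.fn) == (0, 1, 2)

    def test_merge_column(self):
        m = np.array([[0.3], [0.2]])
        res = classify_fascicles(m, t=0.4)
        assert res.merged_pred_ids == [1]
        assert res.tp == 0 and res.fn == 2
        assert res.fp == 1  # column max 0.3 < t

    def test_merge_split_threshold_is_exclusive(self):
        m = np.array([[MERGE_SPLIT_IOU, MERGE_SPLIT_IOU]])
        assert classify_fascicles(m, t=0.4).split_true_ids == []

    def test_conservation_tp_fn(self, rng):
        for _ in range(30):
            t, p = random_mask_pair(rng)
            m = iou_matrix(label_fascicles(t), label_fascicles(p))
            for thr in (0.1, 0.4, 0.7):
                res = classify_fascicles(m, thr)
                assert res.tp + res.fn == m.shape[0]

    def test_unique_partner_above_half(self, rng):
        # for t > 0.5 every TP row has exactly one qualifying column
        for _ in range(30):
            t, p = random_mask_pair(rng)
            m = iou_matrix(label_fascicles(t), label_fascicles(p))
            if m.size == 0:
                continue
            res = classify_fascicles(m, 0.6)
            matched_cols = int((m.max(axis=0) >= 0.6).sum())
            assert res.tp == matched_cols

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="t must"):
            classify_fascicles(np.eye(2), t=0.0)


class TestF1:
    def test_perfect(self):
        assert f1_fascicle(5, 0, 0) == 1.0

    def test_no_true_positives(self):
        assert f1_fascicle(0, 3, 0) == 0.0

    def test_3_1_2_by_hand(self):
        assert f1_fascicle(3, 1, 2) == pytest.approx(3 / 4.5)
        assert f1_fascicle(3, 1, 2) == pytest.approx(0.6667, abs=1e-4)

    def test_all_zero_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="no fascicles"):
            assert f1_fascicle(0, 0, 0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            f1_fascicle(-1, 0, 0)


class TestSizeClasses:
    @pytest.mark.parametrize(
        "area, expected",
        [
            (500_000, SizeClass.LARGE),
            (300_000, SizeClass.LARGE),  # boundary belongs upward
            (299_999, SizeClass.MEDIUM),
            (90_000, SizeClass.MEDIUM),
            (25_000, SizeClass.SMALL),
            (20_000, SizeClass.SMALL),
            (19_999, SizeClass.TINY),
            (1, SizeClass.TINY),
        ],
    )
    def test_binning(self, area, expected):
        assert size_class_of(area) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            size_class_of(0)

    def test_area_from_pixel_count(self):
        m = np.zeros((32, 32), bool)
        m[0:25, 0:10] = True  # 250 px
        lm = label_fascicles(m)
        assert fascicle_area_um2(1, lm, pixel_spacing=10.0) == 25_000.0

    def test_single_pixel_area(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = True
        assert fascicle_area_um2(1, label_fascicles(m), 10.0) == 100.0

    def test_absent_label_rejected(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = True
        with pytest.raises(ValueError, match="label"):
            fascicle_area_um2(2, label_fascicles(m), 10.0)


class TestOracleEquivalence:
    """The package metrics must agree exactly with the brute-force pixel-set
    oracle on randomized instances."""

    def test_pixel_metrics_agree(self, rng):
        for _ in range(50):
            t, p = random_mask_pair(rng)
            assert dice_coefficient(t, p) == oracle.dice(t.tolist(), p.tolist())
            assert pixel_precision_recall(t, p) == oracle.precision_recall(t.tolist(), p.tolist())

    def test_instance_pipeline_agrees(self, rng):
        n_trials = 60
        for _ in range(n_trials):
            t, p = random_mask_pair(rng)
            lm_t, lm_p = label_fascicles(t), label_fascicles(p)
            o_t = oracle.components(t.tolist())
            o_p = oracle.components(p.tolist())
            m = iou_matrix(lm_t, lm_p)
            om = oracle.iou_matrix(o_t, o_p)
            assert m.shape == (len(o_t), len(o_p))
            assert np.allclose(m, np.array(om).reshape(m.shape), atol=0, rtol=0)
            for thr in (0.3, 0.4, 0.6):
                res = classify_fascicles(m, thr)
                ores = oracle.classify(om, thr, n_pred=len(o_p))
                assert (res.tp, res.fp, res.fn) == (ores["tp"], ores["fp"], ores["fn"])
                assert res.split_true_ids == ores["split"]
                assert res.merged_pred_ids == ores["merged"]
                assert res.f1() == oracle.f1(ores["tp"], ores["fp"], ores["fn"])
            for comp in o_t:
                area = len(comp) * 100.0
                assert size_class_of(area).value == oracle.size_class(area)


class TestPRCurve:
    def test_perfect_predictor(self):
        t = np.zeros((3, 16, 16), bool)
        t[:, 4:10, 4:10] = True
        curve = pr_curve(t, t.astype(float))
        assert len(curve.thresholds) == 51
        interior = (curve.thresholds > 0) & (curve.thresholds < 1)
        assert np.allclose(curve.precision[interior], 1.0)
        assert np.allclose(curve.recall[interior], 1.0)
        assert curve.auc == pytest.approx(1.0)

    def test_51_threshold_points_step_002(self, rng):
        t = rng.random((2, 8, 8)) < 0.3
        curve = pr_curve(t, rng.random((2, 8, 8)))
        assert len(curve.thresholds) == 51
        assert np.allclose(np.diff(curve.thresholds), 0.02)

    def test_constant_half_probability_map(self):
        t = np.zeros((1, 10, 10), bool)
        t[0, :5, :] = True  # f = 0.5
        p = np.full((1, 10, 10), 0.5)
        curve = pr_curve(t, p)
        below = curve.thresholds < 0.5
        above = curve.thresholds >= 0.5
        assert np.allclose(curve.recall[below], 1.0)
        assert np.allclose(curve.recall[above], 0.0)
        assert np.allclose(curve.precision[below], 0.5)  # foreground fraction

    def test_optimal_threshold_maximizes_dice(self, rng):
        t = rng.random((2, 16, 16)) < 0.2
        probs = np.clip(t * 0.7 + rng.normal(0, 0.2, t.shape), 0, 1)
        curve = pr_curve(t, probs)
        k = np.argmin(np.abs(curve.thresholds - curve.optimal_threshold))
        assert curve.dice[k] == curve.dice.max()

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pr_curve(np.zeros((0, 4, 4), bool), np.zeros((0, 4, 4)))


class TestErrorBreakdown:
    def _disk(self, size, cy, cx, r):
        yy, xx = np.mgrid[0:size, 0:size]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    def test_perfect_prediction_all_zero(self, rng):
        t, _ = random_mask_pair(rng)
        lm = [label_fascicles(t)]
        report = error_breakdown(lm, lm, pixel_spacing=10.0, t=0.4)
        assert all(v == 0 for kind in report.error_counts.values() for v in kind.values())
        assert all(v == 0.0 for v in report.totals().values())

    def test_two_of_twenty_tiny_missed_is_ten_percent(self):
        size = 64
        truths, preds = [], []
        for k in range(20):
            t = self._disk(size, 20, 20, 4)  # ~50 px -> 5,000 um^2 -> tiny
            p = t.copy() if k >= 2 else np.zeros_like(t)  # miss the first two
            truths.append(label_fascicles(t))
            preds.append(label_fascicles(p))
        report = error_breakdown(truths, preds, pixel_spacing=10.0, t=0.4)
        assert report.true_counts["tiny"] == 20
        assert report.error_counts["missed"]["tiny"] == 2
        assert report.percentage("missed", "tiny") == pytest.approx(10.0)

    def test_missed_plus_detected_partition(self, rng):
        truths, preds = [], []
        for _ in range(10):
            t, p = random_mask_pair(rng)
            truths.append(label_fascicles(t))
            preds.append(label_fascicles(p))
        report = error_breakdown(truths, preds, pixel_spacing=10.0, t=0.4)
        for cls in SizeClass:
            n = report.true_counts[cls.value]
            if n:
                missed = report.error_counts["missed"][cls.value]
                assert 0 <= missed <= n
                detected_pct = 100.0 * (n - missed) / n
                assert report.percentage("missed", cls) + detected_pct == pytest.approx(100.0)

    def test_relabeling_invariance(self, rng):
        t, p = random_mask_pair(rng)
        lm_t, lm_p = label_fascicles(t), label_fascicles(p)
        m = iou_matrix(lm_t, lm_p)
        res = classify_fascicles(m, 0.4)
        perm = rng.permutation(lm_p.n_labels)
        relabeled = np.zeros_like(lm_p.labels)
        for new, old in enumerate(perm, start=1):
            relabeled[lm_p.labels == old + 1] = new
        from fasciseg.metrics import LabelMap

        lm_p2 = LabelMap(labels=relabeled, n_labels=lm_p.n_labels)
        res2 = classify_fascicles(iou_matrix(lm_t, lm_p2), 0.4)
        assert (res.tp, res.fp, res.fn) == (res2.tp, res2.fp, res2.fn)
        assert res.f1() == res2.f1()


class TestEvaluateStack:
    def test_identity_prediction(self, rng):
        truth = np.stack([random_mask_pair(rng)[0] for _ in range(10)])
        report = evaluate_stack(truth, truth, t_values=[0.2, 0.4, 0.8])
        assert report["dice_mean"] == 1.0
        assert all(v == 1.0 for v in report["f1_pooled"].values())

    def test_f1_non_increasing_in_t(self, rng):
        truth = []
        pred = []
        for _ in range(6):
            t, p = random_mask_pair(rng)
            truth.append(t)
            pred.append(p)
        report = evaluate_stack(np.stack(truth), np.stack(pred), t_values=[0.1, 0.3, 0.5, 0.7, 0.9])
        f1s = [report["f1_pooled"][t] for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(f1s, f1s[1:]))

    def test_length_mismatch_rejected(self, rng):
        t = np.zeros((3, 8, 8), bool)
        p = np.zeros((2, 8, 8), bool)
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_stack(t, p)

    def test_summary_percentiles_ordering(self, rng):
        truth, pred = [], []
        for _ in range(8):
            t, p = random_mask_pair(rng)
            truth.append(t)
            pred.append(p)
        report = evaluate_stack(np.stack(truth), np.stack(pred))
        assert report["dice_p5"] <= report["dice_mean"] <= report["dice_p95"] + 1e-12


class TestReportOutputs:
    def test_save_and_plot_report(self, tmp_path, rng):
        from fasciseg.metrics import plot_report, save_report

        truth = np.stack([random_mask_pair(rng)[0] for _ in range(4)])
        pred = np.stack([random_mask_pair(rng)[1] for _ in range(4)])
        report = evaluate_stack(truth, pred, t_values=[0.2, 0.4])
        save_report(report, tmp_path)
        assert (tmp_path / "per_slice.csv").exists()
        assert (tmp_path / "summary.json").exists()
        curve = pr_curve(truth, rng.random(truth.shape))
        written = plot_report(report, tmp_path, pr=curve)
        assert len(written) == 4
        assert all(p.exists() and p.stat().st_size > 0 for p in written)
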