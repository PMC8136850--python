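"""Unit, oracle and property tests for the segmentation metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from fioseg import (
    ConfusionCounts,
    aggregate_tables,
    boundary_f1,
    class_iou,
    confusion_counts,
    evaluate_image,
    evaluate_set,
    global_accuracy,
    load_reference_table,
    metrics_table,
    pixel_f1,
    read_mask,
    round_half_up,
    write_mask,
)
from fioseg.metrics import boundary_pixels

from conftest import random_mask


# --- independent brute-force oracles ---------------------------------------

def brute_confusion(pred, truth):
    tp = tn = fp = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j] == 2, truth[i, j] == 2
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def brute_boundary(mask, cls):
    h, w = mask.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] != cls:
                continue
            edge = i in (0, h - 1) or j in (0, w - 1)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < h and 0 <= jj < w and mask[ii, jj] != cls:
                    edge = True
            if edge:
                pts.append((i, j))
    return pts


def brute_boundary_f1(pred, truth, cls, tol):
    bp, bt = brute_boundary(pred, cls), brute_boundary(truth, cls)
    if not bp and not bt:
        return math.nan
    if not bp or not bt:
        return 0.0

    def hits(src, dst):
        n = 0
        for a in src:
            d = min(math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2) for b in dst)
            if d <= tol:
                n += 1
        return n

    precision = hits(bp, bt) / len(bp)
    recall = hits(bt, bp) / len(bt)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# --- confusion counts and scalar metrics ------------------------------------

HAND_TRUTH = np.array([[2, 2, 2], [1, 1, 1], [1, 1, 1]])  # tumor = top row
HAND_PRED = np.array([[2, 1, 1], [2, 1, 1], [2, 1, 1]])   # tumor = left column


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.ones((4, 4), int)
        truth.flat[:5] = 2
        c = confusion_counts(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 11, 0, 0)

    def test_empty_prediction(self):
        truth = np.ones((4, 4), int)
        truth.flat[:5] = 2
        c = confusion_counts(np.ones((4, 4), int), truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 11, 0, 5)

    def test_hand_drawn_pair(self):
        c = confusion_counts(HAND_PRED, HAND_TRUTH)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 2, 2, 4)

    def test_shape_mismatch_and_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.ones((2, 2), int), np.ones((3, 3), int))
        with pytest.raises(ValueError, match="labels"):
            confusion_counts(np.full((2, 2), 7), np.ones((2, 2), int))

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(50):
            h, w = rng.integers(1, 13, size=2)
            pred, truth = random_mask(rng, h, w), random_mask(rng, h, w)
            c, o = confusion_counts(pred, truth), brute_confusion(pred, truth)
            assert c == o
            assert c.total == h * w


class TestScalarMetrics:
    def test_global_accuracy_values(self):
        assert global_accuracy(ConfusionCounts(5, 11, 0, 0)) == 1.0
        assert global_accuracy(ConfusionCounts(1, 4, 2, 2)) == pytest.approx(5 / 9)
        assert global_accuracy(ConfusionCounts(0, 0, 3, 3)) == 0.0
        with pytest.raises(ValueError):
            global_accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_class_iou_values(self):
        c = confusion_counts(HAND_PRED, HAND_TRUTH)
        assert class_iou(c, 2) == pytest.approx(0.2)
        assert class_iou(c, 1) == pytest.approx(4 / 8)
        assert math.isnan(class_iou(ConfusionCounts(0, 9, 0, 0), 2))
        assert class_iou(ConfusionCounts(0, 3, 2, 2), 2) == 0.0

    def test_pixel_f1_is_dice(self):
        c = confusion_counts(HAND_PRED, HAND_TRUTH)
        # tp=1, fp=2, fn=2 -> 2*1/(2*1+2+2) = 1/3
        assert pixel_f1(c, 2) == pytest.approx(1 / 3)

    def test_dice_jaccard_identity_on_random_tables(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            for cls in (1, 2):
                iou, f1 = class_iou(c, cls), pixel_f1(c, cls)
                if math.isnan(iou):
                    assert math.isnan(f1)
                else:
                    assert f1 == pytest.approx(2 * iou / (1 + iou))

    def test_label_swap_symmetry(self, rng):
        pred, truth = random_mask(rng, 8, 8), random_mask(rng, 8, 8)
        c = confusion_counts(pred, truth)
        cs = confusion_counts(3 - pred, 3 - truth)
        assert global_accuracy(c) == global_accuracy(cs)
        assert class_iou(c, 2) == class_iou(cs, 1)
        assert pixel_f1(c, 1) == pixel_f1(cs, 2)


class TestBoundaryF1:
    def test_identical_masks_score_one(self, rng):
        mask = random_mask(rng, 10, 10, structured=True)
        for tol in (0, 1, 3):
            assert boundary_f1(mask, mask, 2, tol) == 1.0

    def test_one_sided_empty_boundary_scores_zero(self):
        truth = np.ones((6, 6), int)
        truth[2:4, 2:4] = 2
        assert boundary_f1(np.ones((6, 6), int), truth, 2, 1) == 0.0

    def test_both_empty_is_absent(self):
        ones = np.ones((5, 5), int)
        assert math.isnan(boundary_f1(ones, ones, 2, 1))

    def test_shifted_square_matches_brute_force(self):
        truth = np.ones((10, 10), int)
        truth[2:6, 2:6] = 2
        pred = np.ones((10, 10), int)
        pred[2:6, 3:7] = 2
        got = boundary_f1(pred, truth, 2, tolerance=1)
        assert got == brute_boundary_f1(pred, truth, 2, 1)

    def test_matches_brute_force_on_random_masks(self, rng):
        for k in range(60):
            h, w = rng.integers(2, 13, size=2)
            pred = random_mask(rng, h, w, structured=k % 2 == 0)
            truth = random_mask(rng, h, w, structured=k % 3 == 0)
            tol = float(rng.choice([0, 1, 1.5, 2]))
            for cls in (1, 2):
                got = boundary_f1(pred, truth, cls, tol)
                want = brute_boundary_f1(pred, truth, cls, tol)
                assert got == want or (math.isnan(got) and math.isnan(want))

    def test_monotone_in_tolerance(self, rng):
        pred = random_mask(rng, 12, 12, structured=True)
        truth = random_mask(rng, 12, 12, structured=True)
        scores = [boundary_f1(pred, truth, 2, t) for t in (0, 1, 2, 4, 8)]
        scores = [s for s in scores if not math.isnan(s)]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_boundary_includes_image_border(self):
        mask = np.full((4, 4), 2)
        b = boundary_pixels(mask, 2)
        assert b[0].all() and b[-1].all() and b[:, 0].all() and b[:, -1].all()
        assert not b[1:3, 1:3].any()


class TestEvaluate:
    def test_perfect_pair_all_ones(self):
        truth = np.ones((8, 8), int)
        truth[2:5, 2:5] = 2
        m = evaluate_image(truth, truth)
        assert m.global_accuracy == 1.0 and m.mean_iou == 1.0 and m.mean_bf == 1.0

    def test_hand_drawn_pair_metrics(self):
        m = evaluate_image(HAND_PRED, HAND_TRUTH)
        assert m.global_accuracy == pytest.approx(5 / 9)
        assert m.iou_per_class[2] == pytest.approx(0.2)
        assert m.iou_per_class[1] == pytest.approx(0.5)
        assert m.mean_iou == pytest.approx(0.35)

    def test_all_normal_prediction_scores_zero_for_tumor(self):
        truth = np.ones((8, 8), int)
        truth[2:5, 2:5] = 2
        m = evaluate_image(np.ones((8, 8), int), truth)
        assert m.iou_per_class[2] == 0.0
        assert m.bf_per_class[2] == 0.0

    def test_set_accumulates_pixels_for_global_accuracy(self):
        truth = np.ones((4, 4), int)
        truth[:2] = 2
        wrong = 3 - truth
        m = evaluate_set([(truth, truth), (wrong, truth)])
        assert m.global_accuracy == 0.5

    def test_singleton_set_equals_single_image(self, rng):
        pred = random_mask(rng, 9, 9, structured=True)
        truth = random_mask(rng, 9, 9, structured=True)
        single, as_set = evaluate_image(pred, truth), evaluate_set([(pred, truth)])
        assert as_set.global_accuracy == single.global_accuracy
        assert as_set.mean_iou == pytest.approx(single.mean_iou)
        assert as_set.mean_bf == pytest.approx(single.mean_bf)

    def test_dataset_iou_averaging_mode(self):
        truth = np.ones((4, 4), int)
        truth[:1] = 2
        pred = np.ones((4, 4), int)
        pred[:2] = 2
        m_img = evaluate_set([(pred, truth), (truth, truth)], iou_averaging="image")
        m_ds = evaluate_set([(pred, truth), (truth, truth)], iou_averaging="dataset")
        assert m_img.mean_iou != m_ds.mean_iou

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_set([])


class TestAggregateTables:
    def test_known_cross_table_cell(self):
        t3 = aggregate_tables([load_reference_table("t1"), load_reference_table("t2")])
        assert t3.loc["DeepLabV3+-ResNet50", ("Global Accuracy", "After")] == 96.15

    def test_single_table_is_identity_before_average_row(self):
        t1 = load_reference_table("t1")
        agg = aggregate_tables([t1])
        pd.testing.assert_frame_equal(agg.drop(index="Average"), t1)

    def test_duplicate_tables_average_to_themselves(self):
        t1 = load_reference_table("t1")
        agg = aggregate_tables([t1, t1, t1])
        pd.testing.assert_frame_equal(agg.drop(index="Average"), t1)

    def test_order_invariant(self):
        t1, t2 = load_reference_table("t1"), load_reference_table("t2")
        pd.testing.assert_frame_equal(
            aggregate_tables([t1, t2]), aggregate_tables([t2, t1])
        )

    def test_average_row_is_column_mean_of_model_rows(self):
        from decimal import ROUND_HALF_UP, Decimal

        agg = aggregate_tables([load_reference_table("t1"), load_reference_table("t2")])
        body = agg.drop(index="Average")
        for col in agg.columns:
            want = (sum(Decimal(repr(v)) for v in body[col]) / Decimal(len(body))).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
            assert agg.loc["Average", col] == float(want)

    def test_mismatched_rows_rejected(self):
        t1 = load_reference_table("t1")
        t2 = load_reference_table("t2").iloc[:4]
        with pytest.raises(ValueError):
            aggregate_tables([t1, t2])

    def test_half_up_rounding(self):
        assert round_half_up(87.085) == 87.09
        assert round_half_up(96.145) == 96.15
        assert round_half_up(1.004) == 1.00

    def test_metrics_table_builder_orders_columns(self):
        rows = {"m": {("Mean BF", "After"): 1.0, ("Global Accuracy", "Before"): 2.0}}
        df = metrics_table(rows)
        assert list(df.columns) == [("Global Accuracy", "Before"), ("Mean BF", "After")]


class TestMaskIO:
    def test_round_trip_preserves_labels(self, rng, tmp_path):
        mask = random_mask(rng, 16, 16, structured=True)
        path = tmp_path / "m.png"
        write_mask(path, mask)
        assert (read_mask(path) == mask).all()

    def test_binary_mapping(self, tmp_path):
        from PIL import Image

        arr = np.zeros((4, 4), np.uint8)
        arr[1:3, 1:3] = 255
        Image.fromarray(arr, mode="L").save(tmp_path / "b.png")
        mask = read_mask(tmp_path / "b.png", mapping="binary")
        assert set(np.unique(mask)) == {1, 2}
        assert (mask[1:3, 1:3] == 2).all()

    def test_stray_label_rejected_with_filename(self, tmp_path):
        from PIL import Image

        arr = np.full((4, 4), 7, np.uint8)
        Image.fromarray(arr, mode="L").save(tmp_path / "bad.png")
        with pytest.raises(ValueError, match="bad.png"):
            read_mask(tmp_path / "bad.png")
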