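"""Mask metrics, the detection rule, and dataset-level evaluation."""

import math

import numpy as np
import pytest

from pdeseray import (ConfusionCounts, binarize, classification_metrics,
                      detect, evaluate_dataset, iou_to_dsc,
                      segmentation_metrics)
from pdeseray.metrics import resize_mask_nearest

RNG = np.random.default_rng(7)


class TestBinarize:
    def test_below_threshold_is_zero(self):
        assert binarize(np.full((4, 4), 0.4)).sum() == 0

    def test_threshold_is_inclusive(self):
        assert binarize(np.array([[0.5]]))[0, 0] == 1
        assert binarize(np.array([[0.4999]]))[0, 0] == 0

    def test_matches_elementwise_bruteforce(self):
        probs = RNG.random((32, 32))
        expected = np.array([[1 if v >= 0.5 else 0 for v in row]
                             for row in probs])
        np.testing.assert_array_equal(binarize(probs), expected)

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), threshold=1.5)

    def test_out_of_range_probabilities_raise(self):
        with pytest.raises(ValueError):
            binarize(np.full((2, 2), 1.2))


class TestDetect:
    def test_exactly_at_threshold_is_positive(self):
        mask = np.zeros((512, 512), dtype=np.uint8)
        mask.ravel()[:3500] = 1
        assert detect(mask) is True

    def test_one_below_threshold_is_negative(self):
        mask = np.zeros((512, 512), dtype=np.uint8)
        mask.ravel()[:3499] = 1
        assert detect(mask) is False

    def test_all_zero_is_negative(self):
        assert detect(np.zeros((512, 512), dtype=np.uint8)) is False

    def test_threshold_fraction_matches_printed_percentage(self):
        assert round(3500 / 512 ** 2 * 100, 2) == 1.34

    def test_monotone_in_activated_pixels(self):
        mask = np.zeros((512, 512), dtype=np.uint8)
        mask.ravel()[:3500] = 1
        assert detect(mask)
        mask.ravel()[3500:5000] = 1
        assert detect(mask)  # adding pixels never flips positive->negative

    def test_other_sizes_resized_first(self):
        assert detect(np.ones((64, 64), dtype=np.uint8)) is True
        assert detect(np.zeros((64, 64), dtype=np.uint8)) is False

    def test_non_binary_input_raises(self):
        with pytest.raises(ValueError):
            detect(np.full((512, 512), 0.7))

    def test_nearest_resize_preserves_binarity(self):
        mask = (RNG.random((100, 100)) < 0.3).astype(np.uint8)
        out = resize_mask_nearest(mask, 512)
        assert set(np.unique(out)) <= {0, 1}
        assert out.shape == (512, 512)


class TestSegmentationMetrics:
    def test_hand_worked_overlap(self):
        pred = np.zeros((4, 4), dtype=np.uint8)
        truth = np.zeros((4, 4), dtype=np.uint8)
        pred.ravel()[:4] = 1          # |X| = 4
        truth.ravel()[1:7] = 1        # |Y| = 6, overlap = 3
        dsc, iou = segmentation_metrics(pred, truth)
        assert dsc == pytest.approx(0.6)
        assert iou == pytest.approx(3 / 7)

    def test_identical_nonempty_masks_score_one(self):
        m = (RNG.random((16, 16)) < 0.4).astype(np.uint8)
        assert segmentation_metrics(m, m) == (1.0, 1.0)

    def test_both_empty_convention(self):
        z = np.zeros((8, 8), dtype=np.uint8)
        assert segmentation_metrics(z, z) == (1.0, 1.0)

    def test_one_empty_scores_zero(self):
        z = np.zeros((8, 8), dtype=np.uint8)
        o = np.ones((8, 8), dtype=np.uint8)
        assert segmentation_metrics(z, o) == (0.0, 0.0)
        assert segmentation_metrics(o, z) == (0.0, 0.0)

    def test_dsc_iou_identity_on_random_pairs(self):
        for _ in range(50):
            a = (RNG.random((12, 12)) < 0.4).astype(np.uint8)
            b = (RNG.random((12, 12)) < 0.4).astype(np.uint8)
            dsc, iou = segmentation_metrics(a, b)
            assert dsc >= iou
            assert dsc == pytest.approx(iou_to_dsc(iou), abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((2, 2), dtype=np.uint8),
                                 np.zeros((3, 3), dtype=np.uint8))


class TestIouToDsc:
    def test_printed_pair(self):
        assert iou_to_dsc(0.882) == pytest.approx(0.937, abs=5e-4)

    @pytest.mark.parametrize("iou,dsc", [(0.0, 0.0), (1.0, 1.0)])
    def test_endpoints(self, iou, dsc):
        assert iou_to_dsc(iou) == dsc

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            iou_to_dsc(1.2)


class TestClassificationMetrics:
    def test_hand_worked_counts(self):
        m = classification_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=6))
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(6 / 7)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["f2"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_f2_matches_weighted_fbeta_bruteforce(self):
        for _ in range(50):
            tp, fp, fn, tn = RNG.integers(1, 30, size=4)
            m = classification_metrics(ConfusionCounts(int(tp), int(fp),
                                                       int(fn), int(tn)))
            prec, rec = tp / (tp + fp), tp / (tp + fn)
            fbeta = (1 + 4) * prec * rec / (4 * prec + rec)
            assert m["f2"] == pytest.approx(fbeta, abs=1e-12)

    def test_zero_denominators_are_nan_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert math.isnan(m["sensitivity"])
        assert m["specificity"] == 1.0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(tp=-1))


class TestEvaluateDataset:
    @staticmethod
    def _mask(frac, size=64):
        m = np.zeros((size, size), dtype=np.uint8)
        m.ravel()[:int(frac * size * size)] = 1
        return m

    def test_perfect_predictions(self):
        truths = [self._mask(0.1), self._mask(0.0), self._mask(0.3)]
        probs = [t.astype(float) for t in truths]
        rep = evaluate_dataset(probs, truths)
        assert rep.mdsc == rep.miou == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_report_equals_hand_computed_means(self):
        # image 1: |X|=4, |Y|=6, overlap 3 -> DSC 0.6, IoU 3/7
        pred1 = np.zeros((4, 4)); pred1.ravel()[:4] = 1
        truth1 = np.zeros((4, 4), dtype=np.uint8); truth1.ravel()[1:7] = 1
        # image 2: identical nonempty masks -> (1, 1)
        truth2 = np.ones((4, 4), dtype=np.uint8)
        rep = evaluate_dataset([pred1, truth2.astype(float)], [truth1, truth2])
        assert rep.mdsc == pytest.approx((0.6 + 1.0) / 2)
        assert rep.miou == pytest.approx((3 / 7 + 1.0) / 2)
        assert rep.n_images == 2

    def test_order_invariance(self):
        probs = [RNG.random((32, 32)) for _ in range(6)]
        truths = [(RNG.random((32, 32)) < 0.2).astype(np.uint8)
                  for _ in range(6)]
        a = evaluate_dataset(probs, truths)
        b = evaluate_dataset(probs[::-1], truths[::-1])
        assert a.mdsc == pytest.approx(b.mdsc)
        assert a.confusion == b.confusion

    def test_all_negative_truths_with_empty_predictions(self):
        z = np.zeros((64, 64))
        rep = evaluate_dataset([z] * 4, [z.astype(np.uint8)] * 4)
        assert rep.specificity == 1.0
        assert math.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined

    def test_ground_truth_label_ignores_pixel_count_rule(self):
        """A truth mask with a single pixel counts as a positive image."""
        truth = np.zeros((64, 64), dtype=np.uint8)
        truth[0, 0] = 1
        rep = evaluate_dataset([np.zeros((64, 64))], [truth])
        assert rep.confusion.fn == 1

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            evaluate_dataset([], [])
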