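import numpy as np
import pytest

from pituseg.evaluation import (
    averaged_roc,
    classification_metrics,
    confusion_counts,
    dice_iou,
    evaluate_test_set,
)
from pituseg.roi import PatchSpec, extract_patch


def _pair_with_overlap(shape=(8, 8, 8)):
    """pred has 6 foreground, truth 4, overlap 3."""
    pred = np.zeros(shape, dtype=np.uint8)
    truth = np.zeros(shape, dtype=np.uint8)
    pred.flat[:6] = 1
    truth.flat[3:7] = 1
    return pred, truth


class TestConfusionCounts:
    def test_perfect_prediction(self):
        truth = np.zeros((32, 32, 32), dtype=np.uint8)
        truth.flat[:4] = 1
        assert confusion_counts(truth, truth) == (4, 0, 0, 32**3 - 4)

    def test_all_negative_prediction(self):
        truth = np.zeros((8, 8, 8), dtype=np.uint8)
        truth.flat[:6] = 1
        tp, fp, fn, tn = confusion_counts(np.zeros_like(truth), truth)
        assert (tp, fn) == (0, 6)
        assert tp + fp + fn + tn == truth.size

    def test_partial_overlap_brute_force(self):
        pred, truth = _pair_with_overlap()
        tp, fp, fn, tn = confusion_counts(pred, truth)
        assert (tp, fp, fn) == (3, 3, 1)
        assert tn == pred.size - 7

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestDiceIoU:
    def test_identical_masks(self, rng):
        m = (rng.uniform(size=(8, 8, 8)) > 0.5).astype(np.uint8)
        assert dice_iou(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dice_iou(a, b) == (0.0, 0.0)

    def test_set_count_oracle(self):
        pred, truth = _pair_with_overlap()
        dice, iou = dice_iou(pred, truth)
        assert dice == pytest.approx(0.6)
        assert iou == pytest.approx(3 / 7)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4, 4), dtype=np.uint8)
        assert dice_iou(z, z) == (1.0, 1.0)

    def test_dice_iou_identity_random_pairs(self, rng):
        for _ in range(100):
            a = (rng.uniform(size=(6, 6, 6)) > 0.4).astype(np.uint8)
            b = (rng.uniform(size=(6, 6, 6)) > 0.4).astype(np.uint8)
            dice, iou = dice_iou(a, b)
            assert dice == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


class TestClassificationMetrics:
    def test_f1_from_printed_precision_recall(self):
        """Precision 0.87 and recall 0.91 determine F1 = 0.89 (2 dp)."""
        tp = 8700 * 91
        fp = tp * 13 / 87  # precision 0.87
        fn = tp * 9 / 91  # recall 0.91
        m = classification_metrics((tp, round(fp), round(fn), 10**6))
        assert m["precision"] == pytest.approx(0.87, abs=1e-4)
        assert m["recall"] == pytest.approx(0.91, abs=1e-4)
        assert m["f1"] == pytest.approx(2 * 0.87 * 0.91 / (0.87 + 0.91), abs=1e-4)
        assert round(m["f1"], 2) == 0.89

    def test_perfect_prediction(self):
        m = classification_metrics((10, 0, 0, 90))
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == (1, 1, 1, 1)

    def test_arithmetic_example(self):
        m = classification_metrics((3, 3, 1, 93))
        assert m["accuracy"] == pytest.approx(0.96)
        assert m["precision"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.6)

    def test_undefined_ratios_flagged(self):
        m = classification_metrics((0, 0, 0, 100))
        assert m["precision"] == 0.0 and m["recall"] == 0.0
        assert {"precision", "recall", "f1"} <= set(m["undefined"])

    def test_f1_equals_dice_identity(self, rng):
        """F1 from confusion counts equals DICE from the same counts."""
        for _ in range(50):
            a = (rng.uniform(size=(6, 6, 6)) > 0.4).astype(np.uint8)
            b = (rng.uniform(size=(6, 6, 6)) > 0.4).astype(np.uint8)
            counts = confusion_counts(a, b)
            if counts[0] + counts[1] + counts[2] == 0:
                continue
            dice, _ = dice_iou(a, b)
            assert classification_metrics(counts)["f1"] == pytest.approx(dice, abs=1e-12)


class TestAveragedRoc:
    def test_perfect_probabilities(self):
        truth = np.zeros((6, 6, 6))
        truth.flat[:9] = 1
        _, _, area = averaged_roc([(truth.astype(float), truth)])
        assert area == pytest.approx(1.0)

    def test_uninformative_probabilities(self, rng):
        """Probabilities independent of truth give area ~ 0.5."""
        subjects = []
        for _ in range(10):
            truth = (rng.uniform(size=(16, 16, 16)) > 0.9).astype(int)
            subjects.append((rng.uniform(size=(16, 16, 16)), truth))
        _, _, area = averaged_roc(subjects)
        assert area == pytest.approx(0.5, abs=0.05)

    def test_single_subject_is_own_curve(self, rng):
        truth = (rng.uniform(size=(8, 8, 8)) > 0.8).astype(int)
        probs = rng.uniform(size=(8, 8, 8))
        grid, tpr1, area1 = averaged_roc([(probs, truth)])
        _, tpr2, area2 = averaged_roc([(probs, truth), (probs, truth)])
        np.testing.assert_allclose(tpr1, tpr2)
        assert area1 == area2

    def test_monotone_transform_invariance(self, rng):
        truth = (rng.uniform(size=(8, 8, 8)) > 0.8).astype(int)
        probs = rng.uniform(size=(8, 8, 8))
        _, _, a1 = averaged_roc([(probs, truth)])
        _, _, a2 = averaged_roc([(probs**3, truth)])
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_subject_skipped_with_warning(self, rng):
        good = ((rng.uniform(size=(4, 4, 4))), (rng.uniform(size=(4, 4, 4)) > 0.5).astype(int))
        bad = (rng.uniform(size=(4, 4, 4)), np.zeros((4, 4, 4), dtype=int))
        with pytest.warns(UserWarning, match="single-class"):
            _, _, area = averaged_roc([good, bad])
        assert 0.0 <= area <= 1.0


class _OracleModel:
    """Stand-in model that predicts the ground truth exactly."""

    threshold = 0.5

    def __init__(self, spec, pairs):
        self._lookup = [extract_patch(m, spec).astype(np.float32) for _, m in pairs]
        self._i = 0

    def predict_proba(self, X):
        out = self._lookup[self._i][None]
        self._i += 1
        return out


class _ZeroModel:
    threshold = 0.5

    def predict_proba(self, X):
        return np.zeros_like(np.asarray(X, dtype=np.float32))


class TestEvaluateTestSet:
    def test_oracle_model_scores_one(self, small_cohort):
        pairs = [(s.volume, s.mask) for s in small_cohort[:3]]
        spec = PatchSpec(center=(32, 34, 33), size=32)
        report = evaluate_test_set(_OracleModel(spec, pairs), pairs, spec)
        for key in ("dice", "iou", "accuracy", "precision", "recall", "f1"):
            assert report.averaged[key] == pytest.approx(1.0)
        assert report.roc_area == pytest.approx(1.0)

    def test_constant_zero_model_has_zero_recall(self, small_cohort):
        pairs = [(s.volume, s.mask) for s in small_cohort[:2]]
        spec = PatchSpec(center=(32, 34, 33), size=32)
        report = evaluate_test_set(_ZeroModel(), pairs, spec, with_roc=False)
        assert report.averaged["recall"] == 0.0
        assert report.averaged["dice"] == 0.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_test_set(_ZeroModel(), [], PatchSpec((16, 16, 16)))
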