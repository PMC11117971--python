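"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest

from murss.metrics import (
    bootstrap_ci,
    class_iou,
    confusion_matrix,
    evaluate_with_rejection,
    mean_iou,
    pixel_accuracy,
)

# ---------------------------------------------------------------------------
# Independent oracles (loops and explicit cell-role bookkeeping; no shared
# code with the implementation)
# ---------------------------------------------------------------------------

def oracle_confusion(pred, truth, accept):
    cm = np.zeros((3, 3), dtype=int)
    for p, t, a in zip(np.ravel(pred), np.ravel(truth), np.ravel(accept)):
        if t != 255 and a:
            cm[t][p] += 1
    return cm


def oracle_iou(cm, k, paper_mode):
    tp = fp = fn = 0
    for t in range(3):
        for p in range(3):
            if t == p == k:
                tp += cm[t][p]
            elif p == k:
                fp += cm[t][p]
            elif t == p:
                pass  # other class correct: true negative for k
            elif paper_mode:
                fn += cm[t][p]  # any remaining misclassification
            elif t == k:
                fn += cm[t][p]  # standard: only missed truth-k pixels
    return 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)


FOUR_PIXEL = dict(
    truth=np.array([0, 0, 1, 2]),  # B B D I
    pred=np.array([0, 1, 1, 2]),  # B D D I
)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([0, 1, 2, 1, 0])
        cm = confusion_matrix(y, y)
        assert np.trace(cm) == 5 and cm.sum() == 5

    def test_four_pixel_worked_example(self):
        cm = confusion_matrix(FOUR_PIXEL["pred"], FOUR_PIXEL["truth"])
        assert cm.tolist() == [[1, 1, 0], [0, 1, 0], [0, 0, 1]]

    def test_nothing_accepted_gives_empty_matrix(self):
        cm = confusion_matrix(
            FOUR_PIXEL["pred"], FOUR_PIXEL["truth"], np.zeros(4, dtype=bool)
        )
        assert cm.sum() == 0

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.array([0, 5]), np.array([0, 1]))


class TestAccuracy:
    def test_worked_examples(self):
        cm = confusion_matrix(FOUR_PIXEL["pred"], FOUR_PIXEL["truth"])
        assert pixel_accuracy(cm) == pytest.approx(75.0)
        assert pixel_accuracy(np.diag([3, 4, 5])) == 100.0
        assert pixel_accuracy(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])) == 0.0

    def test_empty_matrix_is_nan(self):
        assert np.isnan(pixel_accuracy(np.zeros((3, 3), dtype=int)))


class TestClassIoU:
    def test_idc_table_semantics_vs_standard(self):
        """In the evaluation protocol's convention, the benign->DCIS
        confusion counts as a false negative for IDC, halving its IoU."""
        cm = confusion_matrix(FOUR_PIXEL["pred"], FOUR_PIXEL["truth"])
        assert class_iou(cm, 2, "paper_table1") == pytest.approx(0.5)
        assert class_iou(cm, 2, "standard") == pytest.approx(1.0)

    def test_perfect_prediction_is_one_in_both_modes(self):
        cm = np.diag([5, 6, 7])
        for mode in ("paper_table1", "standard"):
            assert all(class_iou(cm, k, mode) == 1.0 for k in range(3))

    def test_fuzzed_matrices_match_oracle_and_ordering(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            cm = rng.integers(0, 20, (3, 3))
            for k in range(3):
                paper = class_iou(cm, k, "paper_table1")
                std = class_iou(cm, k, "standard")
                assert paper == pytest.approx(oracle_iou(cm, k, True))
                assert std == pytest.approx(oracle_iou(cm, k, False))
                assert std >= paper  # the paper-mode FN set is a superset

    def test_unknown_class_or_mode_rejected(self):
        with pytest.raises(ValueError):
            class_iou(np.eye(3, dtype=int), 5)
        with pytest.raises(ValueError):
            class_iou(np.eye(3, dtype=int), 0, mode="bogus")


class TestMeanIoU:
    def test_extremes_and_worked_example(self):
        assert mean_iou(np.diag([1, 1, 1])) == 1.0
        all_wrong = np.array([[0, 3, 0], [0, 0, 3], [3, 0, 0]])
        assert mean_iou(all_wrong) == 0.0
        cm = confusion_matrix(FOUR_PIXEL["pred"], FOUR_PIXEL["truth"])
        expected = np.mean([oracle_iou(cm, k, True) for k in range(3)])
        assert mean_iou(cm, "paper_table1") == pytest.approx(expected)


class TestBootstrap:
    def test_identical_units_collapse_to_point(self):
        cm = np.array([[5, 1, 0], [0, 4, 1], [0, 0, 6]])
        lo, hi = bootstrap_ci([cm] * 8, pixel_accuracy, n_boot=200, seed=0)
        point = pixel_accuracy(cm * 8)
        assert lo == pytest.approx(point) and hi == pytest.approx(point)

    def test_constant_metric_gives_degenerate_interval(self):
        units = [np.diag([1, 2, 3]), np.diag([4, 0, 1])]
        lo, hi = bootstrap_ci(units, lambda c: 7.0, n_boot=100, seed=1)
        assert (lo, hi) == (7.0, 7.0)

    def test_matches_independent_resampling_oracle(self):
        rng = np.random.default_rng(5)
        units = [rng.integers(0, 10, (3, 3)) for _ in range(10)]
        lo, hi = bootstrap_ci(units, pixel_accuracy, n_boot=1000, seed=123)
        # independently coded resampler following the same seed protocol
        oracle_rng = np.random.default_rng(123)
        stats = []
        arr = np.stack(units)
        for _ in range(1000):
            idx = oracle_rng.integers(0, 10, size=10)
            pooled = arr[idx].sum(axis=0)
            stats.append(100.0 * np.trace(pooled) / pooled.sum())
        assert lo == np.percentile(stats, 2.5)
        assert hi == np.percentile(stats, 97.5)

    def test_empty_units_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], pixel_accuracy)


class TestEvaluateWithRejection:
    def make_scores(self, pred, n_classes=3):
        O = np.zeros((len(pred), n_classes))
        O[np.arange(len(pred)), pred] = 1.0
        return O.T[None]  # (1, C, 1, n)

    def test_full_selection_equals_plain_evaluation(self):
        truth = FOUR_PIXEL["truth"][None, None]
        O = self.make_scores(FOUR_PIXEL["pred"]).reshape(1, 3, 1, 4)
        rep = evaluate_with_rejection(O, np.ones((1, 1, 4)), truth)
        assert rep.rejection_fraction == 0.0
        assert rep.accuracy == pytest.approx(75.0)

    def test_eight_pixel_case_with_two_rejected(self):
        truth = np.array([[0, 0, 1, 1, 2, 2, 0, 1]])[:, None]
        pred = np.array([0, 1, 1, 2, 2, 2, 0, 0])
        O = self.make_scores(pred).reshape(1, 3, 1, 8)
        S = np.array([[[1, 1, 1, 0, 1, 1, 1, 0]]], dtype=float)
        rep = evaluate_with_rejection(O, S, truth, threshold=0.5)
        assert rep.rejection_fraction == pytest.approx(25.0)
        accept = S[0, 0] >= 0.5
        assert np.array_equal(
            rep.confusion, oracle_confusion(pred, truth.ravel(), accept)
        )

    def test_everything_rejected_reports_missing_metrics(self):
        truth = FOUR_PIXEL["truth"][None, None]
        O = self.make_scores(FOUR_PIXEL["pred"]).reshape(1, 3, 1, 4)
        rep = evaluate_with_rejection(O, np.zeros((1, 1, 4)), truth)
        assert rep.rejection_fraction == 100.0
        assert np.isnan(rep.accuracy) and np.isnan(rep.miou)

    def test_rejecting_exactly_the_errors_raises_accuracy_conservatively(self):
        """Accuracy over all pixels decomposes as the coverage-weighted
        combination of accepted and rejected accuracy, so rejecting only
        misclassified pixels can never lower accepted-set accuracy."""
        rng = np.random.default_rng(7)
        truth = rng.integers(0, 3, (1, 1, 50))
        pred = truth.copy().ravel()
        wrong = rng.random(50) < 0.3
        pred[wrong] = (pred[wrong] + 1) % 3
        O = self.make_scores(pred).reshape(1, 3, 1, 50)
        S = (~wrong).astype(float)[None, None]
        rep_all = evaluate_with_rejection(O, np.ones_like(S), truth)
        rep_sel = evaluate_with_rejection(O, S, truth)
        assert rep_sel.accuracy == pytest.approx(100.0)
        assert rep_sel.accuracy >= rep_all.accuracy
        # conservation: overall = covered * acc_cov + rejected * acc_rej
        acc_rej = 0.0  # all rejected pixels are wrong by construction
        cov = 1 - rep_sel.rejection_fraction / 100
        recomposed = cov * rep_sel.accuracy + (1 - cov) * acc_rej
        assert recomposed == pytest.approx(rep_all.accuracy)

    def test_argmax_ties_break_to_lowest_class(self):
        O = np.full((1, 3, 1, 2), 0.5)
        rep = evaluate_with_rejection(O, np.ones((1, 1, 2)), np.zeros((1, 1, 2), int))
        assert rep.accuracy == 100.0  # ties resolve to class 0 == truth

    def test_per_unit_bootstrap_attaches_cis(self):
        rng = np.random.default_rng(11)
        O = rng.random((6, 3, 4, 4))
        S = np.ones((6, 4, 4))
        y = rng.integers(0, 3, (6, 4, 4))
        rep = evaluate_with_rejection(O, S, y, per_unit=True, n_boot=50, seed=2)
        lo, hi = rep.ci["accuracy"]
        assert lo <= rep.accuracy <= hi
        assert rep.n_units == 6
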