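"""Metric suite: formula oracles, published-table recomputation, sklearn
cross-checks."""

import numpy as np
import pytest
import sklearn.metrics as skm

from histonet import metrics as mm
from histonet.metrics import (ClassMetrics, accuracy, aggregate, build_report,
                              class_metrics, confusion_matrix,
                              f1_from_percent, jaccard, roc_auc)

LABELS8 = ("A", "DC", "F", "LC", "MC", "PC", "PT", "TA")

# Published per-class results of the reference study's 40x test split:
# (precision %, sensitivity %, specificity %, F1 %, support)
TABLE_40X = {
    "A": (100, 100, 100.0, 100, 13),
    "DC": (96, 92, 97.48, 94, 88),
    "F": (96, 100, 99.45, 98, 26),
    "LC": (71, 94, 96.86, 81, 16),
    "MC": (95, 95, 99.46, 95, 21),
    "PC": (93, 87, 99.48, 90, 15),
    "PT": (100, 92, 100.0, 96, 12),
    "TA": (100, 100, 100.0, 100, 16),
}
# And the corresponding 100x rows.
TABLE_100X = {
    "A": (100, 92, 100.0, 96, 12),
    "DC": (93, 96, 94.26, 94, 91),
    "F": (96, 88, 99.47, 92, 26),
    "LC": (78, 78, 97.95, 78, 18),
    "MC": (95, 91, 99.47, 93, 23),
    "PC": (94, 100, 99.49, 97, 15),
    "PT": (92, 92, 99.50, 92, 13),
    "TA": (100, 100, 100.0, 100, 15),
}


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = ["A", "DC", "F", "A"]
        cm = confusion_matrix(y, y, ("A", "DC", "F"))
        assert np.trace(cm.counts) == 4
        assert cm.counts.sum() == 4

    def test_hand_example(self):
        cm = confusion_matrix(("A", "A", "DC"), ("A", "DC", "DC"), ("A", "DC"))
        assert cm.counts[0, 0] == 1  # A -> A
        assert cm.counts[0, 1] == 1  # A -> DC
        assert cm.counts[1, 1] == 1  # DC -> DC

    def test_matches_brute_force_tally(self, rng):
        y_true = rng.choice(LABELS8, 200)
        y_pred = rng.choice(LABELS8, 200)
        cm = confusion_matrix(y_true, y_pred, LABELS8)
        for i, a in enumerate(LABELS8):
            for j, b in enumerate(LABELS8):
                tally = sum(1 for t, p in zip(y_true, y_pred)
                            if t == a and p == b)
                assert cm.counts[i, j] == tally

    def test_one_vs_rest_partition(self, rng):
        y_true = rng.choice(LABELS8, 100)
        y_pred = rng.choice(LABELS8, 100)
        cm = confusion_matrix(y_true, y_pred, LABELS8)
        for label in LABELS8:
            tp, fp, fn, tn = cm.one_vs_rest(label)
            assert tp + fp + fn + tn == 100

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["A"], ["XX"], ("A",))


class TestClassMetrics:
    def test_published_f1_cells_from_precision_sensitivity(self):
        """The harmonic mean of each published precision-sensitivity pair
        reproduces the published F1 cell after rounding."""
        for table in (TABLE_40X, TABLE_100X):
            for label, (prec, sens, _spec, f1, _n) in table.items():
                assert round(f1_from_percent(prec, sens)) == f1, label

    def test_diagonal_matrix_all_hundred(self):
        cm = mm.ConfusionMatrix(np.diag([5, 3, 2]), ("A", "B", "C"))
        for label in ("A", "B", "C"):
            m = class_metrics(cm, label)
            assert (m.precision, m.sensitivity, m.specificity, m.f1) == \
                (100.0, 100.0, 100.0, 100.0)

    def test_matches_sklearn_on_random_labels(self, rng):
        y_true = rng.choice(LABELS8, 300)
        y_pred = rng.choice(LABELS8, 300)
        cm = confusion_matrix(y_true, y_pred, LABELS8)
        prec = skm.precision_score(y_true, y_pred, labels=LABELS8,
                                   average=None, zero_division=0)
        rec = skm.recall_score(y_true, y_pred, labels=LABELS8, average=None,
                               zero_division=0)
        f1 = skm.f1_score(y_true, y_pred, labels=LABELS8, average=None,
                          zero_division=0)
        for k, label in enumerate(LABELS8):
            m = class_metrics(cm, label)
            assert m.precision == pytest.approx(100 * prec[k], abs=1e-9)
            assert m.sensitivity == pytest.approx(100 * rec[k], abs=1e-9)
            assert m.f1 == pytest.approx(100 * f1[k], abs=1e-9)

    def test_zero_denominator_policy(self):
        cm = mm.ConfusionMatrix(np.array([[0, 2], [0, 3]]), ("A", "B"))
        with pytest.warns(RuntimeWarning):
            m = class_metrics(cm, "A")
        assert m.precision == 0.0 and m.sensitivity == 0.0 and m.f1 == 0.0


class TestAggregate:
    def test_published_macro_specificity(self):
        """Unweighted mean of the published 40x per-class specificities."""
        per_class = {k: ClassMetrics(p, s, sp, f, n)
                     for k, (p, s, sp, f, n) in TABLE_40X.items()}
        macro, _ = aggregate(per_class)
        assert round(macro.specificity, 2) == 99.09

    def test_published_weighted_precision(self):
        """Support-weighted mean of the published 40x per-class precisions
        rounds to the published 95."""
        per_class = {k: ClassMetrics(p, s, sp, f, n)
                     for k, (p, s, sp, f, n) in TABLE_40X.items()}
        _, weighted = aggregate(per_class)
        assert round(weighted.precision) == 95

    def test_identical_classes_macro_equals_weighted(self):
        per_class = {c: ClassMetrics(80.0, 70.0, 90.0, 74.7, 10)
                     for c in ("A", "B", "C")}
        macro, weighted = aggregate(per_class)
        for f in ("precision", "sensitivity", "specificity", "f1"):
            assert getattr(macro, f) == pytest.approx(getattr(weighted, f))

    def test_weighted_sensitivity_is_accuracy(self, rng):
        y_true = rng.choice(LABELS8, 150)
        y_pred = rng.choice(LABELS8, 150)
        cm = confusion_matrix(y_true, y_pred, LABELS8)
        per_class = {c: class_metrics(cm, c) for c in LABELS8}
        _, weighted = aggregate(per_class)
        assert weighted.sensitivity == pytest.approx(accuracy(cm), abs=1e-9)

    def test_micro_identity(self, rng):
        y_true = rng.choice(LABELS8, 123)
        y_pred = rng.choice(LABELS8, 123)
        cm = confusion_matrix(y_true, y_pred, LABELS8)
        tp_sum = sum(cm.one_vs_rest(c)[0] for c in LABELS8)
        assert 100.0 * tp_sum / 123 == pytest.approx(accuracy(cm))


class TestJaccard:
    def test_perfect(self):
        y = ["A", "B", "A"]
        assert jaccard(y, y, ("A", "B")) == 100.0

    def test_empty_intersection(self):
        assert jaccard(["A", "A"], ["B", "B"], ("A", "B")) == 0.0

    def test_hand_tally_half_correct(self):
        # one class half-recovered against one alternative:
        # A: TP=1, FN=1, FP=0 -> 1/2; B: TP=2, FP=1, FN=0 -> 2/3
        y_true = ["A", "A", "B", "B"]
        y_pred = ["A", "B", "B", "B"]
        expected = 100 * (1 / 2 + 2 / 3) / 2
        assert jaccard(y_true, y_pred, ("A", "B")) == pytest.approx(expected)

    def test_matches_sklearn_macro(self, rng):
        y_true = rng.choice(LABELS8, 100)
        y_pred = rng.choice(LABELS8, 100)
        expected = 100 * skm.jaccard_score(y_true, y_pred, labels=LABELS8,
                                           average="macro", zero_division=0)
        with np.errstate(all="ignore"):
            assert jaccard(y_true, y_pred, LABELS8) == pytest.approx(expected)


class TestRocAuc:
    def test_perfect_ranking(self):
        y = ["A", "A", "B", "B"]
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert roc_auc(scores, y, ("A", "B")) == pytest.approx(100.0)

    def test_constant_scores_chance_level(self):
        y = ["A", "B"] * 10
        scores = np.full((20, 2), 0.5)
        assert roc_auc(scores, y, ("A", "B")) == pytest.approx(50.0)

    def test_matches_mann_whitney_oracle(self, rng):
        """Trapezoidal AUC equals the all-pairs concordance probability
        P(score_pos > score_neg) + 0.5 P(tie)."""
        y = rng.choice(("A", "B", "C"), 20)
        raw = rng.random((20, 3))
        scores = raw / raw.sum(axis=1, keepdims=True)
        per_class = []
        for k, label in enumerate(("A", "B", "C")):
            pos = scores[np.array(y) == label, k]
            neg = scores[np.array(y) != label, k]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            per_class.append(wins / (len(pos) * len(neg)))
        expected = 100 * np.mean(per_class)
        assert roc_auc(scores, y, ("A", "B", "C")) == pytest.approx(expected)

    def test_matches_sklearn_ovr_macro(self, rng):
        y = rng.choice(LABELS8, 200)
        raw = rng.random((200, 8))
        scores = raw / raw.sum(axis=1, keepdims=True)
        y_idx = np.array([LABELS8.index(t) for t in y])
        expected = 100 * skm.roc_auc_score(y_idx, scores, multi_class="ovr",
                                           average="macro", labels=range(8))
        assert roc_auc(scores, y, LABELS8) == pytest.approx(expected, abs=1e-9)

    def test_absent_class_skipped_with_warning(self):
        y = ["A", "A", "B"]
        scores = np.array([[0.5, 0.3, 0.2]] * 3)
        with pytest.warns(RuntimeWarning):
            roc_auc(scores, y, ("A", "B", "C"))


class TestReport:
    def test_support_column_sums_to_test_size(self, rng):
        y_true = rng.choice(LABELS8, 97)
        y_pred = rng.choice(LABELS8, 97)
        report = build_report(y_true, y_pred, LABELS8)
        assert sum(m.support for m in report.per_class.values()) == 97

    def test_report_weighted_sensitivity_equals_accuracy(self, rng):
        y_true = rng.choice(LABELS8, 60)
        y_pred = rng.choice(LABELS8, 60)
        report = build_report(y_true, y_pred, LABELS8)
        assert report.weighted_row.sensitivity == pytest.approx(report.accuracy)

    def test_summary_contains_table_rows(self):
        y = ["A", "B", "A", "B"]
        report = build_report(y, y, ("A", "B"))
        text = report.summary()
        assert "Macro Average" in text and "Weighted Average" in text
        assert "Specificity" in text

    def test_artifacts_written(self, tmp_path, rng):
        y_true = rng.choice(("A", "B"), 20)
        y_pred = rng.choice(("A", "B"), 20)
        raw = rng.random((20, 2))
        report = build_report(y_true, y_pred, ("A", "B"),
                              raw / raw.sum(1, keepdims=True))
        report.write(tmp_path)
        for name in ("report.json", "confusion_matrix.csv", "per_class.csv",
                     "confusion_matrix.png"):
            assert (tmp_path / name).exists()

    @pytest.mark.parametrize("trial", range(5))
    def test_property_full_agreement_with_sklearn(self, trial):
        """Randomized cross-check of the whole per-class metric block
        against an independent implementation."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(20, 200))
        labels = LABELS8[: int(rng.integers(2, 8))]
        y_true = rng.choice(labels, n)
        y_pred = rng.choice(labels, n)
        cm = confusion_matrix(y_true, y_pred, labels)
        skcm = skm.confusion_matrix(y_true, y_pred, labels=labels)
        np.testing.assert_array_equal(cm.counts, skcm)
        assert accuracy(cm) == pytest.approx(
            100 * skm.accuracy_score(y_true, y_pred))
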