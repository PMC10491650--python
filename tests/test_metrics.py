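"""Confusion table, group SPE/SEN formulas, ROC/AUC, PRC, and the full report."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ictalnet.bonn import TASKS
from ictalnet.metrics import (
    ConfusionTable,
    accuracy,
    confusion_table,
    evaluation_report,
    group_sensitivity,
    group_specificity,
    macro_ovr_auc,
    ovr_roc_auc,
    pr_curve,
)

from oracles import (
    auc_pair_counting,
    confusion_loops,
    ovr_recall_loops,
    ovr_specificity_loops,
    pr_points_brute,
)

# worked three-group table: rows = real class
A_EXAMPLE = ConfusionTable(np.array([[8, 1, 1], [0, 9, 1], [0, 0, 10]]))


class TestConfusionTable:
    def test_identity_predictions(self):
        A = confusion_table([0, 1, 2], [0, 1, 2], 3)
        assert np.array_equal(A.table, np.eye(3, dtype=int))
        assert accuracy(A) == 1.0

    def test_single_off_diagonal_cell(self):
        A = confusion_table([0, 0], [1, 1], 3)
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = 2
        assert np.array_equal(A.table, expected)

    def test_matches_tally_oracle(self, rng):
        t = rng.integers(0, 4, size=1000)
        p = rng.integers(0, 4, size=1000)
        assert np.array_equal(confusion_table(t, p, 4).table, confusion_loops(t, p, 4))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            confusion_table([0, 3], [0, 1], 3)


class TestGroupFormulas:
    def test_sensitivity_worked_example(self):
        assert group_sensitivity(A_EXAMPLE, 0) == pytest.approx(0.8)
        assert group_sensitivity(A_EXAMPLE, 1) == pytest.approx(0.9)
        assert group_sensitivity(A_EXAMPLE, 2) == pytest.approx(1.0)

    def test_specificity_worked_example(self):
        # (A22+A23+A32+A33)/(A2+A3) and the two analogous expressions
        assert group_specificity(A_EXAMPLE, 0) == pytest.approx(1.0)
        assert group_specificity(A_EXAMPLE, 1) == pytest.approx(0.95)
        assert group_specificity(A_EXAMPLE, 2) == pytest.approx(0.9)

    def test_perfect_diagonal(self):
        A = ConfusionTable(np.diag([5, 7, 3]))
        for g in range(3):
            assert group_sensitivity(A, g) == 1.0
            assert group_specificity(A, g) == 1.0

    def test_accuracy_worked_example(self):
        assert accuracy(A_EXAMPLE) == pytest.approx(0.9)

    def test_zero_diagonal_accuracy(self):
        assert accuracy(ConfusionTable(np.array([[0, 2], [3, 0]]))) == 0.0

    def test_empty_group_rejected(self):
        A = ConfusionTable(np.array([[0, 0, 0], [0, 5, 0], [0, 0, 5]]))
        with pytest.raises(ValueError, match="undefined"):
            group_sensitivity(A, 0)

    def test_formulas_equal_one_vs_rest_oracles(self, rng):
        # printed group formulas == independent OvR recall / true-negative rate
        for _ in range(500):
            A = ConfusionTable(rng.integers(1, 20, size=(3, 3)))
            for g in range(3):
                assert group_sensitivity(A, g) == pytest.approx(
                    ovr_recall_loops(A.table, g), abs=1e-12
                )
                assert group_specificity(A, g) == pytest.approx(
                    ovr_specificity_loops(A.table, g), abs=1e-12
                )

    def test_accuracy_invariant_under_permutation(self, rng):
        A = rng.integers(0, 20, size=(3, 3))
        perm = rng.permutation(3)
        assert accuracy(ConfusionTable(A)) == pytest.approx(
            accuracy(ConfusionTable(A[np.ix_(perm, perm)]))
        )


class TestROCAUC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        truths = np.array([1, 1, 0, 0])
        _, auc = ovr_roc_auc(scores, truths, 1)
        assert auc == 1.0

    def test_single_tie_gives_half(self):
        _, auc = ovr_roc_auc(np.array([0.5, 0.5]), np.array([1, 0]), 1)
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.random(200), 2)  # rounding forces ties
        truths = (rng.random(200) < 0.4).astype(int)
        _, auc = ovr_roc_auc(scores, truths, 1)
        assert auc == pytest.approx(auc_pair_counting(scores, truths == 1), abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.random(300)
        truths = (rng.random(300) < 0.5).astype(int)
        _, auc = ovr_roc_auc(scores, truths, 1)
        assert auc == pytest.approx(roc_auc_score(truths, scores), abs=1e-12)

    def test_score_reversal_flips_auc(self, rng):
        scores = rng.random(100)
        truths = (rng.random(100) < 0.5).astype(int)
        _, auc = ovr_roc_auc(scores, truths, 1)
        _, rev = ovr_roc_auc(-scores, truths, 1)
        assert auc + rev == pytest.approx(1.0, abs=1e-12)

    def test_roc_endpoints(self, rng):
        pts, _ = ovr_roc_auc(rng.random(50), (rng.random(50) < 0.5).astype(int), 1)
        assert np.array_equal(pts[0], [0.0, 0.0])
        assert np.array_equal(pts[-1], [1.0, 1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ovr_roc_auc(np.array([0.1, 0.2]), np.array([1, 1]), 1)

    def test_macro_is_mean_of_per_class(self, rng):
        probs = rng.dirichlet(np.ones(3), size=120)
        truths = rng.integers(0, 3, size=120)
        per_class = [ovr_roc_auc(probs, truths, c)[1] for c in range(3)]
        assert macro_ovr_auc(probs, truths, 3) == pytest.approx(np.mean(per_class), abs=1e-12)

    def test_macro_perfect_probabilities(self):
        truths = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[truths]
        assert macro_ovr_auc(probs, truths, 3) == 1.0

    def test_macro_missing_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            macro_ovr_auc(np.full((4, 3), 1 / 3), np.array([0, 1, 0, 1]), 3)


class TestPRCurve:
    def test_perfect_separation_endpoint(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truths = np.array([1, 1, 0, 0])
        pts = pr_curve(scores, truths, 1)
        assert (1.0, 1.0) in {(p, r) for _, p, r in pts}

    def test_lowest_threshold_gives_prevalence(self, rng):
        truths = (rng.random(80) < 0.3).astype(int)
        pts = pr_curve(rng.random(80), truths, 1)
        assert pts[-1, 2] == 1.0
        assert pts[-1, 1] == pytest.approx(truths.mean())

    def test_recall_nondecreasing(self, rng):
        pts = pr_curve(rng.random(60), (rng.random(60) < 0.4).astype(int), 1)
        assert np.all(np.diff(pts[:, 2]) >= 0)

    def test_matches_brute_force_thresholds(self, rng):
        scores = np.round(rng.random(200), 2)
        truths = (rng.random(200) < 0.4).astype(int)
        np.testing.assert_allclose(
            pr_curve(scores, truths, 1), pr_points_brute(scores, truths == 1), atol=1e-12
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve(np.array([0.3, 0.4]), np.array([0, 0]), 1)


class TestEvaluationReport:
    def _ternary_report(self, rng, n=90):
        truths = rng.integers(0, 3, size=n)
        probs = rng.dirichlet(np.ones(3), size=n)
        probs[np.arange(n), truths] += 1.0  # make predictions informative
        probs /= probs.sum(axis=1, keepdims=True)
        return evaluation_report(probs, truths, TASKS["ternary"]), probs, truths

    def test_schema(self, rng):
        report, _, _ = self._ternary_report(rng)
        assert report.group_names == ["{F/N}", "{O/Z}", "{S}"]
        assert len(report.sensitivity) == 3
        assert len(report.specificity) == 3
        assert len(report.auc) == 3
        assert 0.0 <= report.macro_auc <= 1.0
        assert 0.0 <= report.accuracy <= 1.0

    def test_binary_reduces_to_standard_definitions(self, rng):
        n = 100
        truths = rng.integers(0, 2, size=n)
        p1 = np.clip(truths * 0.6 + rng.random(n) * 0.4, 0, 1)
        probs = np.column_stack([1 - p1, p1])
        report = evaluation_report(probs, truths, TASKS["Z_vs_S"])
        preds = probs.argmax(axis=1)
        tp = ((preds == 1) & (truths == 1)).sum()
        fn = ((preds == 0) & (truths == 1)).sum()
        tn = ((preds == 0) & (truths == 0)).sum()
        fp = ((preds == 1) & (truths == 0)).sum()
        assert report.sensitivity["{S}"] == pytest.approx(tp / (tp + fn))
        assert report.specificity["{S}"] == pytest.approx(tn / (tn + fp))

    def test_relabeling_symmetry(self, rng):
        report, probs, truths = self._ternary_report(rng)
        perm = np.array([2, 0, 1])  # new label of old class c is perm[c]
        inv = np.argsort(perm)
        report2 = evaluation_report(probs[:, inv], perm[truths], TASKS["ternary"])
        names = report.group_names
        for old, new in enumerate(perm):
            assert report2.sensitivity[names[new]] == pytest.approx(
                report.sensitivity[names[old]]
            )
            assert report2.auc[names[new]] == pytest.approx(report.auc[names[old]])
        assert report2.accuracy == pytest.approx(report.accuracy)

    def test_serialization_round_trip(self, rng):
        import json

        report, _, _ = self._ternary_report(rng)
        payload = json.loads(json.dumps(report.to_dict()))
        assert payload["accuracy"] == pytest.approx(report.accuracy)
        assert np.array_equal(payload["confusion"], report.confusion.table)
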