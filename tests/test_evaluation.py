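"""Diagnostic metrics, split protocols, ROC, and the experiment runner."""

import math

import numpy as np
import pytest

from wavelstm import (
    BaselineConfig,
    PipelineSpec,
    binary_metrics,
    confusion_matrix,
    macro_metrics,
    make_split_plan,
    roc_points,
    run_experiment,
)


class TestConfusionMatrix:
    def test_direct_count_example(self):
        cm = confusion_matrix([1, 1, 0, 0], [1, 0, 0, 0], 2)
        # positive class 1: TP=1, FN=1, TN=2, FP=0
        assert cm[1, 1] == 1 and cm[1, 0] == 1
        assert cm[0, 0] == 2 and cm[0, 1] == 0

    def test_perfect_prediction_is_diagonal(self, rng):
        y = rng.integers(0, 3, size=50)
        cm = confusion_matrix(y, y, 3)
        assert cm.sum() == 50
        assert np.trace(cm) == 50

    def test_total_conserved(self, rng):
        t = rng.integers(0, 4, size=200)
        p = rng.integers(0, 4, size=200)
        assert confusion_matrix(t, p, 4).sum() == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)


class TestBinaryMetrics:
    def test_direct_arithmetic_example(self):
        cm = np.array([[8, 1], [2, 9]])  # TN=8 FP=1 FN=2 TP=9
        rep = binary_metrics(cm)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.sensitivity == pytest.approx(100 * 9 / 11)
        assert rep.specificity == pytest.approx(100 * 8 / 9)

    def test_youden_identity_holds(self, rng):
        for _ in range(20):
            cm = rng.integers(1, 40, size=(2, 2))
            rep = binary_metrics(cm)
            assert rep.youden == pytest.approx(
                rep.sensitivity / 100 + rep.specificity / 100 - 1, abs=1e-12
            )

    def test_perfect_classifier_reaches_maximum_informedness(self):
        rep = binary_metrics(np.array([[10, 0], [0, 10]]))
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0
        assert rep.youden == pytest.approx(1.0)

    def test_zero_denominator_flagged_not_silently_zero(self):
        rep = binary_metrics(np.array([[5, 3], [0, 0]]))  # no positives
        assert math.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined
        assert math.isnan(rep.youden)

    def test_display_rounding_convention(self):
        rep = binary_metrics(np.array([[8, 1], [2, 9]]))
        rounded = rep.rounded()
        assert rounded["sensitivity"] == 81.8
        assert rounded["youden"] == round(rep.youden, 2)


class TestMacroMetrics:
    def test_perfect_three_class(self):
        rep = macro_metrics(np.eye(3, dtype=int) * 12)
        assert rep.accuracy == pytest.approx(100.0)
        assert rep.sensitivity == pytest.approx(100.0)
        assert rep.specificity == pytest.approx(100.0)
        assert rep.youden == pytest.approx(1.0)

    def test_uniform_random_predictions_closed_form(self):
        # balanced 3-class with uniform predictions: every cell equal
        rep = macro_metrics(np.full((3, 3), 8))
        assert rep.sensitivity == pytest.approx(100 / 3)
        assert rep.specificity == pytest.approx(200 / 3)
        assert rep.accuracy == pytest.approx(100 / 3)

    def test_two_class_macro_consistent_with_binary(self):
        cm = np.array([[30, 5], [4, 21]])
        macro = macro_metrics(cm)
        pos = binary_metrics(cm, positive=1)
        neg = binary_metrics(cm, positive=0)
        assert macro.sensitivity == pytest.approx(
            (pos.sensitivity + neg.sensitivity) / 2
        )

    def test_micro_sensitivity_equals_accuracy_on_balanced_tests(self):
        cm = np.array([[20, 3, 2], [4, 18, 3], [1, 2, 22]])
        rep = macro_metrics(cm, average="micro")
        assert rep.sensitivity == pytest.approx(rep.accuracy)

    def test_empty_class_flagged(self):
        cm = np.array([[10, 0, 0], [0, 5, 0], [0, 0, 0]])
        rep = macro_metrics(cm)
        assert "sensitivity" in rep.undefined


class TestSplitPlans:
    def test_stratified_70_30_of_112_gives_78_and_34(self):
        labels = np.repeat([0, 1], 56)
        plan = make_split_plan(labels, repeats=5, seed=3)
        assert plan.n_splits == 5
        for tr, te in plan.splits:
            assert tr.size == 78 and te.size == 34
            assert np.intersect1d(tr, te).size == 0
            assert np.union1d(tr, te).size == 112
            assert np.bincount(labels[tr]).tolist() == [39, 39]
            assert np.bincount(labels[te]).tolist() == [17, 17]

    def test_three_class_300_sample_stratification(self):
        labels = np.repeat([0, 1, 2], 100)
        plan = make_split_plan(labels, repeats=5, seed=1)
        for tr, te in plan.splits:
            assert np.bincount(labels[tr]).tolist() == [70, 70, 70]
            assert np.bincount(labels[te]).tolist() == [30, 30, 30]

    def test_kfold_partitions_every_sample_once(self):
        labels = np.repeat([0, 1, 2], 100)
        plan = make_split_plan(labels, protocol="kfold", fraction_or_k=5, seed=2)
        seen = np.concatenate([te for _, te in plan.splits])
        assert np.sort(seen).tolist() == list(range(300))
        for tr, te in plan.splits:
            assert np.intersect1d(tr, te).size == 0
            counts = np.bincount(labels[te], minlength=3)
            assert counts.max() - counts.min() <= 1

    def test_same_seed_identical_plan(self):
        labels = np.repeat([0, 1], 20)
        a = make_split_plan(labels, repeats=3, seed=7)
        b = make_split_plan(labels, repeats=3, seed=7)
        for (tr1, te1), (tr2, te2) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_infeasible_stratification_rejected(self):
        with pytest.raises(ValueError):
            make_split_plan(np.array([0, 0, 0, 1]), repeats=1)
        with pytest.raises(ValueError):
            make_split_plan(np.repeat([0, 1], 3), protocol="kfold", fraction_or_k=5)


class TestROC:
    def test_perfect_separation_gives_unit_area(self):
        _, _, area = roc_points(np.array([0.9, 0.8, 0.2, 0.1]),
                                np.array([1, 1, 0, 0]))
        assert area == pytest.approx(1.0)

    def test_constant_scores_give_chance_area(self):
        fpr, tpr, area = roc_points(np.full(10, 0.5), np.array([0, 1] * 5))
        assert area == pytest.approx(0.5)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_area_equals_concordance_probability(self, rng):
        """Trapezoidal ROC area equals the Mann-Whitney statistic."""
        for _ in range(10):
            n = 30
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            ) / (pos.size * neg.size)
            _, _, area = roc_points(scores, labels)
            assert area == pytest.approx(conc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points(np.array([0.1, 0.9]), np.array([1, 1]))


class TestRunExperiment:
    def test_table_shape_and_self_consistency(self, small_separable):
        _, data = small_separable
        plan = make_split_plan(data.labels, repeats=5, seed=4)
        spec = PipelineSpec(transform="dwt", classifier="knn",
                            baseline=BaselineConfig())
        table = run_experiment(data.features, data.labels, spec, plan)
        assert len(table.per_split) == 5
        assert len(table.confusions) == 5
        for metric in ("accuracy", "sensitivity", "specificity", "youden"):
            assert table.mean[metric] == pytest.approx(
                table.per_split[metric].mean()
            )
            assert table.std[metric] == pytest.approx(
                table.per_split[metric].std(ddof=1)
            )

    def test_identical_rerun_gives_identical_table(self, small_separable):
        _, data = small_separable
        plan = make_split_plan(data.labels, repeats=3, seed=8)
        spec = PipelineSpec(transform="none", classifier="svm")
        t1 = run_experiment(data.features, data.labels, spec, plan)
        t2 = run_experiment(data.features, data.labels, spec, plan)
        assert t1.per_split.equals(t2.per_split)

    def test_results_serialization(self, small_separable, tmp_path):
        _, data = small_separable
        plan = make_split_plan(data.labels, repeats=2, seed=8)
        spec = PipelineSpec(transform="none", classifier="knn")
        table = run_experiment(data.features, data.labels, spec, plan)
        table.to_json(tmp_path / "r.json")
        table.to_csv(tmp_path / "r.csv")
        assert (tmp_path / "r.json").exists()
        summary = table.summary()
        assert "mean" in summary.index and "std" in summary.index
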