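"""Confusion tallies, metric formulas, and the experiment harnesses."""

from __future__ import annotations

import numpy as np
import pytest

from ocusiam.evaluation import (
    ConfusionCounts,
    ExperimentGrid,
    compute_metrics,
    confusion_from_predictions,
    metrics_from_predictions,
    run_classifier_comparison,
    run_k_sweep,
)
from ocusiam.knn import FeatureGallery


class TestConfusion:
    def test_perfect_agreement(self):
        truth = ["P"] * 12 + ["N"] * 8
        c = confusion_from_predictions(truth, truth, "P")
        assert (c.tp, c.tn, c.fp, c.fn) == (12, 8, 0, 0)

    def test_degenerate_all_negative_predictor(self):
        truth = ["P"] * 12 + ["N"] * 8
        c = confusion_from_predictions(truth, ["N"] * 20, "P")
        assert (c.fn, c.tn, c.tp, c.fp) == (12, 8, 0, 0)

    def test_hand_tally_with_mixed_errors(self):
        truth = ["P"] * 10 + ["N"] * 10
        pred = ["P"] * 9 + ["N"] + ["P"] * 2 + ["N"] * 8
        c = confusion_from_predictions(truth, pred, "P")
        assert (c.tp, c.fn, c.fp, c.tn) == (9, 1, 2, 8)

    def test_unknown_positive_class_rejected(self):
        with pytest.raises(ValueError, match="positive class"):
            confusion_from_predictions(["A", "B"], ["A", "B"], "C")

    def test_three_classes_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            confusion_from_predictions(["A", "B", "C"], ["A", "B", "C"], "A")


class TestMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(tp=9, fn=1, fp=2, tn=8))
        assert m.accuracy == pytest.approx(0.85, abs=1e-12)
        assert m.precision == pytest.approx(9 / 11, abs=1e-12)
        assert m.recall == pytest.approx(0.9, abs=1e-12)
        assert m.f1 == pytest.approx(0.8571, abs=1e-4)
        assert not m.degenerate

    def test_perfect_classifier_scores_one_everywhere(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_no_positive_predictions_flags_degenerate(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=5))
        assert m.precision == 0.0 and m.degenerate

    def test_accuracy_identity_and_f1_harmonic_mean(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            m = compute_metrics(c)
            assert m.accuracy * c.total == pytest.approx(tp + tn, abs=1e-9)
            if m.precision + m.recall > 0:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-12
                )

    def test_swapping_positive_class_swaps_rates_but_not_accuracy(self):
        truth = ["P"] * 10 + ["N"] * 10
        pred = ["P"] * 9 + ["N"] + ["P"] * 2 + ["N"] * 8
        mp = metrics_from_predictions(truth, pred, "P")
        mn = metrics_from_predictions(truth, pred, "N")
        assert mp.accuracy == mn.accuracy
        # N as positive: TP=8, FP=1, FN=2
        assert mn.precision == pytest.approx(8 / 9, abs=1e-12)
        assert mn.recall == pytest.approx(0.8, abs=1e-12)
        # the macro average is invariant to the designation
        assert mp.macro_f1 == pytest.approx(mn.macro_f1, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

        truth = [str(x) for x in rng.integers(0, 2, size=60)]
        pred = [str(x) for x in rng.integers(0, 2, size=60)]
        m = metrics_from_predictions(truth, pred, "1")
        assert m.accuracy == pytest.approx(accuracy_score(truth, pred))
        assert m.precision == pytest.approx(
            precision_score(truth, pred, pos_label="1")
        )
        assert m.recall == pytest.approx(recall_score(truth, pred, pos_label="1"))
        assert m.f1 == pytest.approx(f1_score(truth, pred, pos_label="1"))

    def test_empty_evaluation_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


def _separable_gallery(rng, n=20):
    """Two well-separated 2-D clusters."""
    a = rng.normal(loc=(-3, 0), scale=0.2, size=(n // 2, 2))
    b = rng.normal(loc=(3, 0), scale=0.2, size=(n // 2, 2))
    vecs = np.vstack([a, b])
    labels = ["VO"] * (n // 2) + ["PVD"] * (n // 2)
    return FeatureGallery(vecs, labels)


class TestKSweep:
    def test_four_rows_for_the_standard_sweep(self, rng):
        g = _separable_gallery(rng)
        queries = g.vectors + rng.normal(scale=0.05, size=g.vectors.shape)
        table = run_k_sweep(g, queries, g.labels, [2, 4, 8, 10])
        assert list(table["k"]) == [2, 4, 8, 10]
        assert (table["accuracy"] == 1.0).all()

    def test_k_equal_gallery_size_votes_globally(self, rng):
        vecs = np.array([[0.0], [0.1], [0.2], [5.0]])
        labels = ["A", "A", "A", "B"]
        g = FeatureGallery(vecs, labels)
        table = run_k_sweep(g, np.array([[10.0]]), ["B"], [4], positive_class="A")
        # the whole-gallery majority is A regardless of the query
        assert table.iloc[0]["accuracy"] == 0.0

    def test_duplicate_ks_deduplicated_with_warning(self, rng):
        g = _separable_gallery(rng)
        with pytest.warns(UserWarning, match="deduplicated"):
            table = run_k_sweep(g, g.vectors, g.labels, [2, 2, 4])
        assert list(table["k"]) == [2, 4]

    def test_invalid_k_rejected(self, rng):
        g = _separable_gallery(rng, n=6)
        with pytest.raises(ValueError, match="invalid k"):
            run_k_sweep(g, g.vectors, g.labels, [7])


class TestClassifierComparison:
    def test_all_heads_solve_a_separable_toy_gallery(self, rng):
        g = _separable_gallery(rng)
        queries = g.vectors + rng.normal(scale=0.05, size=g.vectors.shape)
        table = run_classifier_comparison(g, queries, g.labels, seed=0)
        assert set(table["head"]) == {"knn", "svm", "random_forest",
                                      "gradient_boosting"}
        assert (table["status"] == "ok").all()
        assert (table["accuracy"] == 1.0).all()

    def test_knn_head_reproduces_knn_module_results(self, rng):
        from ocusiam.knn import KnnConfig, knn_classify

        g = _separable_gallery(rng)
        queries = rng.normal(size=(10, 2))
        truth = ["VO"] * 5 + ["PVD"] * 5
        table = run_classifier_comparison(g, queries, truth, heads=["knn"])
        direct = [knn_classify(g, q, KnnConfig(k=2))[0] for q in queries]
        expected = metrics_from_predictions(truth, direct)
        assert table.iloc[0]["accuracy"] == pytest.approx(expected.accuracy)

    def test_failing_head_is_isolated(self, rng):
        class Exploding:
            def fit(self, X, y):
                raise RuntimeError("boom")

            def predict(self, X):  # pragma: no cover
                raise RuntimeError("boom")

        g = _separable_gallery(rng)
        table = run_classifier_comparison(
            g, g.vectors, g.labels, heads=["knn", ("boom", Exploding())]
        )
        by_head = table.set_index("head")
        assert by_head.loc["knn", "status"] == "ok"
        assert by_head.loc["boom", "status"] == "failed"
        assert "boom" in by_head.loc["boom", "error"]

    def test_unknown_head_id_rejected(self, rng):
        g = _separable_gallery(rng)
        with pytest.raises(ValueError, match="unknown classifier head"):
            run_classifier_comparison(g, g.vectors, g.labels, heads=["mlp9000"])


class TestExperimentGrid:
    def test_unknown_attention_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown attention"):
            ExperimentGrid(attention_variants=("none", "quantum"))

    def test_duplicate_variants_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExperimentGrid(attention_variants=("none", "none"))
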