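import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from depthbcs.evaluate import (ConfusionMatrix, EvaluationError, ToleranceBand,
                               accuracy, class_metrics, confusion_matrix,
                               evaluate_predictions, f1_score,
                               relabel_within_tolerance, render_report_table,
                               weighted_average, weighted_metrics, _round2)

# Published per-class values for the angled-camera model (percent):
# exact band class 2.00 and the weighted averages, and the 0.5-band class 3.25.
ANGLED_EXACT_F1 = [0.0, 25.0, 6.06, 32.65, 35.58, 29.75, 12.5, 0.0]
ANGLED_EXACT_RECALL = [0.0, 27.27, 4.69, 31.25, 35.37, 37.5, 12.5, 0.0]
TEST_COUNTS = [16, 44, 64, 128, 164, 96, 32, 4]


class TestToleranceRelabel:
    def test_band_zero_is_identity(self):
        true = np.array([1, 2, 3]); pred = np.array([0, 2, 5])
        np.testing.assert_array_equal(
            relabel_within_tolerance(true, pred, ToleranceBand(0)), pred)

    def test_one_step_inside_band_scored_as_true(self):
        out = relabel_within_tolerance(np.array([4]), np.array([5]),
                                       ToleranceBand(1))
        assert out[0] == 4

    def test_two_steps_outside_one_step_band(self):
        out = relabel_within_tolerance(np.array([4]), np.array([6]),
                                       ToleranceBand(1))
        assert out[0] == 6

    def test_invalid_band_rejected(self):
        with pytest.raises(EvaluationError):
            ToleranceBand(3)

    def test_band_tolerance_in_score_units(self):
        assert ToleranceBand(2).bcs_tolerance == 0.5


class TestAccuracy:
    def test_all_correct(self):
        y = np.array([0, 1, 2])
        assert accuracy(y, y) == 100.0

    def test_half_correct(self):
        true = np.zeros(548, int)
        pred = np.zeros(548, int); pred[274:] = 1
        assert accuracy(true, pred) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            accuracy(np.array([]), np.array([]))

    def test_micro_identity_weighted_recall_equals_accuracy(self):
        """On any prediction set, weighted recall == accuracy per band."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(20, 200))
            true = rng.integers(0, 8, n)
            pred = rng.integers(0, 8, n)
            for steps in (0, 1, 2):
                adj = relabel_within_tolerance(true, pred, ToleranceBand(steps))
                cm = confusion_matrix(true, adj)
                wm = weighted_metrics(class_metrics(cm))
                assert wm["recall"] == pytest.approx(accuracy(true, adj))


class TestClassMetrics:
    def test_f1_from_published_precision_recall_pairs(self):
        assert _round2(f1_score(23.08, 27.27)) == 25.0
        assert _round2(f1_score(100.0, 84.38)) == 91.53

    def test_perfect_classifier_all_100(self):
        cm = ConfusionMatrix(np.diag([5, 3, 7, 2, 8, 1, 4, 6]))
        pc = class_metrics(cm)
        assert (pc[["precision", "recall", "f1"]].to_numpy() == 100.0).all()

    def test_zero_denominator_convention(self):
        counts = np.zeros((8, 8), int)
        counts[0, 1] = 4        # class 0 never predicted, never correct
        pc = class_metrics(ConfusionMatrix(counts))
        assert pc.loc[0, "precision"] == 0.0
        assert pc.loc[0, "recall"] == 0.0
        assert pc.loc[0, "f1"] == 0.0

    def test_matches_sklearn_on_random_predictions(self):
        rng = np.random.default_rng(1)
        true = rng.integers(0, 8, 300)
        pred = rng.integers(0, 8, 300)
        pc = class_metrics(confusion_matrix(true, pred))
        p, r, f, _ = precision_recall_fscore_support(
            true, pred, labels=range(8), zero_division=0)
        np.testing.assert_allclose(pc["precision"], 100 * p, atol=1e-9)
        np.testing.assert_allclose(pc["recall"], 100 * r, atol=1e-9)
        np.testing.assert_allclose(pc["f1"], 100 * f, atol=1e-9)

    def test_f1_between_min_and_max_of_p_and_r(self):
        rng = np.random.default_rng(2)
        true = rng.integers(0, 8, 400)
        pred = np.where(rng.random(400) < 0.5, true, rng.integers(0, 8, 400))
        pc = class_metrics(confusion_matrix(true, pred))
        pos = (pc["precision"] > 0) & (pc["recall"] > 0)
        lo = pc[["precision", "recall"]].min(axis=1)[pos]
        hi = pc[["precision", "recall"]].max(axis=1)[pos]
        assert ((pc["f1"][pos] >= lo - 1e-9) & (pc["f1"][pos] <= hi + 1e-9)).all()


class TestWeightedMetrics:
    def test_published_weighted_f1_and_recall(self):
        assert _round2(weighted_average(ANGLED_EXACT_F1, TEST_COUNTS)) == 26.93
        assert _round2(weighted_average(ANGLED_EXACT_RECALL, TEST_COUNTS)) == 27.92

    def test_uniform_counts_reduce_to_plain_mean(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        assert weighted_average(vals, [5, 5, 5, 5]) == pytest.approx(np.mean(vals))

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            vals = rng.uniform(0, 100, 8)
            counts = rng.integers(1, 50, 8)
            brute = sum(v * c for v, c in zip(vals, counts)) / counts.sum()
            assert weighted_average(vals, counts) == pytest.approx(brute)

    def test_zero_total_rejected(self):
        with pytest.raises(EvaluationError):
            weighted_average([1.0], [0])


class TestEvaluatePredictions:
    def test_perfect_predictions_all_bands_100(self):
        y = np.array([0, 3, 5, 7, 2])
        report = evaluate_predictions(y, y)
        for steps in (0, 1, 2):
            assert report.accuracy(steps) == 100.0

    def test_accuracy_monotone_in_band(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(10, 120))
            true = rng.integers(0, 8, n)
            pred = rng.integers(0, 8, n)
            report = evaluate_predictions(true, pred)
            accs = [report.accuracy(s) for s in (0, 1, 2)]
            assert accs[0] <= accs[1] <= accs[2]

    def test_report_table_has_seven_rows(self):
        rng = np.random.default_rng(5)
        true = rng.integers(0, 8, 60)
        names = ["Angled only", "Rear only", "Top only", "Angled-rear",
                 "Angled-top", "Top-rear", "All cameras combined"]
        reports = [evaluate_predictions(true, rng.integers(0, 8, 60), name=n)
                   for n in names]
        table = render_report_table(reports)
        body = table.splitlines()[2:]
        assert len(body) == 7
        assert body[-1].startswith("All cameras combined")

    def test_report_serialization_round_trip_stable(self):
        rng = np.random.default_rng(6)
        true = rng.integers(0, 8, 80)
        pred = rng.integers(0, 8, 80)
        a = evaluate_predictions(true, pred).to_dict()
        b = evaluate_predictions(true, pred).to_dict()
        assert a == b

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate_predictions(np.array([1, 2]), np.array([1]))


class TestPredictionsCSV:
    def test_round_trip_preserves_classes_and_report(self, tmp_path):
        from depthbcs.evaluate import load_predictions, save_predictions
        from depthbcs.fusion import PredictionRecord

        rng = np.random.default_rng(7)
        recs = []
        for i in range(30):
            p = rng.dirichlet(np.ones(8))
            recs.append(PredictionRecord(
                cow_id=f"c{i:03d}", per_camera={}, fused=p,
                predicted_class=int(np.argmax(p)),
                true_class=int(rng.integers(0, 8))))
        path = tmp_path / "preds.csv"
        save_predictions(recs, "All cameras combined", path)
        true, pred, df = load_predictions(path)
        np.testing.assert_array_equal(true, [r.true_class for r in recs])
        np.testing.assert_array_equal(pred, [r.predicted_class for r in recs])
        a = evaluate_predictions(true, pred).to_dict()
        b = evaluate_predictions(np.array([r.true_class for r in recs]),
                                 np.array([r.predicted_class for r in recs])).to_dict()
        assert a == b
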