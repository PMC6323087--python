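import numpy as np
import pytest

from msidiscrim import classification as clf
from msidiscrim import synthetic_data as syn
from msidiscrim.io_core import FeatureTable, RoiMask, ValidationError


def _planted_table(n_noise=20, n_pixels=400, d_sep=4.0, seed=0, n_planted=1):
    """Feature table with ``n_planted`` separating features among noise."""
    rng = np.random.default_rng(seed)
    n_cancer = n_pixels // 2
    labels = np.array(
        ["cancer"] * n_cancer + ["epithelium"] * (n_pixels - n_cancer),
        dtype=object,
    )
    rows = [rng.normal(0, 1, n_pixels) + 10 for _ in range(n_noise)]
    planted_idx = []
    for k in range(n_planted):
        sig = rng.normal(0, 1, n_pixels) + 10
        sig[:n_cancer] += d_sep
        planted_idx.append(len(rows))
        rows.append(sig)
    ab = np.clip(np.array(rows), 0, None)
    ids = 1000.0 + 10.0 * np.arange(len(rows))
    return FeatureTable(ids, ab), RoiMask(labels), planted_idx


class TestMetrics:
    def test_weighted_accuracy_consistency_peptide(self):
        assert clf.weighted_accuracy(78.7, 90.7) == pytest.approx(84.7)

    def test_weighted_accuracy_consistency_lipid(self):
        assert clf.weighted_accuracy(56.0, 82.4) == pytest.approx(69.2)

    def test_perfect_predictor(self):
        y = np.array([1, 1, 0, 0], dtype=bool)
        m = clf.compute_metrics(y, y)
        assert m.sensitivity == m.specificity == m.accuracy == 100.0
        assert m.weighted_accuracy == m.precision == m.f_measure == 100.0

    def test_invariants_enforced(self):
        with pytest.raises(AssertionError):
            clf.ValidationMetrics(80.0, 90.0, 85.0, 99.0, 50.0, 61.5)

    def test_single_class_errors(self):
        y = np.ones(4, dtype=bool)
        with pytest.raises(ValidationError):
            clf.compute_metrics(y, y)

    def test_f_measure_harmonic_mean(self):
        y_true = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        y_pred = np.array([1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
        m = clf.compute_metrics(y_true, y_pred)
        expected = 2 * m.precision * m.sensitivity / (m.precision + m.sensitivity)
        assert m.f_measure == pytest.approx(expected)


class TestRandomValidation:
    def test_perfect_feature_selected_first(self):
        table, mask, planted = _planted_table(n_noise=10, seed=1)
        runs = clf.run_random_validation(table, mask, n_iter=1, seed=2)
        assert runs[0].signature[0] == planted[0]

    def test_downsampling_balance(self):
        rng = np.random.default_rng(3)
        labels = np.array(
            ["cancer"] * 400 + ["epithelium"] * 100, dtype=object
        )
        ab = rng.random((5, 500)) + (labels == "cancer") * 0.5
        table = FeatureTable(1000.0 + np.arange(5.0), ab)
        mask = RoiMask(labels)
        runs = clf.run_random_validation(table, mask, n_iter=5, seed=4)
        for run in runs:
            assert run.train_idx.size + run.test_idx.size == 500
            assert np.intersect1d(run.train_idx, run.test_idx).size == 0

    def test_deterministic_under_seed(self):
        table, mask, _ = _planted_table(seed=5)
        a = clf.run_random_validation(table, mask, n_iter=3, seed=6)
        b = clf.run_random_validation(table, mask, n_iter=3, seed=6)
        for ra, rb in zip(a, b):
            assert ra.signature == rb.signature
            np.testing.assert_array_equal(ra.train_idx, rb.train_idx)
            assert (
                ra.test_metrics.weighted_accuracy
                == rb.test_metrics.weighted_accuracy
            )

    def test_minority_too_small_errors(self):
        rng = np.random.default_rng(0)
        labels = np.array(["cancer"] * 5 + ["epithelium"] * 50, dtype=object)
        table = FeatureTable(np.array([1000.0]), rng.random((1, 55)))
        with pytest.raises(ValidationError):
            clf.run_random_validation(table, RoiMask(labels), n_iter=1, seed=1)


class TestScoring:
    def _mk_run(self, it, signature, wacc):
        m = clf.ValidationMetrics(wacc, wacc, wacc, wacc, wacc,
                                  wacc if wacc > 0 else 0.0)
        return clf.ValidationRun(it, np.array([0]), np.array([1]), signature, m)

    def test_always_first_full_accuracy(self):
        table = FeatureTable(1000.0 + np.arange(3.0), np.zeros((3, 4)))
        runs = [self._mk_run(i, [2, 0], 100.0) for i in range(7)]
        scores = clf.score_and_rank_features(runs, table)
        top = scores[0]
        assert top.component_index == 2
        assert top.score == pytest.approx(7.0)  # n_iter x 1.0 x weight 1

    def test_never_selected_scores_zero(self):
        table = FeatureTable(1000.0 + np.arange(3.0), np.zeros((3, 4)))
        runs = [self._mk_run(0, [0], 90.0)]
        scores = clf.score_and_rank_features(runs, table)
        assert scores[-1].score == 0.0
        assert {s.component_index for s in scores} == {0, 1, 2}

    def test_position_weights(self):
        table = FeatureTable(1000.0 + np.arange(2.0), np.zeros((2, 4)))
        runs = [self._mk_run(0, [1, 0], 80.0)]
        scores = clf.score_and_rank_features(runs, table)
        lookup = {s.component_index: s.score for s in scores}
        assert lookup[1] == pytest.approx(0.8 * 1.0)
        assert lookup[0] == pytest.approx(0.8 * 0.5)

    def test_ranks_are_permutation_scores_decreasing(self):
        table, mask, _ = _planted_table(n_noise=8, seed=7)
        runs = clf.run_random_validation(table, mask, n_iter=5, seed=8)
        scores = clf.score_and_rank_features(runs, table)
        ranks = [s.rank for s in scores]
        assert ranks == list(range(len(scores)))
        vals = [s.score for s in scores]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestKnee:
    def test_constructed_knee_at_three(self):
        vals = np.array([10.0, 9.0, 8.0, 1.0, 0.9, 0.8])
        assert clf._knee_index(vals) == 2  # 0-based -> size 3

    def test_flat_scores_degenerate(self):
        assert clf._knee_index(np.full(6, 3.0)) == 0

    def test_phantom_signature_size(self):
        # features individually weak enough that all five contribute
        table, mask, planted = _planted_table(
            n_noise=30, n_pixels=800, d_sep=1.2, seed=9, n_planted=5
        )
        model, runs, scores = clf.train_classifier(table, mask, n_iter=10, seed=10)
        assert 4 <= len(model.component_indices) <= 7


class TestEvaluateAndMap:
    def test_zero_model_probability_half(self):
        table = FeatureTable(np.array([1000.0]), np.ones((1, 6)))
        model = clf.ClassifierModel([0], [1000.0], np.zeros(1), 0.0)
        proba = model.predict_proba(table)
        np.testing.assert_allclose(proba, 0.5)

    def test_probability_map_layout(self):
        table = FeatureTable(np.array([1000.0]), np.ones((1, 4)))
        model = clf.ClassifierModel([0], [1000.0], np.array([0.0]), 2.0)
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        img = clf.probability_map(model, table, coords)
        assert img.shape == (2, 2)
        np.testing.assert_allclose(img, 1 / (1 + np.exp(-2.0)))

    def test_map_respects_unassigned(self):
        table = FeatureTable(np.array([1000.0]), np.ones((1, 4)))
        model = clf.ClassifierModel([0], [1000.0], np.array([1.0]), 0.0)
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        mask = RoiMask(np.array(
            ["cancer", "unassigned", "epithelium", "cancer"], dtype=object
        ))
        img = clf.probability_map(model, table, coords, mask)
        assert np.isnan(img[0, 1])
        assert np.isfinite(img[0, 0])

    def test_label_swap_complement(self):
        table, mask, _ = _planted_table(n_noise=5, seed=11)
        model, _, _ = clf.train_classifier(table, mask, n_iter=3, seed=12)
        swapped = clf.ClassifierModel(
            model.component_indices, model.component_ids,
            -model.coefficients, -model.intercept,
        )
        p = model.predict_proba(table)
        q = swapped.predict_proba(table)
        np.testing.assert_allclose(p + q, 1.0, atol=1e-12)

    def test_phantom_probability_contrast(self):
        table, mask, _ = _planted_table(n_noise=10, seed=13)
        model, _, _ = clf.train_classifier(table, mask, n_iter=5, seed=14)
        proba = model.predict_proba(table)
        assert (
            proba[mask.labels == "cancer"].mean()
            > proba[mask.labels == "epithelium"].mean()
        )


class TestFeatureCorrelations:
    def test_duplicated_feature_reported(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 200)
        table = FeatureTable(
            np.array([1000.0, 1010.0]), np.vstack([a, a]) + 10.0
        )
        df = clf.feature_correlations(table, [0, 1])
        assert df["r"].iloc[0] == pytest.approx(1.0)
        assert bool(df["reported"].iloc[0])

    def test_null_significance_rate(self):
        rng = np.random.default_rng(16)
        n_feat = 15
        table = FeatureTable(
            1000.0 + np.arange(float(n_feat)),
            rng.normal(10, 1, (n_feat, 1000)),
        )
        df = clf.feature_correlations(table, list(range(n_feat)))
        raw_sig = (df["p"] < 0.05).mean()
        assert raw_sig < 0.15  # ~5% expected
        assert not df["reported"].any()  # |r| never near 0.5 under null

    def test_signature_too_small_errors(self):
        table = FeatureTable(np.array([1000.0]), np.ones((1, 5)))
        with pytest.raises(ValidationError):
            clf.feature_correlations(table, [0])

    def test_constant_feature_flagged(self):
        table = FeatureTable(
            np.array([1000.0, 1010.0]),
            np.vstack([np.ones(50), np.random.default_rng(0).random(50)]),
        )
        df = clf.feature_correlations(table, [0, 1])
        assert np.isnan(df["r"].iloc[0])


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        m = clf.ClassifierModel([3, 1], [1030.0, 1010.0],
                                np.array([0.5, -0.2]), 0.1, seed=9,
                                n_iterations=50)
        path = tmp_path / "m.json"
        m.to_json(path)
        back = clf.ClassifierModel.from_json(path)
        assert back.component_indices == [3, 1]
        np.testing.assert_allclose(back.coefficients, m.coefficients)
        assert back.intercept == m.intercept
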