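import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from rpikit import (
    ModelConfig,
    classify,
    cross_validate,
    feature_importance,
    greedy_forward_select,
    load_model,
    normalized_poly_kernel,
    predict_proba,
    save_model,
    train,
)
from rpikit.models import _gram


class TestNormalizedPolyKernel:
    @given(
        hnp.arrays(
            np.float64,
            st.integers(2, 40),
            elements=st.floats(0, 5, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_self_similarity_is_one(self, x):
        assert normalized_poly_kernel(x, x, 2) == pytest.approx(1.0)

    def test_orthonormal_pair_gives_one_quarter(self):
        x = np.array([1.0, 0.0, 0.0])
        y = np.array([0.0, 1.0, 0.0])
        # (0 + 1)^2 / sqrt(2^2 * 2^2)
        assert normalized_poly_kernel(x, y, 2) == pytest.approx(0.25)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(10), rng.random(10)
            assert normalized_poly_kernel(x, y, 2) == pytest.approx(
                normalized_poly_kernel(y, x, 2)
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            normalized_poly_kernel(np.ones(3), np.ones(4), 2)

    def test_gram_matrix_is_symmetric_psd(self):
        rng = np.random.default_rng(1)
        for n in (5, 15, 30):
            X = rng.random((n, 8))
            G = _gram(X, X, 2)
            np.testing.assert_allclose(G, G.T, atol=1e-12)
            eigvals = np.linalg.eigvalsh(G)
            assert eigvals.min() > -1e-8

    def test_range_for_nonnegative_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y = rng.random(6), rng.random(6)
            k = normalized_poly_kernel(x, y, 2)
            assert 0.0 < k <= 1.0 + 1e-12


@pytest.mark.parametrize("family", ["random_forest", "svm"])
class TestTrain:
    def test_separable_toy_training_accuracy(self, toy_separable, family):
        from rpikit import encode_dataset

        cfg = ModelConfig(family=family, seed=0)
        model = train(toy_separable, cfg)
        X, y, _ = encode_dataset(toy_separable)
        preds = classify(predict_proba(model, X), cfg.decision_threshold)
        assert np.array_equal(preds, y)

    def test_deterministic_given_seed(self, planted_small, family):
        _, X, y = planted_small
        probe = X[:10]
        p1 = predict_proba(train(None, ModelConfig(family=family, seed=5), X=X, y=y), probe)
        p2 = predict_proba(train(None, ModelConfig(family=family, seed=5), X=X, y=y), probe)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, family):
        X = np.random.default_rng(0).random((10, 599))
        with pytest.raises(ValueError, match="both classes"):
            train(None, ModelConfig(family=family), X=X, y=np.ones(10, dtype=int))

    def test_probabilities_in_unit_interval(self, planted_small, family):
        _, X, y = planted_small
        model = train(None, ModelConfig(family=family, seed=1), X=X, y=y)
        p = predict_proba(model, X)
        assert np.all((p >= 0) & (p <= 1))


def test_shuffled_labels_give_chance_level_auc(planted_medium):
    """Permutation null: destroying the pair labels destroys the signal."""
    _, X, y = planted_medium
    n = 200  # 100 per class keeps the null CV quick
    X_sub = np.vstack([X[y == 1][:100], X[y == 0][:100]])
    y_sub = np.concatenate([np.ones(100, dtype=int), np.zeros(100, dtype=int)])
    rng = np.random.default_rng(17)
    y_perm = rng.permutation(y_sub)
    report = cross_validate(None, ModelConfig(seed=17), folds=5, X=X_sub, y=y_perm)
    assert 0.4 <= report.auc <= 0.6


class TestPredictProba:
    def test_rf_probability_is_vote_fraction(self, planted_small):
        _, X, y = planted_small
        model = train(None, ModelConfig(seed=3), X=X, y=y)
        p = predict_proba(model, X[:20])
        votes = np.stack(
            [t.predict(X[:20]) for t in model.estimator.estimators_]
        )
        np.testing.assert_allclose(p, votes.mean(axis=0))

    def test_single_tree_probabilities_are_binary(self, planted_small):
        _, X, y = planted_small
        model = train(None, ModelConfig(rf_trees=1, seed=3), X=X, y=y)
        p = predict_proba(model, X)
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_schema_mismatch_rejected(self, planted_small):
        _, X, y = planted_small
        model = train(None, ModelConfig(seed=3), X=X, y=y)
        with pytest.raises(ValueError, match="schema"):
            predict_proba(model, X[:, :100])


class TestClassify:
    @pytest.mark.parametrize(
        "prob,threshold,expected",
        [(0.50, 0.50, 1), (0.49, 0.50, 0), (0.2, 0.0, 1), (1.0, 0.99, 1)],
    )
    def test_threshold_is_inclusive(self, prob, threshold, expected):
        assert classify(np.array([prob]), threshold)[0] == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify(np.array([1.5]))


class TestFeatureImportance:
    def test_svm_unsupported(self, planted_small):
        _, X, y = planted_small
        model = train(None, ModelConfig(family="svm", seed=1), X=X, y=y)
        with pytest.raises(ValueError, match="random_forest"):
            feature_importance(model)

    def test_ranking_covers_all_features(self, planted_small):
        _, X, y = planted_small
        model = train(None, ModelConfig(seed=1), X=X, y=y)
        ranked = feature_importance(model)
        assert len(ranked) == 599
        imps = [v for _, v in ranked]
        assert imps == sorted(imps, reverse=True)

    def test_constant_feature_has_zero_importance(self):
        rng = np.random.default_rng(4)
        X = rng.random((60, 3))
        X[:, 2] = 0.7  # constant column can never split
        y = (X[:, 0] > 0.5).astype(int)
        model = train(
            None, ModelConfig(seed=0, rf_features_per_split=None),
            X=X, y=y, feature_schema=["f0", "f1", "const"],
        )
        imp = dict(feature_importance(model))
        assert imp["const"] == 0.0


class TestGreedyForwardSelect:
    def test_perfect_feature_selected_first_then_stop(self):
        rng = np.random.default_rng(5)
        X = rng.random((40, 5))
        y = (X[:, 3] > 0.5).astype(int)
        X[:, 3] = y  # feature 3 separates perfectly
        selected, trace = greedy_forward_select(
            None, ModelConfig(seed=0, rf_features_per_split=None),
            max_features=4, X=X, y=y,
        )
        assert selected[0] == 3
        assert trace[0] == pytest.approx(1.0)
        assert len(selected) == 1  # no improvement possible after a perfect score

    def test_max_features_zero_rejected(self, planted_small):
        _, X, y = planted_small
        with pytest.raises(ValueError, match="max_features"):
            greedy_forward_select(None, max_features=0, X=X, y=y)

    def test_two_informative_features_found_early(self):
        rng = np.random.default_rng(6)
        n = 80
        X = rng.random((n, 8))
        y = rng.integers(0, 2, size=n)
        # two complementary half-informative features: each predicts the
        # label on its own half of the samples only
        half = rng.random(n) < 0.5
        X[:, 1] = np.where(half, y + rng.random(n) * 0.3, rng.random(n))
        X[:, 6] = np.where(~half, y + rng.random(n) * 0.3, rng.random(n))
        selected, _ = greedy_forward_select(
            None, ModelConfig(seed=0, rf_features_per_split=None),
            max_features=5, X=X, y=y,
        )
        assert {1, 6} <= set(selected[:5])

    def test_trace_is_monotone_nondecreasing(self, planted_small):
        _, X, y = planted_small
        _, trace = greedy_forward_select(
            None, ModelConfig(seed=0), max_features=3,
            X=X, y=y, candidate_features=list(range(0, 599, 40)),
        )
        assert all(b >= a for a, b in zip(trace, trace[1:]))


@pytest.mark.parametrize("family", ["random_forest", "svm"])
def test_save_load_roundtrip(tmp_path, planted_small, family):
    _, X, y = planted_small
    model = train(None, ModelConfig(family=family, seed=2), X=X, y=y)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_array_equal(
        predict_proba(model, X[:50]), predict_proba(back, X[:50])
    )
    assert back.config == model.config


def test_load_corrupted_file_rejected(tmp_path):
    path = tmp_path / "junk.joblib"
    path.write_text("this is not a model")
    with pytest.raises(ValueError, match="model"):
        load_model(path)


def test_calibrated_probabilities_monotone_in_margin(planted_small):
    _, X, y = planted_small
    model = train(None, ModelConfig(family="svm", seed=8), X=X, y=y)
    cal = model.estimator  # CalibratedClassifierCV, ensemble=False
    svm = cal.calibrated_classifiers_[0].estimator
    margins = svm.decision_function(X)
    probs = predict_proba(model, X)
    order = np.argsort(margins)
    assert np.all(np.diff(probs[order]) >= -1e-12)


def test_more_trees_do_not_hurt_held_out_auc(planted_small):
    """Going from 20 to 200 trees must not cost more than 0.05 AUC."""
    _, X, y = planted_small
    auc20 = cross_validate(None, ModelConfig(rf_trees=20, seed=1), folds=5, X=X, y=y).auc
    auc200 = cross_validate(None, ModelConfig(rf_trees=200, seed=1), folds=5, X=X, y=y).auc
    assert auc200 >= auc20 - 0.05
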