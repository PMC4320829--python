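import numpy as np
import pytest

from meadev.features import FEATURE_NAMES
from meadev.ml import (
    evaluate,
    impute_median,
    incremental_performance,
    pca_project,
    train_eval,
)


def toy_data(rng, n=40, shift_col=None, shift=0.0):
    X = rng.normal(0, 1, (n, 11))
    y = np.asarray(["CTX"] * (n // 2) + ["HPC"] * (n - n // 2))
    if shift_col is not None:
        X[y == "HPC", shift_col] += shift
    return X, y


class TestPca:
    def test_single_varying_feature_pc1_full(self):
        rng = np.random.default_rng(0)
        X = np.ones((10, 3))
        X[:, 1] = rng.normal(0, 1, 10)
        with pytest.warns(UserWarning):
            res = pca_project(X, ["a", "b", "c"])
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_duplicated_rows_identical_projections(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (6, 4))
        X = np.vstack([X, X[0]])
        res = pca_project(X, list("abcd"))
        np.testing.assert_allclose(res.projections[0], res.projections[-1], atol=1e-10)

    def test_variance_fractions_sum_and_order(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 11))
        res = pca_project(X)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        assert np.all(res.variance_fractions >= 0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 7))
        res = pca_project(X, [f"f{i}" for i in range(7)])
        Z = (X - X.mean(0)) / X.std(0)
        s = np.linalg.svd(Z - Z.mean(0), compute_uv=False)
        oracle = s**2 / np.sum(s**2)
        np.testing.assert_allclose(res.variance_fractions, oracle, atol=1e-9)

    def test_nan_rejected(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            pca_project(X, list("abc"))

    def test_cumulative_variance(self):
        rng = np.random.default_rng(4)
        res = pca_project(rng.normal(0, 1, (20, 5)), list("abcde"))
        assert res.cumulative_variance[-1] == pytest.approx(1.0, abs=1e-9)


class TestImpute:
    def test_fills_with_reference_median(self):
        X = np.array([[1.0, np.nan], [np.nan, 4.0]])
        ref = np.array([[0.0, 10.0], [2.0, 20.0], [4.0, 30.0]])
        out = impute_median(X, reference=ref)
        np.testing.assert_allclose(out, [[1.0, 20.0], [2.0, 4.0]])

    def test_all_nan_column_falls_back_to_zero(self):
        X = np.array([[np.nan], [np.nan]])
        np.testing.assert_allclose(impute_median(X), [[0.0], [0.0]])


class TestTrainEval:
    def test_separable_feature_perfect(self):
        rng = np.random.default_rng(5)
        X, y = toy_data(rng, shift_col=0, shift=20.0)
        assert train_eval(X, y, "tree_ensemble", split_seed=1, n_trees=50) == 100.0
        # SVM: low-dimensional case so the RBF distance is dominated by
        # the separating feature
        X2 = rng.normal(0, 1, (40, 2))
        X2[y == "HPC", 0] += 20.0
        assert train_eval(X2, y, "svm_rbf", split_seed=1) == 100.0

    def test_deterministic_given_seeds(self):
        rng = np.random.default_rng(6)
        X, y = toy_data(rng)
        a = train_eval(X, y, "tree_ensemble", split_seed=7, model_seed=3, n_trees=50)
        b = train_eval(X, y, "tree_ensemble", split_seed=7, model_seed=3, n_trees=50)
        assert a == b

    def test_single_class_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValueError):
            train_eval(X, np.asarray(["CTX"] * 10))

    def test_unknown_method(self):
        rng = np.random.default_rng(8)
        X, y = toy_data(rng)
        with pytest.raises(ValueError):
            train_eval(X, y, method="xgboost")


class TestEvaluate:
    def test_separable_mean_100(self):
        rng = np.random.default_rng(9)
        X, y = toy_data(rng, shift_col=3, shift=20.0)
        res = evaluate(X, y, "tree_ensemble", n_repeats=20, seed=0, n_trees=50)
        # per-tree feature subsampling leaves a sliver of test error
        assert res.mean_accuracy >= 95.0

    def test_planted_single_feature_gets_top_importance(self):
        rng = np.random.default_rng(10)
        X, y = toy_data(rng, n=60, shift_col=5, shift=10.0)
        res = evaluate(X, y, "tree_ensemble", n_repeats=20, seed=0, n_trees=100)
        assert res.importance_scores[FEATURE_NAMES[5]] == 1.0
        others = [v for k, v in res.importance_scores.items() if k != FEATURE_NAMES[5]]
        assert max(others) < 0.5

    def test_importance_max_exactly_one(self):
        rng = np.random.default_rng(11)
        X, y = toy_data(rng)
        res = evaluate(X, y, "tree_ensemble", n_repeats=10, seed=0, n_trees=50)
        assert max(res.importance_scores.values()) == 1.0
        assert min(res.importance_scores.values()) >= 0.0

    def test_null_near_chance(self):
        rng = np.random.default_rng(12)
        X, y = toy_data(rng, n=40)  # pure noise
        res = evaluate(X, y, "tree_ensemble", n_repeats=100, seed=0, n_trees=50)
        assert abs(res.mean_accuracy - 50.0) < 15.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(13)
        X, y = toy_data(rng, shift_col=2, shift=5.0)
        y_perm = rng.permutation(y)
        res = evaluate(X, y_perm, "svm_rbf", n_repeats=100, seed=0)
        assert abs(res.mean_accuracy - 50.0) < 15.0

    def test_reproducible(self):
        rng = np.random.default_rng(14)
        X, y = toy_data(rng)
        a = evaluate(X, y, "tree_ensemble", n_repeats=10, seed=5, n_trees=50)
        b = evaluate(X, y, "tree_ensemble", n_repeats=10, seed=5, n_trees=50)
        assert a.mean_accuracy == b.mean_accuracy
        assert a.importance_scores == b.importance_scores

    def test_svm_has_no_importance(self):
        rng = np.random.default_rng(15)
        X, y = toy_data(rng)
        assert evaluate(X, y, "svm_rbf", n_repeats=5, seed=0).importance_scores is None

    def test_ranking_invariant_to_column_permutation(self):
        rng = np.random.default_rng(16)
        X, y = toy_data(rng, n=60, shift_col=5, shift=10.0)
        res = evaluate(X, y, "tree_ensemble", n_repeats=10, seed=0, n_trees=100)
        perm = rng.permutation(11)
        res_p = evaluate(
            X[:, perm], y, "tree_ensemble", n_repeats=10, seed=0, n_trees=100,
            feature_names=[FEATURE_NAMES[i] for i in perm],
        )
        top = max(res.importance_scores, key=res.importance_scores.get)
        top_p = max(res_p.importance_scores, key=res_p.importance_scores.get)
        assert top == top_p == FEATURE_NAMES[5]


class TestIncremental:
    def test_k_full_matches_evaluate(self):
        rng = np.random.default_rng(17)
        X, y = toy_data(rng, shift_col=1, shift=3.0)
        ranking = list(FEATURE_NAMES)
        table = incremental_performance(X, y, ranking, n_repeats=10, seed=2, n_trees=50)
        full = evaluate(X, y, "tree_ensemble", n_repeats=10, seed=2, n_trees=50)
        assert len(table) == 11
        assert table.iloc[-1]["accuracy"] == pytest.approx(full.mean_accuracy)

    def test_noise_top_feature_near_chance(self):
        rng = np.random.default_rng(18)
        X, y = toy_data(rng, n=60)
        table = incremental_performance(
            X, y, [FEATURE_NAMES[0]], n_repeats=50, seed=0, n_trees=50
        )
        assert abs(table.iloc[0]["accuracy"] - 50.0) < 15.0

    def test_informative_features_accumulate(self):
        rng = np.random.default_rng(19)
        X, y = toy_data(rng, n=80)
        for col, s in ((0, 0.8), (1, 0.8), (2, 0.8)):
            X[y == "HPC", col] += s
        ranking = [FEATURE_NAMES[i] for i in (0, 1, 2)]
        table = incremental_performance(X, y, ranking, n_repeats=30, seed=1, n_trees=100)
        assert table.iloc[2]["accuracy"] > table.iloc[0]["accuracy"]

    def test_unknown_feature_in_ranking(self):
        rng = np.random.default_rng(20)
        X, y = toy_data(rng)
        with pytest.raises(ValueError):
            incremental_performance(X, y, ["bogus"], n_repeats=2)
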