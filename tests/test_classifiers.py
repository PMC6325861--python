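"""Classifier families: convergence, closed forms, oracles, serialization."""

import itertools

import numpy as np
import pytest

from hpscore.classifiers import (
    KernelSpec,
    PerceptronConfig,
    fit_bernoulli_naive_bayes,
    fit_decision_tree,
    fit_pocket_perceptron,
    fit_svm_smo,
    model_from_dict,
)
from hpscore.evaluation import SplitPlan, stratified_kfold_cv
from hpscore.pipeline import classifier_factory

from conftest import make_dataset

ALL_VECTORS = np.array(list(itertools.product([0, 1], repeat=9)), dtype=np.int8)


def two_point_dataset():
    return make_dataset([[1] * 9, [0] * 9], y=[1, 0])


class TestPocketPerceptron:
    def test_reaches_perfect_accuracy_on_separable_data(self):
        model = fit_pocket_perceptron(
            two_point_dataset(), PerceptronConfig(eta=0.2, n_iterations=1000)
        )
        assert model.training_accuracy == 1.0
        assert model.predict(np.eye(9, dtype=np.int8) * 0).tolist() == [0] * 9

    def test_zero_iterations_returns_initial_random_weights(self):
        cfg = PerceptronConfig(n_iterations=0, seed=123)
        model = fit_pocket_perceptron(two_point_dataset(), cfg)
        expected = np.random.default_rng(123).standard_normal(9)
        assert np.allclose(model.weights, expected)

    def test_pocket_accuracy_trace_is_non_decreasing(self, default_dataset):
        model = fit_pocket_perceptron(
            default_dataset, PerceptronConfig(n_iterations=1000, seed=5)
        )
        trace = np.array(model.accuracy_trace)
        assert len(trace) == 1000
        assert np.all(np.diff(trace) >= 0)
        assert model.training_accuracy == trace[-1]

    def test_bias_variant_handles_shifted_threshold(self):
        # all-zero positives are unclassifiable without a bias term
        data = make_dataset([[0] * 9, [1] * 9], y=[1, 0])
        cfg = PerceptronConfig(n_iterations=500, include_bias=True, seed=2)
        model = fit_pocket_perceptron(data, cfg)
        assert model.training_accuracy == 1.0

    def test_deterministic_given_seed(self, default_dataset):
        cfg = PerceptronConfig(seed=9)
        a = fit_pocket_perceptron(default_dataset, cfg)
        b = fit_pocket_perceptron(default_dataset, cfg)
        assert np.array_equal(a.weights, b.weights)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PerceptronConfig(eta=0.0)
        with pytest.raises(ValueError):
            fit_pocket_perceptron(make_dataset(np.zeros((0, 9))))


class TestBernoulliNaiveBayes:
    def test_symmetric_tie_breaks_negative(self):
        data = make_dataset([[1] + [0] * 8, [0] * 8 + [1]], y=[1, 0])
        model = fit_bernoulli_naive_bayes(data)
        query = np.zeros((1, 9), dtype=np.int8)
        post = model.posterior(query)
        assert np.allclose(post, 0.5)
        assert model.predict(query)[0] == 0

    def test_posteriors_match_hand_computed_closed_form(self):
        # 4 rows, alpha=1: every conditional is (count+1)/(n_c+2)
        X = [[1, 1, 0, 0, 0, 0, 0, 0, 0],
             [1, 0, 0, 0, 0, 0, 0, 0, 0],
             [0, 0, 1, 0, 0, 0, 0, 0, 0],
             [0, 0, 0, 0, 0, 0, 0, 0, 0]]
        y = [1, 1, 0, 0]
        model = fit_bernoulli_naive_bayes(make_dataset(X, y=y), laplace_alpha=1.0)
        q = np.array([[1, 0, 0, 0, 0, 0, 0, 0, 0]])

        def lik(p1_counts, n_c, bits):
            out = 0.5  # prior
            for j in range(9):
                p1 = (p1_counts[j] + 1.0) / (n_c + 2.0)
                out *= p1 if bits[j] else (1.0 - p1)
            return out

        pos = lik([2, 1, 0, 0, 0, 0, 0, 0, 0], 2, q[0])
        neg = lik([0, 0, 1, 0, 0, 0, 0, 0, 0], 2, q[0])
        expected = pos / (pos + neg)
        assert abs(model.posterior(q)[0, 1] - expected) < 1e-12

    def test_alpha_zero_zero_probability_short_circuit(self):
        X = [[1] + [0] * 8, [0] * 9]
        model = fit_bernoulli_naive_bayes(make_dataset(X, y=[1, 0]),
                                          laplace_alpha=0.0)
        pred = model.predict(np.array([[1] + [0] * 8, [0] * 9]))
        assert pred.tolist() == [1, 0]

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            fit_bernoulli_naive_bayes(two_point_dataset(), laplace_alpha=-0.1)

    def test_agrees_with_sklearn_reference(self, default_dataset):
        sklearn = pytest.importorskip("sklearn.naive_bayes")
        model = fit_bernoulli_naive_bayes(default_dataset, laplace_alpha=1.0)
        ref = sklearn.BernoulliNB(alpha=1.0).fit(
            default_dataset.X, default_dataset.y
        )
        assert np.array_equal(model.predict(ALL_VECTORS),
                              ref.predict(ALL_VECTORS))
        mine = model.joint_log_likelihood(ALL_VECTORS)
        theirs = ref._joint_log_likelihood(ALL_VECTORS)
        assert np.allclose(mine, theirs, atol=1e-10)


class TestDecisionTree:
    def test_single_predictive_feature_gives_depth_one_tree(self):
        X = np.zeros((8, 9), dtype=np.int8)
        X[:4, 2] = 1
        data = make_dataset(X, y=[1, 1, 1, 1, 0, 0, 0, 0])
        tree = fit_decision_tree(data)
        assert tree.depth() == 1
        assert tree.root.feature == 2
        assert tree.training_accuracy == 1.0

    def test_pure_dataset_gives_single_leaf(self):
        data = make_dataset([[1, 0] + [0] * 7, [0] * 9], y=[1, 1])
        tree = fit_decision_tree(data)
        assert tree.depth() == 0
        assert tree.root.prediction == 1

    def test_xor_of_two_features_solved_at_depth_two(self):
        X = np.zeros((4, 9), dtype=np.int8)
        X[:, 0] = [0, 0, 1, 1]
        X[:, 1] = [0, 1, 0, 1]
        data = make_dataset(X, y=[0, 1, 1, 0])
        tree = fit_decision_tree(data, min_leaf=1)
        assert tree.training_accuracy == 1.0
        assert tree.depth() == 2

    def test_min_leaf_validation(self):
        with pytest.raises(ValueError):
            fit_decision_tree(two_point_dataset(), min_leaf=0)

    def test_leaf_tie_goes_to_negative_class(self):
        data = make_dataset([[0] * 9, [0] * 9], y=[1, 0])
        tree = fit_decision_tree(data)
        assert tree.predict(np.zeros((1, 9), dtype=np.int8))[0] == 0


class TestSvmSmo:
    def test_two_point_analytic_solution(self):
        model = fit_svm_smo(two_point_dataset(), kernel=KernelSpec("linear"))
        assert model.predict(np.array([[1] * 9]))[0] == 1
        assert model.predict(np.array([[0] * 9]))[0] == 0
        # analytic solution: w = (2/9) 1, b = -1; boundary at sum(x) = 4.5
        boundary = np.full((1, 9), 0.5)
        assert abs(model.decision_values(boundary)[0]) < 1e-6

    def test_dual_constraints_hold_at_convergence(self, default_dataset):
        C = 1.0
        model = fit_svm_smo(default_dataset, C=C)
        alphas = model.alphas_
        y = default_dataset.y.astype(float) * 2 - 1
        assert np.all(alphas >= -1e-9) and np.all(alphas <= C + 1e-9)
        assert abs(float(alphas @ y)) < 1e-8

    def test_single_class_training_rejected(self):
        data = make_dataset([[1] * 9, [0] * 9], y=[1, 1])
        with pytest.raises(ValueError):
            fit_svm_smo(data)

    @pytest.mark.parametrize("kernel", [
        KernelSpec("linear"),
        KernelSpec("poly", degree=2),
        KernelSpec("rbf", gamma=0.5),
        KernelSpec("normalized_poly", degree=2),
    ], ids=lambda k: k.name)
    def test_predictions_match_qp_solver_on_small_data(self, kernel):
        from scipy.optimize import LinearConstraint, minimize
        rng = np.random.default_rng(0)
        X = (rng.random((20, 9)) < 0.5).astype(np.int8)
        y01 = np.array([1] * 10 + [0] * 10, dtype=np.int8)
        data = make_dataset(X, y=y01)
        model = fit_svm_smo(data, kernel=kernel, C=1.0, tol=1e-4)

        y = y01.astype(float) * 2 - 1
        K = kernel.gram(X, X)
        Q = (y[:, None] * y[None, :]) * K

        def neg_dual(a):
            return 0.5 * a @ Q @ a - a.sum()

        res = minimize(
            neg_dual, np.zeros(20), jac=lambda a: Q @ a - 1,
            bounds=[(0.0, 1.0)] * 20,
            constraints=[LinearConstraint(y, 0.0, 0.0)],
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
        )
        assert res.success
        a = res.x
        free = (a > 1e-6) & (a < 1.0 - 1e-6)
        f_no_b = (a * y) @ K
        b = np.mean(y[free] - f_no_b[free])
        oracle_dec = f_no_b + b
        model_dec = model.decision_values(X)
        # same optimum of the dual ...
        am = model.alphas_
        # SMO stops at a KKT tolerance, so allow a commensurate gap in the
        # objective and in the offset-sensitive decision values
        assert abs((0.5 * am @ Q @ am - am.sum()) - res.fun) < 1e-3
        assert np.allclose(model_dec, oracle_dec, atol=2e-2)
        # ... and identical labels wherever the decision is not a near-tie
        decided = np.abs(oracle_dec) > 2e-2
        assert np.array_equal(model.predict(X)[decided],
                              (oracle_dec > 0).astype(int)[decided])


@pytest.mark.parametrize("family", ["perceptron", "naive_bayes",
                                    "decision_tree", "svm"])
class TestSharedContract:
    def test_serialization_round_trips_all_512_inputs(
        self, family, default_dataset
    ):
        model = classifier_factory(family, seed=0)(default_dataset)
        clone = model_from_dict(model.to_dict())
        assert np.array_equal(model.predict(ALL_VECTORS),
                              clone.predict(ALL_VECTORS))

    def test_training_accuracy_at_least_majority_baseline(self, family):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            X = (rng.random((60, 9)) < 0.5).astype(np.int8)
            y = (rng.random(60) < 0.4).astype(np.int8)
            data = make_dataset(X, y=y)
            model = classifier_factory(family, seed=seed)(data)
            baseline = max(y.mean(), 1 - y.mean())
            assert model.training_accuracy >= baseline - 1e-12

    def test_perfect_cv_on_fully_separated_profile(
        self, family, separated_dataset
    ):
        _, pooled = stratified_kfold_cv(
            separated_dataset, classifier_factory(family, seed=0),
            SplitPlan(seed=0),
        )
        assert pooled.accuracy == 1.0
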