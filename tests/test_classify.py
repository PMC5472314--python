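import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitdrift import (
    KBDRClassifier,
    KernelParams,
    LinearSVMClassifier,
    fit_kbdr_binary,
    fit_linear_svm_binary,
    poly_kernel,
    proximal_point_solve,
)
from gaitdrift.classify import (
    KBDR_ALPHA_GRID,
    KBDR_BETA_GRID,
    KBDR_EXP_GRID,
    SVM_C_GRID,
    signed_power,
    svm_objective,
)


class TestPolyKernel:
    def test_zero_vectors_with_offset_one_degree_two(self):
        p = KernelParams(exp=2.0, alpha=1e-5, beta=1.0)
        assert poly_kernel(np.zeros(3), np.zeros(3), p) == 1.0

    def test_linear_case(self):
        p = KernelParams(exp=1.0, beta=1.0)
        x = np.array([1.0, 1.0, 1.0])
        z = np.array([1.0, 1.0, 1.0])
        assert poly_kernel(x, z, p) == pytest.approx(4.0)

    def test_signed_power_extension_is_odd_and_continuous(self):
        p = 0.5
        s = np.array([-4.0, -1e-12, 0.0, 1e-12, 4.0])
        out = signed_power(s, p)
        assert out[0] == -2.0 and out[-1] == 2.0
        assert abs(out[1]) < 1e-5 and out[2] == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, z = rng.normal(size=5), rng.normal(size=5)
        p = KernelParams(exp=1.7, beta=0.3)
        assert poly_kernel(x, z, p) == pytest.approx(poly_kernel(z, x, p))

    def test_grids_match_design(self):
        # exp and beta grids follow the same 1-3-per-decade convention,
        # with exp reaching its printed endpoint 3
        assert KBDR_EXP_GRID == (0.1, 0.3, 1.0, 3.0)
        assert KBDR_ALPHA_GRID == (1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
        assert KBDR_BETA_GRID == (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
        assert len(SVM_C_GRID) == 81
        assert SVM_C_GRID[0] == 2.0**-5 and SVM_C_GRID[-1] == 2.0**15


class TestProximalPoint:
    def test_zero_target_returns_zero(self):
        K = np.eye(4)
        c = proximal_point_solve(K, np.zeros(4), alpha=0.1)
        np.testing.assert_array_equal(c, 0.0)

    def test_identity_kernel_no_ridge_recovers_target(self):
        y = np.array([1.0, -2.0, 0.5])
        c = proximal_point_solve(np.eye(3), y, alpha=0.0)
        np.testing.assert_allclose(c, y, atol=1e-8)

    def test_fixed_point_matches_direct_solve(self, rng):
        n = 12
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        y = rng.choice([-1.0, 1.0], size=n)
        alpha = 1e-4
        direct = np.linalg.solve(K.T @ K + alpha * np.eye(n), K.T @ y)
        prox = proximal_point_solve(K, y, alpha)
        assert np.max(np.abs(direct - prox)) < 1e-6

    def test_nonconvergence_signals_with_residual(self):
        from gaitdrift.classify import ConvergenceError

        K = np.eye(3)
        with pytest.raises(ConvergenceError) as err:
            proximal_point_solve(K, np.ones(3), alpha=0.0, step_lambda=50.0,
                                 tol=1e-14, max_iter=3)
        assert err.value.residual >= 0.0

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            proximal_point_solve(np.eye(2), np.ones(2), 0.1, step_lambda=0.0)


class TestKbdr:
    def test_separated_points_sign_correct(self):
        X = np.array([[5.0, 0.0], [-5.0, 0.0]])
        y = np.array([1, -1])
        model = fit_kbdr_binary(X, y, KernelParams(exp=1.0, alpha=1e-6, beta=1.0))
        assert list(model.predict(X)) == [1, -1]

    def test_huge_ridge_shrinks_coefficients_to_zero(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.choice([-1, 1], size=10)
        model = fit_kbdr_binary(X, y, KernelParams(exp=1.0, alpha=1e12, beta=1.0))
        assert np.max(np.abs(model.dual_coef_)) < 1e-6
        assert np.max(np.abs(model.decision_function(X))) < 1e-3

    def test_solvers_agree_on_random_problem(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.choice([-1, 1], size=20)
        params = KernelParams(exp=1.5, alpha=1e-4, beta=0.3)
        direct = KBDRClassifier(params, solver="direct").fit(X, y)
        prox = KBDRClassifier(params, solver="proximal_point").fit(X, y)
        assert np.max(np.abs(direct.dual_coef_ - prox.dual_coef_)) < 1e-6

    def test_degree_one_equals_ridge_on_kernel_design(self, rng):
        """(K^T K + aI)c = K^T y is ridge regression with design matrix K."""
        from sklearn.linear_model import Ridge

        X = rng.normal(size=(15, 6))
        y = rng.choice([-1, 1], size=15)
        params = KernelParams(exp=1.0, alpha=1e-3, beta=1.0)
        model = fit_kbdr_binary(X, y, params)
        K = poly_kernel(X, X, params)
        ref = Ridge(alpha=params.alpha, fit_intercept=False, tol=1e-12)
        ref.fit(K, np.where(y == model.classes_[1], 1.0, -1.0))
        np.testing.assert_allclose(model.dual_coef_[1], ref.coef_, atol=1e-8)

    def test_training_point_recovered_in_interpolation_regime(self, rng):
        # d > n keeps the linear-kernel Gram full rank, so the tiny-ridge
        # model interpolates its +-1 indicator targets
        X = rng.normal(size=(12, 30)) * 3
        y = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        model = KBDRClassifier(KernelParams(exp=1.0, alpha=1e-8, beta=1.0)).fit(X, y)
        assert list(model.predict(X)) == list(y)

    def test_binary_ova_argmax_equals_sign_of_discriminant(self, rng):
        X = rng.normal(size=(14, 3))
        y = rng.choice([-1, 1], size=14)
        model = KBDRClassifier(KernelParams(exp=1.3, alpha=1e-4, beta=0.5)).fit(X, y)
        scores = model.decision_function(X)
        # mirrored targets: f_{+1} = -f_{-1}, so argmax == sign of either
        np.testing.assert_allclose(scores[:, 0], -scores[:, 1], atol=1e-8)
        preds = model.predict(X)
        np.testing.assert_array_equal(preds, np.where(scores[:, 1] > 0, 1, -1))

    def test_three_distant_clusters_fully_separated(self, rng):
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        X = np.vstack([c + rng.normal(0, 0.1, size=(5, 2)) for c in centers])
        y = np.repeat(["c0", "c1", "c2"], 5)
        model = KBDRClassifier(KernelParams(exp=1.0, alpha=1e-6, beta=1.0)).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0
        # brute-force nearest-cluster oracle agrees
        d = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
        oracle = np.array(["c0", "c1", "c2"])[np.argmin(d, axis=1)]
        np.testing.assert_array_equal(model.predict(X), oracle)

    def test_row_permutation_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(18, 5))
        y = rng.choice(["s1", "s2", "s3"], size=18)
        while len(np.unique(y)) < 3:
            y = rng.choice(["s1", "s2", "s3"], size=18)
        Q = rng.normal(size=(7, 5))
        params = KernelParams(exp=1.9, alpha=1e-5, beta=0.1)
        base = KBDRClassifier(params).fit(X, y).predict(Q)
        perm = rng.permutation(18)
        shuffled = KBDRClassifier(params).fit(X[perm], y[perm]).predict(Q)
        np.testing.assert_array_equal(base, shuffled)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        y = np.array([1, 1, 1, -1, -1, -1])
        model = KBDRClassifier().fit(X, y)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 5)))

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.choice([-1, 1], size=8)
        model = KBDRClassifier(KernelParams(exp=0.7, alpha=1e-5, beta=3.0)).fit(X, y)
        back = KBDRClassifier.from_json(model.to_json())
        Q = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            model.decision_function(Q), back.decision_function(Q), atol=1e-12
        )


class TestLinearSvm:
    def test_separable_pair_classified(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, -1.0])
        w = fit_linear_svm_binary(X, y, cost=100.0)
        assert np.sign(X @ w[:-1] + w[-1]).tolist() == [1.0, -1.0]

    def test_vanishing_cost_shrinks_weights(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.choice([-1.0, 1.0], size=20)
        w = fit_linear_svm_binary(X, y, cost=1e-9)
        assert np.linalg.norm(w) < 1e-3

    @pytest.mark.parametrize("cost", [0.01, 1.0, 100.0])
    def test_objective_matches_liblinear_reference(self, rng, cost):
        """Our primal solution matches sklearn's squared-hinge LinearSVC
        objective to 1e-4 relative (bias augmented and regularised in both)."""
        from sklearn.svm import LinearSVC

        X = rng.normal(size=(40, 10))
        w_true = rng.normal(size=10)
        y = np.sign(X @ w_true + 0.1 * rng.normal(size=40))
        Xa = np.hstack([X, np.ones((40, 1))])
        w = fit_linear_svm_binary(X, y, cost=cost)
        ref = LinearSVC(
            C=cost, loss="squared_hinge", fit_intercept=True,
            intercept_scaling=1.0, tol=1e-12, max_iter=200000,
        ).fit(X, y)
        w_ref = np.append(ref.coef_.ravel(), ref.intercept_)
        ours = svm_objective(w, Xa, y, cost)
        theirs = svm_objective(w_ref, Xa, y, cost)
        assert ours <= theirs * (1 + 1e-4)
        assert abs(ours - theirs) / theirs < 1e-3

    def test_span_and_primal_routes_agree(self, rng):
        # n < d exercises the span route; duplicating rows forces primal
        X = rng.normal(size=(8, 20))
        y = rng.choice([-1.0, 1.0], size=8)
        w_span = fit_linear_svm_binary(X, y, cost=2.0)
        X2 = np.vstack([X, X, X])
        y2 = np.concatenate([y, y, y])
        Xa2 = np.hstack([X2, np.ones((24, 1))])
        w_primal = fit_linear_svm_binary(X2, y2, cost=2.0 / 3.0)
        # tripled data with C/3 has the same objective: solutions must agree
        np.testing.assert_allclose(w_span, w_primal, atol=1e-4)

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            LinearSVMClassifier(1.0).fit(X, np.array([1, -1]))

    def test_multiclass_ova_and_json_round_trip(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([c + rng.normal(0, 0.2, size=(6, 2)) for c in centers])
        y = np.repeat([0, 1, 2], 6)
        model = LinearSVMClassifier(cost=10.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0
        back = LinearSVMClassifier.from_json(model.to_json())
        np.testing.assert_array_equal(model.predict(X), back.predict(X))

    def test_deterministic_given_data(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.choice([-1.0, 1.0], size=15)
        w1 = fit_linear_svm_binary(X, y, cost=3.0)
        w2 = fit_linear_svm_binary(X, y, cost=3.0)
        np.testing.assert_array_equal(w1, w2)
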