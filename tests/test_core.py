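"""Kernel, dual objective, projection, model extraction and exact solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import fireflysvm as f
from fireflysvm.core import (
    GRID_LOG2C_EXPONENTS,
    GRID_LOG2GAMMA_EXPONENTS,
    decision_values,
    grid_search,
    predict_many,
)
from fireflysvm.types import DegenerateModelError

from conftest import random_feasible_alpha


class TestRbfKernel:
    def test_zero_distance_and_zero_width_give_one(self):
        x = np.array([1.2, -3.0])
        assert f.rbf_kernel(x, x, 3.7) == 1.0
        assert f.rbf_kernel(x, np.array([0.0, 5.0]), 0.0) == 1.0

    def test_closed_form_value(self):
        # exp(-0.5 * ||(0,0)-(1,1)||^2) = e^-1
        k = f.rbf_kernel(np.zeros(2), np.ones(2), 0.5)
        assert k == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, z = rng.normal(size=3), rng.normal(size=3)
            g = rng.uniform(0, 5)
            kxz = f.rbf_kernel(x, z, g)
            assert kxz == pytest.approx(f.rbf_kernel(z, x, g))
            assert 0.0 < kxz <= 1.0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            f.rbf_kernel(np.zeros(2), np.zeros(3), 1.0)

    def test_gram_matrix_is_psd(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        K = f.rbf_gram(X, 0.8)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestDualObjective:
    def test_zero_alpha_gives_zero(self, blobs20):
        assert f.dual_objective(np.zeros(blobs20.n), 1.0, blobs20) == 0.0

    def test_two_point_hand_expansion(self, two_point_toy):
        val = f.dual_objective(np.array([1.0, 1.0]), np.log(2.0), two_point_toy)
        assert val == pytest.approx(1.5, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        data = f.generate(f.SynthSpec(n_per_class=4, separation=2.0, seed=5))
        alpha = rng.uniform(0, 2, size=data.n)
        gamma = 0.7
        # independent O(n^2) evaluation
        expected = alpha.sum()
        for i in range(data.n):
            for j in range(data.n):
                expected -= 0.5 * (
                    alpha[i] * alpha[j] * data.y[i] * data.y[j]
                    * np.exp(-gamma * np.sum((data.X[i] - data.X[j]) ** 2))
                )
        assert f.dual_objective(alpha, gamma, data) == pytest.approx(expected, abs=1e-10)


class TestProjectFeasible:
    def test_feasible_input_unchanged(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        alpha = np.array([0.3, 0.3, 0.2, 0.2])
        out = f.project_feasible(alpha, 1.0, y)
        np.testing.assert_array_equal(out, alpha)

    def test_two_point_euclidean_projection(self):
        out = f.project_feasible(np.array([1.0, 0.0]), 1.0, np.array([1.0, -1.0]))
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-12)

    def test_matches_qp_projection_oracle(self):
        """Euclidean projection cross-checked against an SLSQP solve of
        min ||a - a0||^2 s.t. box and equality (both land on the set;
        the alternating projection need not be the nearest point, but on
        interior cases the hyperplane step is exact, so compare there)."""
        rng = np.random.default_rng(2)
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        C = 2.0
        a0 = rng.uniform(0.2, 1.8, size=6)  # interior: one shift suffices
        res = minimize(
            lambda a: np.sum((a - a0) ** 2), x0=np.clip(a0, 0, C),
            bounds=[(0, C)] * 6,
            constraints={"type": "eq", "fun": lambda a: a @ y},
            method="SLSQP",
        )
        out = f.project_feasible(a0, C, y, feas_tol=1e-10)
        np.testing.assert_allclose(out, res.x, atol=1e-6)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_postconditions_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        y = rng.choice([-1.0, 1.0], size=n)
        if abs(y.sum()) == n:  # single-class label vector: flip one
            y[0] = -y[0]
        C = float(2.0 ** rng.uniform(-5, 8))
        tol = f.core.default_feas_tol(n, C)
        a = rng.uniform(-0.5 * C, 1.5 * C, size=n)
        out = f.project_feasible(a, C, y)
        assert np.all(out >= 0) and np.all(out <= C)
        assert abs(out @ y) <= tol
        again = f.project_feasible(out, C, y)
        np.testing.assert_allclose(again, out, atol=1e-12)


class TestBuildModelAndPrediction:
    def test_single_sv_count(self, blobs20):
        alpha = np.zeros(blobs20.n)
        alpha[0] = 0.5
        sol = f.SolutionString(alpha=alpha, log2C=0.0, log2gamma=0.0)
        model = f.build_model(sol, blobs20)
        assert model.n_sv == 1

    def test_two_point_toy_bias_zero(self, two_point_toy):
        sol = f.SolutionString(
            alpha=np.array([2.0, 2.0]),
            log2C=np.log2(10.0),
            log2gamma=np.log2(np.log(2.0)),
        )
        model = f.build_model(sol, two_point_toy)
        assert model.bias == pytest.approx(0.0, abs=1e-12)

    def test_no_sv_raises(self, blobs20):
        sol = f.SolutionString(alpha=np.zeros(blobs20.n), log2C=0.0, log2gamma=0.0)
        with pytest.raises(DegenerateModelError):
            f.build_model(sol, blobs20)

    def test_bias_finite_and_alphas_boxed(self, blobs20):
        rng = np.random.default_rng(5)
        C = 4.0
        alpha = random_feasible_alpha(rng, blobs20.y, C)
        sol = f.SolutionString(alpha=alpha, log2C=2.0, log2gamma=-1.0)
        model = f.build_model(sol, blobs20)
        assert np.isfinite(model.bias)
        assert np.all(model.sv_alpha <= C + 1e-12)

    def test_label_flip_antisymmetry(self, blobs20):
        sol = f.smo_solve(blobs20, C=4.0, gamma_kernel=0.5)
        model = f.build_model(sol, blobs20)
        flipped = f.SVMModel(
            sv_features=model.sv_features, sv_alpha=model.sv_alpha,
            sv_labels=-model.sv_labels, bias=-model.bias,
            gamma_kernel=model.gamma_kernel, C=model.C,
        )
        grid = np.random.default_rng(0).normal(size=(15, blobs20.d))
        np.testing.assert_allclose(
            decision_values(flipped, grid), -decision_values(model, grid),
            atol=1e-12,
        )

    def test_kkt_margin_at_free_support_vectors(self, blobs_overlap):
        C, gamma = 2.0, 0.5
        sol = f.smo_solve(blobs_overlap, C, gamma, tol=1e-10)
        model = f.build_model(sol, blobs_overlap)
        free = (sol.alpha > 1e-6 * C) & (sol.alpha < C * (1 - 1e-6))
        assert free.any()
        fvals = decision_values(model, blobs_overlap.X[free])
        np.testing.assert_allclose(fvals, blobs_overlap.y[free], atol=1e-6)

    def test_tie_maps_to_plus_one(self):
        model = f.SVMModel(
            sv_features=np.zeros((1, 1)), sv_alpha=np.array([1.0]),
            sv_labels=np.array([1.0]), bias=-1.0, gamma_kernel=1.0, C=1.0,
        )
        # decision value at the SV itself: 1*1*1 + (-1) = 0 -> +1
        assert f.predict(model, np.zeros(1)) == 1


class TestSmoSolve:
    def test_two_point_analytic_optimum(self, two_point_toy):
        sol = f.smo_solve(two_point_toy, C=10.0, gamma_kernel=np.log(2.0))
        np.testing.assert_allclose(sol.alpha, [2.0, 2.0], atol=1e-6)
        assert sol.brightness == pytest.approx(2.0, abs=1e-6)

    def test_two_point_box_clipped(self, two_point_toy):
        sol = f.smo_solve(two_point_toy, C=1.0, gamma_kernel=np.log(2.0))
        np.testing.assert_allclose(sol.alpha, [1.0, 1.0], atol=1e-9)
        assert sol.brightness == pytest.approx(1.5, abs=1e-9)

    def test_matches_general_qp_solver(self):
        """On random n=20 problems the SMO optimum matches an SLSQP solve
        of the same concave QP to 1e-6."""
        for seed in range(3):
            data = f.generate(f.SynthSpec(n_per_class=10, separation=2.0, seed=seed))
            C, gamma = 3.0, 0.6
            K = f.rbf_gram(data.X, gamma)
            y = data.y.astype(float)
            Q = np.outer(y, y) * K

            def neg_dual(a):
                return -(a.sum() - 0.5 * a @ Q @ a)

            res = minimize(
                neg_dual, x0=np.full(data.n, C / 2),
                jac=lambda a: -(1.0 - Q @ a),
                bounds=[(0, C)] * data.n,
                constraints={"type": "eq", "fun": lambda a: a @ y,
                             "jac": lambda a: y},
                method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
            )
            sol = f.smo_solve(data, C, gamma, tol=1e-10)
            assert sol.brightness == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_reference_svm_library(self, blobs_overlap):
        """Independent cross-check of the trained machine against the
        sklearn RBF SVC at identical (C, gamma)."""
        from sklearn.svm import SVC

        C, gamma = 2.0, 0.7
        sol = f.smo_solve(blobs_overlap, C, gamma, tol=1e-10)
        model = f.build_model(sol, blobs_overlap)
        ref = SVC(C=C, gamma=gamma, tol=1e-8).fit(blobs_overlap.X, blobs_overlap.y)
        grid = np.random.default_rng(1).normal(size=(40, 2)) * 2
        np.testing.assert_allclose(
            decision_values(model, grid), ref.decision_function(grid), atol=1e-4
        )

    def test_feasibility_of_solution(self, blobs20):
        C = 5.0
        sol = f.smo_solve(blobs20, C, 1.0)
        assert np.all(sol.alpha >= -1e-12) and np.all(sol.alpha <= C + 1e-12)
        assert abs(sol.alpha @ blobs20.y) <= 1e-8 * blobs20.n * C

    def test_size_guard(self):
        big = f.Dataset(np.zeros((2001, 1)), np.array([1, -1] * 1000 + [1]))
        with pytest.raises(ValueError):
            f.smo_solve(big, 1.0, 1.0)


class TestGridSearch:
    def test_exponent_ranges_and_count(self):
        assert GRID_LOG2C_EXPONENTS[0] == -15 and GRID_LOG2C_EXPONENTS[-1] == 15
        assert GRID_LOG2GAMMA_EXPONENTS[0] == -5 and GRID_LOG2GAMMA_EXPONENTS[-1] == 5
        assert len(GRID_LOG2C_EXPONENTS) * len(GRID_LOG2GAMMA_EXPONENTS) == 341

    def test_separable_blobs_and_consistency(self, blobs20):
        from fireflysvm.core import _ccr_of_pair

        C, gamma, cv = grid_search(blobs20, folds=2, seed=0)
        assert np.log2(C) in GRID_LOG2C_EXPONENTS
        assert np.log2(gamma) in GRID_LOG2GAMMA_EXPONENTS
        assert cv == pytest.approx(100.0)
        assert _ccr_of_pair(blobs20, C, gamma, 2, 0) == pytest.approx(cv)
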