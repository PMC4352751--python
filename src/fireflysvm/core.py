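"""Kernel, dual objective, feasibility projection and exact dual solvers.

The binary soft-margin SVM is trained entirely in its dual form: maximize

    L(alpha) = sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j)

subject to 0 <= alpha_i <= C and sum_i alpha_i y_i = 0, with the RBF kernel
K(x, z) = exp(-gamma ||x - z||^2).  This module provides the pieces every
optimizer shares — kernel evaluation, the dual objective (the metaheuristic
"brightness"), projection of a candidate multiplier vector onto the feasible
set — plus an exact sequential-minimal-optimization solver for fixed
(C, gamma) and the classical exponential grid search built on it.  The SMO
solver doubles as the test oracle: the dual is concave, so its optimum
bounds the objective of any feasible point.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .types import (
    LOG2C_RANGE,
    LOG2GAMMA_RANGE,
    Dataset,
    DegenerateModelError,
    SolutionString,
    SVMModel,
)

__all__ = [
    "rbf_kernel",
    "rbf_gram",
    "dual_objective",
    "project_feasible",
    "default_feas_tol",
    "build_model",
    "decision_value",
    "predict",
    "smo_solve",
    "grid_search",
    "GRID_LOG2C_EXPONENTS",
    "GRID_LOG2GAMMA_EXPONENTS",
]

# Exhaustive exponent grid: C in [2^-15, 2^15], gamma in [2^-5, 2^5], step 2^1.
GRID_LOG2C_EXPONENTS = tuple(range(-15, 16))
GRID_LOG2GAMMA_EXPONENTS = tuple(range(-5, 6))


def rbf_kernel(x: np.ndarray, z: np.ndarray, gamma_kernel: float) -> float:
    """Evaluate exp(-gamma ||x - z||^2) for a single pair of points."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    if gamma_kernel < 0:
        raise ValueError("gamma_kernel must be nonnegative")
    diff = x - z
    return float(np.exp(-gamma_kernel * (diff @ diff)))


def rbf_gram(X: np.ndarray, gamma_kernel: float, Z: np.ndarray | None = None) -> np.ndarray:
    """RBF Gram matrix K[i, j] = exp(-gamma ||X_i - Z_j||^2) (Z defaults to X)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = X if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    return np.exp(-gamma_kernel * cdist(X, Z, "sqeuclidean"))


def squared_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, cached by optimizers so that a
    change of kernel width costs only one elementwise exp."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return cdist(X, X, "sqeuclidean")


def dual_objective(
    alpha: np.ndarray,
    gamma_kernel: float,
    data: Dataset,
    sqdist: np.ndarray | None = None,
) -> float:
    """The kernelized dual objective — the firefly brightness.

    ``sqdist`` may carry precomputed pairwise squared distances to avoid
    recomputing them for every kernel-width proposal.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (data.n,):
        raise ValueError("alpha length must equal the number of samples")
    data.require_binary()
    if sqdist is None:
        sqdist = squared_distances(data.X)
    K = np.exp(-gamma_kernel * sqdist)
    ay = alpha * data.y
    return float(alpha.sum() - 0.5 * (ay @ K @ ay))


def default_feas_tol(n: int, C: float) -> float:
    """Tolerance on |sum alpha_i y_i|, scale-invariant in C."""
    return 1e-8 * n * C


def project_feasible(
    alpha: np.ndarray,
    C: float,
    labels: np.ndarray,
    feas_tol: float | None = None,
    max_sweeps: int = 200,
) -> np.ndarray:
    """Repair a multiplier vector onto {0 <= alpha <= C, |alpha.y| <= tol}.

    Alternating projection: exact Euclidean projection onto the hyperplane
    alpha.y = 0 (a shift along y, since y has +-1 entries), then clipping to
    the box.  Both sets are convex so the iteration converges; a vector that
    is already feasible is returned unchanged.  If the tolerance is not met
    within ``max_sweeps`` the all-zero vector (always feasible) is returned.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    y = np.asarray(labels, dtype=float)
    a = np.clip(np.asarray(alpha, dtype=float), 0.0, C)
    n = a.size
    if feas_tol is None:
        feas_tol = default_feas_tol(n, C)
    if abs(float(a @ y)) <= feas_tol and np.array_equal(
        a, np.asarray(alpha, dtype=float)
    ):
        return np.asarray(alpha, dtype=float).copy()
    for _ in range(max_sweeps):
        gap = float(a @ y)
        if abs(gap) <= feas_tol:
            return a
        # ||y||^2 = n for +-1 labels
        a = np.clip(a - (gap / n) * y, 0.0, C)
    gap = float(a @ y)
    if abs(gap) <= feas_tol:
        return a
    return np.zeros_like(a)


def build_model(
    solution: SolutionString,
    data: Dataset,
    sv_threshold: float | None = None,
) -> SVMModel:
    """Extract the support-vector machine encoded by a feasible solution.

    Points with alpha above ``sv_threshold`` (default 1e-8 * C, scale
    invariant) are kept as support vectors; the bias is the KKT-consistent
    average of y_i - sum_j alpha_j y_j K(x_j, x_i), taken over the free
    support vectors (0 < alpha_i < C, where the margin condition holds
    with equality) when any exist, otherwise over all support vectors.
    """
    C = solution.C
    if sv_threshold is None:
        sv_threshold = 1e-8 * C
    keep = solution.alpha > sv_threshold
    if not np.any(keep):
        raise DegenerateModelError(
            "no multiplier above the support-vector threshold"
        )
    sv_X = data.X[keep]
    sv_a = solution.alpha[keep]
    sv_y = data.y[keep].astype(float)
    K = rbf_gram(sv_X, solution.gamma)
    residual = sv_y - K @ (sv_a * sv_y)
    free = sv_a < C * (1.0 - 1e-8)
    bias = float(residual[free].mean() if free.any() else residual.mean())
    return SVMModel(
        sv_features=sv_X,
        sv_alpha=sv_a,
        sv_labels=sv_y,
        bias=bias,
        gamma_kernel=solution.gamma,
        C=C,
    )


def decision_value(model: SVMModel, x: np.ndarray) -> float:
    """f(x) = sum_i alpha_i y_i K(x_i, x) + b for a single point."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise ValueError(f"expected a point of dimension {model.d}")
    k = rbf_gram(model.sv_features, model.gamma_kernel, x[None, :])[:, 0]
    return float((model.sv_alpha * model.sv_labels) @ k + model.bias)


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Vectorized decision function over the rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"expected points of dimension {model.d}")
    K = rbf_gram(X, model.gamma_kernel, model.sv_features)
    return K @ (model.sv_alpha * model.sv_labels) + model.bias


def predict(model: SVMModel, x: np.ndarray) -> int:
    """sign of the decision value; the tie f(x) = 0 maps to +1."""
    return 1 if decision_value(model, x) >= 0.0 else -1


def predict_many(model: SVMModel, X: np.ndarray) -> np.ndarray:
    f = decision_values(model, X)
    return np.where(f >= 0.0, 1, -1)


def smo_solve(
    data: Dataset,
    C: float,
    gamma_kernel: float,
    tol: float = 1e-8,
    max_iter: int = 200_000,
) -> SolutionString:
    """Exact dual maximizer for fixed (C, gamma) by sequential minimal
    optimization with maximal-violating-pair working-set selection.

    The dual is concave, so on convergence (KKT violation below ``tol``)
    the returned multipliers are globally optimal up to the tolerance.
    A run that exhausts ``max_iter`` marks the result via the attribute
    ``converged`` being False on the returned string.
    """
    data.require_binary()
    n = data.n
    if n > 2000:
        raise ValueError("smo_solve is guarded to n <= 2000 (dense kernel)")
    y = data.y.astype(float)
    K = rbf_gram(data.X, gamma_kernel)
    Q = (y[:, None] * y[None, :]) * K  # Hessian of the (negated) dual
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 a'Qa - e'a at a = 0
    converged = False
    for _ in range(max_iter):
        yg = -y * grad
        up = (y > 0) & (alpha < C - 1e-12 * C) | (y < 0) & (alpha > 1e-12 * C)
        low = (y < 0) & (alpha < C - 1e-12 * C) | (y > 0) & (alpha > 1e-12 * C)
        if not up.any() or not low.any():
            converged = True
            break
        i = int(np.argmax(np.where(up, yg, -np.inf)))
        j = int(np.argmin(np.where(low, yg, np.inf)))
        if yg[i] - yg[j] < tol:
            converged = True
            break
        # One-variable update along the feasible direction for the pair.
        quad = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        quad = max(quad, 1e-12)
        delta = (yg[i] - yg[j]) / quad
        # Step limits keeping both coordinates inside the box.
        if y[i] > 0:
            delta = min(delta, C - alpha[i])
        else:
            delta = min(delta, alpha[i])
        if y[j] > 0:
            delta = min(delta, alpha[j])
        else:
            delta = min(delta, C - alpha[j])
        alpha[i] += y[i] * delta
        alpha[j] -= y[j] * delta
        grad += delta * (y[i] * Q[i] - y[j] * Q[j])
    sol = SolutionString(
        alpha=alpha,
        log2C=float(np.log2(C)),
        log2gamma=float(np.log2(gamma_kernel)) if gamma_kernel > 0 else LOG2GAMMA_RANGE[0],
        brightness=float(alpha.sum() - 0.5 * alpha @ Q @ alpha),
    )
    sol.converged = converged
    return sol


def _ccr_of_pair(data: Dataset, C: float, gamma: float, folds: int, seed: int) -> float:
    """Inner-CV correct-classification ratio of a fixed (C, gamma) pair."""
    from .metrics import ccr, stratified_kfold

    assignment = stratified_kfold(data, k=folds, seed=seed)
    y_true, y_pred = [], []
    for fold in range(1, folds + 1):
        test = assignment == fold
        train = ~test
        sub = Dataset(data.X[train], data.y[train], scaled=data.scaled)
        sol = smo_solve(sub, C, gamma)
        try:
            model = build_model(sol, sub)
        except DegenerateModelError:
            pred = np.ones(int(test.sum()), dtype=int)  # tie rule: +1
        else:
            pred = predict_many(model, data.X[test])
        y_true.extend(data.y[test].tolist())
        y_pred.extend(pred.tolist())
    return ccr(np.asarray(y_true), np.asarray(y_pred))


def grid_search(
    data: Dataset,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Exhaustive exponential grid search over C in [2^-15, 2^15] and gamma
    in [2^-5, 2^5] at step 2^1, scoring each pair by inner-CV CCR with the
    exact SMO solver.  Returns (C, gamma, cv_ccr); ties keep the first
    pair encountered (row-major over increasing exponents).
    """
    data.require_binary()
    best: tuple[float, float, float] | None = None
    for ec in GRID_LOG2C_EXPONENTS:
        for eg in GRID_LOG2GAMMA_EXPONENTS:
            C, gamma = 2.0 ** ec, 2.0 ** eg
            score = _ccr_of_pair(data, C, gamma, folds, seed)
            if best is None or score > best[2]:
                best = (C, gamma, score)
    assert best is not None
    return best
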