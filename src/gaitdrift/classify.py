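"""Kernel-based discriminant regression (KBDR) and L2-regularised L2-loss
linear SVM, each with a one-versus-all multiclass wrapper.

KBDR is defined here as kernel least-squares regression of +-1 class
indicators with a ridge penalty: with kernel matrix ``K`` over the training
set, the dual coefficients per class solve the normal equations

    (K^T K + alpha I) c = K^T y,

which is ridge regression with the kernel columns as the design matrix and
is well posed even when the signed polynomial kernel is not positive
semi-definite.  Two solvers are provided: a direct Cholesky solve and a
proximal-point iteration

    c_{t+1} = (K^T K + (alpha + lambda) I)^{-1} (K^T y + lambda c_t),

whose fixed point satisfies the same normal equations; the two must agree to
tolerance, which is enforced by tests.

The polynomial kernel is ``k(x, z) = s^exp`` with ``s = x.z + beta``, using
the signed-power extension ``sign(s) |s|^exp`` so that fractional degrees are
defined for the negative dot products that [-1, 1]-scaled features admit.

The SVM minimises the standard primal squared-hinge objective

    0.5 ||w||^2 + C sum_i max(0, 1 - y_i w.x~_i)^2

with bias handled by augmenting each x with a constant 1 (the bias is
regularised).  The solver optimises over the span of the training rows when
n < d, which is lossless for this objective, and uses L-BFGS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "KernelParams",
    "ConvergenceError",
    "signed_power",
    "poly_kernel",
    "proximal_point_solve",
    "fit_kbdr_binary",
    "fit_linear_svm_binary",
    "svm_objective",
    "KBDRClassifier",
    "LinearSVMClassifier",
    "KBDR_EXP_GRID",
    "KBDR_ALPHA_GRID",
    "KBDR_BETA_GRID",
    "SVM_C_GRID",
]

#: Polynomial degree grid: 1-3 log sequence 0.1, 0.3, 1, 3 (same notation
#: convention as the beta grid below).
KBDR_EXP_GRID: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0)
#: Ridge regulariser grid 1e-7 .. 1e-3.
KBDR_ALPHA_GRID: tuple[float, ...] = (1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
#: Kernel offset grid, 1-3 sequence per decade.
KBDR_BETA_GRID: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
#: SVM cost grid 2^-5, 2^-4.75, ..., 2^15 (81 values).
SVM_C_GRID: tuple[float, ...] = tuple(
    float(2.0 ** e) for e in np.arange(-5.0, 15.0 + 1e-9, 0.25)
)


class ConvergenceError(RuntimeError):
    """Iterative solver failed to reach tolerance; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class KernelParams:
    """Polynomial-kernel hyperparameters: degree, ridge strength, offset."""

    exp: float = 1.0
    alpha: float = 1e-5
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.exp <= 0:
            raise ValueError("exp must be > 0")


def signed_power(s: np.ndarray, p: float) -> np.ndarray:
    """sign(s) * |s|**p — the standard power for s > 0, extended oddly."""
    s = np.asarray(s, dtype=float)
    return np.sign(s) * np.abs(s) ** p


def poly_kernel(x: np.ndarray, z: np.ndarray, params: KernelParams) -> np.ndarray:
    """Signed polynomial kernel; accepts vectors or (stacks of) row matrices."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    s = x @ z.T if x.ndim > 1 or z.ndim > 1 else float(x @ z)
    return signed_power(np.asarray(s) + params.beta, params.exp)


def proximal_point_solve(
    K: np.ndarray,
    y: np.ndarray,
    alpha: float,
    step_lambda: float = 0.01,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> np.ndarray:
    """Proximal-point iteration for the KBDR normal equations.

    Iterates from c = 0 until the successive max-norm change drops below
    ``tol``.  The fixed point solves (K^T K + alpha I) c = K^T y.
    """
    if step_lambda <= 0:
        raise ValueError("step_lambda must be > 0")
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = K.shape[1]
    A = K.T @ K + (alpha + step_lambda) * np.eye(n)
    chol = cho_factor(A)
    Kty = K.T @ y
    c = np.zeros(n)
    for _ in range(max_iter):
        c_next = cho_solve(chol, Kty + step_lambda * c)
        delta = np.max(np.abs(c_next - c))
        c = c_next
        if delta < tol:
            return c
    residual = float(np.max(np.abs((K.T @ K) @ c + alpha * c - Kty)))
    raise ConvergenceError("proximal-point iteration did not converge", residual)


def _solve_normal_equations(K: np.ndarray, targets: np.ndarray, alpha: float):
    """Direct solve of (K^T K + alpha I) c = K^T y for one or many targets.

    A is positive definite in exact arithmetic; if rounding on badly scaled
    kernels defeats Cholesky, fall back to a least-squares solve before
    declaring the system singular beyond regularisation capacity.
    """
    n = K.shape[1]
    A = K.T @ K + alpha * np.eye(n)
    rhs = K.T @ targets
    try:
        sol = cho_solve(cho_factor(A), rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(
            "normal equations singular beyond regularisation capacity"
        )
    return sol


class KBDRClassifier:
    """One-versus-all KBDR with the signed polynomial kernel.

    Parameters
    ----------
    params : KernelParams
    solver : {'direct', 'proximal_point'}
    """

    def __init__(self, params: KernelParams | None = None, solver: str = "direct"):
        if solver not in ("direct", "proximal_point"):
            raise ValueError("solver must be 'direct' or 'proximal_point'")
        self.params = params or KernelParams()
        self.solver = solver
        self.X_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None
        self.dual_coef_: np.ndarray | None = None  # (n_classes, n)

    def fit(self, X: np.ndarray, y: np.ndarray, _lin_gram: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.X_ = X
        self.classes_ = np.unique(y)
        lin = X @ X.T if _lin_gram is None else _lin_gram
        K = signed_power(lin + self.params.beta, self.params.exp)
        targets = np.stack(
            [np.where(y == c, 1.0, -1.0) for c in self.classes_], axis=1
        )
        if self.solver == "direct":
            coefs = _solve_normal_equations(K, targets, self.params.alpha)
        else:
            coefs = np.stack(
                [
                    proximal_point_solve(K, targets[:, j], self.params.alpha)
                    for j in range(targets.shape[1])
                ],
                axis=1,
            )
        if not np.all(np.isfinite(coefs)):
            raise np.linalg.LinAlgError("non-finite dual coefficients")
        self.dual_coef_ = coefs.T
        return self

    def decision_function(self, Q: np.ndarray) -> np.ndarray:
        """Per-class scores f_c(q) = sum_i coef_ci k(x_i, q); shape (m, n_classes)."""
        if self.X_ is None:
            raise RuntimeError("classifier is not fitted")
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if Q.shape[1] != self.X_.shape[1]:
            raise ValueError("query dimension does not match training dimension")
        Kq = signed_power(self.X_ @ Q.T + self.params.beta, self.params.exp)
        return (self.dual_coef_ @ Kq).T

    def predict(self, Q: np.ndarray) -> np.ndarray:
        scores = self.decision_function(Q)
        # argmax returns the first maximum: ties break to the lowest class index
        return self.classes_[np.argmax(scores, axis=1)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "kbdr",
                "params": {
                    "exp": self.params.exp,
                    "alpha": self.params.alpha,
                    "beta": self.params.beta,
                },
                "solver": self.solver,
                "classes": self.classes_.tolist(),
                "training_matrix": self.X_.tolist(),
                "dual_coef": self.dual_coef_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, blob: str) -> "KBDRClassifier":
        d = json.loads(blob)
        if d.get("kind") != "kbdr":
            raise ValueError("not a KBDR model")
        model = cls(KernelParams(**d["params"]), solver=d["solver"])
        model.X_ = np.asarray(d["training_matrix"], dtype=float)
        model.classes_ = np.asarray(d["classes"])
        model.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        return model


def fit_kbdr_binary(
    X: np.ndarray,
    y_pm1: np.ndarray,
    params: KernelParams,
    solver: str = "direct",
) -> KBDRClassifier:
    """Fit a single +-1 discriminant; returned model predicts in {-1, +1}."""
    y = np.asarray(y_pm1)
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be in {-1, +1}")
    return KBDRClassifier(params, solver=solver).fit(X, y)


# ---------------------------------------------------------------------------
# L2-regularised L2-loss linear SVM


def svm_objective(w: np.ndarray, Xa: np.ndarray, y: np.ndarray, C: float) -> float:
    """Primal squared-hinge objective at bias-augmented weight w."""
    margins = 1.0 - y * (Xa @ w)
    hinge = np.maximum(0.0, margins)
    return 0.5 * float(w @ w) + C * float(hinge @ hinge)


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([X, np.ones((X.shape[0], 1))])


_LBFGS_OPTS = dict(maxiter=5000, ftol=1e-14, gtol=1e-10)


def _solve_l2l2(Xa: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    n, d = Xa.shape
    if n <= d:
        # optimise over the span of the training rows: w = Xa^T beta
        G = Xa @ Xa.T

        def fun(beta):
            m = G @ beta
            h = np.maximum(0.0, 1.0 - y * m)
            obj = 0.5 * float(beta @ m) + C * float(h @ h)
            grad = G @ (beta - 2.0 * C * y * h)
            return obj, grad

        res = minimize(
            fun, np.zeros(n), jac=True, method="L-BFGS-B", options=_LBFGS_OPTS
        )
        return Xa.T @ res.x

    def fun(w):
        margins = 1.0 - y * (Xa @ w)
        h = np.maximum(0.0, margins)
        obj = 0.5 * float(w @ w) + C * float(h @ h)
        grad = w - 2.0 * C * (Xa.T @ (y * h))
        return obj, grad

    res = minimize(
        fun, np.zeros(d), jac=True, method="L-BFGS-B", options=_LBFGS_OPTS
    )
    return res.x


class LinearSVMClassifier:
    """One-versus-all linear SVM (L2 regulariser, squared hinge, bias-augmented)."""

    def __init__(self, cost: float = 1.0):
        if cost <= 0:
            raise ValueError("cost must be > 0")
        self.cost = cost
        self.classes_: np.ndarray | None = None
        self.weights_: np.ndarray | None = None  # (n_classes, d+1)

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        y = np.asarray(y)
        Xa = _augment(X)
        self.classes_ = np.unique(y)
        self.weights_ = np.stack(
            [
                _solve_l2l2(Xa, np.where(y == c, 1.0, -1.0), self.cost)
                for c in self.classes_
            ]
        )
        return self

    def decision_function(self, Q: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("classifier is not fitted")
        Qa = _augment(Q)
        if Qa.shape[1] != self.weights_.shape[1]:
            raise ValueError("query dimension does not match training dimension")
        return Qa @ self.weights_.T

    def predict(self, Q: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(Q), axis=1)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "svm",
                "cost": self.cost,
                "classes": self.classes_.tolist(),
                "weights": self.weights_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, blob: str) -> "LinearSVMClassifier":
        d = json.loads(blob)
        if d.get("kind") != "svm":
            raise ValueError("not a linear SVM model")
        model = cls(cost=d["cost"])
        model.classes_ = np.asarray(d["classes"])
        model.weights_ = np.asarray(d["weights"], dtype=float)
        return model


def fit_linear_svm_binary(
    X: np.ndarray, y_pm1: np.ndarray, cost: float
) -> np.ndarray:
    """Fit one binary squared-hinge SVM; returns the bias-augmented weight."""
    y = np.asarray(y_pm1, dtype=float)
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    return _solve_l2l2(_augment(X), y, cost)
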