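"""WENDY: covariance-matching network inference as least squares.

Given covariances K0 and Kt measured t apart, the linearized dynamics give
Kt ≈ (I + tA^T) K0 (I + tA) + D with D an unknown diagonal matrix.  WENDY
recovers the network A by minimizing the off-diagonal squared residual

    f(A) = 1/2 * sum_{i != j} [Kt - (I + tA^T) K0 (I + tA)]_{ij}^2

(the diagonal is absorbed by D and excluded).  The problem is non-convex
and the minimizer need not be unique; we run a deterministic quasi-Newton
descent from the zero matrix with the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["WendyProblem", "WendyResult", "wendy_objective", "wendy_gradient", "solve_wendy"]


@dataclass
class WendyProblem:
    K0: np.ndarray
    Kt: np.ndarray
    t: float

    def __post_init__(self) -> None:
        k0 = np.asarray(self.K0, dtype=float)
        kt = np.asarray(self.Kt, dtype=float)
        if k0.ndim != 2 or k0.shape[0] != k0.shape[1] or k0.shape != kt.shape:
            raise ValueError("K0 and Kt must be square matrices of the same shape")
        if k0.shape[0] < 2:
            raise ValueError("need at least 2 genes (no off-diagonal residual otherwise)")
        if not (np.isfinite(k0).all() and np.isfinite(kt).all()):
            raise ValueError("K0/Kt contain non-finite entries")
        if self.t <= 0:
            raise ValueError("t must be positive")
        self.K0, self.Kt = k0, kt

    @property
    def n(self) -> int:
        return self.K0.shape[0]


@dataclass
class WendyResult:
    A: np.ndarray
    objective_value: float
    converged: bool
    n_iter: int


def _residual(a: np.ndarray, problem: WendyProblem) -> np.ndarray:
    m = np.eye(problem.n) + problem.t * a
    r = problem.Kt - m.T @ problem.K0 @ m
    np.fill_diagonal(r, 0.0)
    return r


def wendy_objective(A: np.ndarray, problem: WendyProblem) -> float:
    """Off-diagonal squared residual 1/2 * sum_{i!=j} R_ij^2."""
    a = np.asarray(A, dtype=float)
    if a.shape != problem.K0.shape:
        raise ValueError(f"A shape {a.shape} does not match problem size {problem.n}")
    r = _residual(a, problem)
    return 0.5 * float((r * r).sum())


def wendy_gradient(A: np.ndarray, problem: WendyProblem) -> np.ndarray:
    """Analytic gradient of the objective with respect to A.

    With M = I + tA and masked residual R (diagonal zeroed),
    df = -t * (K0 M R^T + K0^T M R); R is symmetric when K0, Kt are.
    """
    a = np.asarray(A, dtype=float)
    m = np.eye(problem.n) + problem.t * a
    r = _residual(a, problem)
    return -problem.t * (problem.K0 @ m @ r.T + problem.K0.T @ m @ r)


def solve_wendy(
    problem: WendyProblem,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> WendyResult:
    """Minimize the WENDY objective by BFGS from the zero matrix.

    Deterministic given inputs and settings.  Returns the local minimizer
    found; non-convergence within ``max_iter`` is reported via the
    ``converged`` flag, never raised.
    """
    n = problem.n
    x0 = np.zeros(n * n) if init is None else np.asarray(init, dtype=float).ravel().copy()
    if x0.size != n * n:
        raise ValueError("init has wrong size")

    def fun(x: np.ndarray) -> float:
        return wendy_objective(x.reshape(n, n), problem)

    def jac(x: np.ndarray) -> np.ndarray:
        return wendy_gradient(x.reshape(n, n), problem).ravel()

    res = minimize(
        fun,
        x0,
        jac=jac,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    a = res.x.reshape(n, n)
    f_final = float(res.fun)
    f_init = fun(x0)
    if f_final > f_init:  # BFGS safeguard: never return worse than the start
        a, f_final = x0.reshape(n, n), f_init
    return WendyResult(
        A=a,
        objective_value=f_final,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
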