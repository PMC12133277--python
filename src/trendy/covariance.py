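"""Gene-gene covariance estimation and the linearized pseudo-target.

``estimate_covariances`` fits a graphical-lasso regularized covariance to
each snapshot.  ``compute_kt_star`` evaluates the covariance the linearized
regulation model predicts at time t given the true network A:

    Kt* = (I + t A^T) K0 (I + t A)

which serves as the regression target for the stage-1 refiner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import GraphicalLasso, empirical_covariance

from .synthetic_data import GroundTruthGRN

__all__ = ["CovariancePair", "estimate_covariances", "compute_kt_star", "glasso_covariance"]

DEFAULT_GLASSO_PENALTY = 0.01


@dataclass
class CovariancePair:
    """Covariance estimates at the two measurement times, t apart."""

    K0: np.ndarray
    Kt: np.ndarray
    t: float

    def __post_init__(self) -> None:
        for name, k in (("K0", self.K0), ("Kt", self.Kt)):
            if k.ndim != 2 or k.shape[0] != k.shape[1]:
                raise ValueError(f"{name} must be square")
            if np.abs(k - k.T).max() > 1e-10:
                raise ValueError(f"{name} must be symmetric")
        if self.K0.shape != self.Kt.shape:
            raise ValueError("K0 and Kt must have the same shape")
        if self.t <= 0:
            raise ValueError("t must be positive")


def glasso_covariance(
    snapshot: np.ndarray,
    penalty: float = DEFAULT_GLASSO_PENALTY,
    return_precision: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Graphical-lasso covariance of one cells x genes snapshot.

    Falls back to the empirical covariance plus a small ridge on the
    diagonal when the graphical-lasso iteration fails to converge (e.g.
    near-singular empirical covariance at low cell counts).  With
    ``return_precision`` the (sparse) estimated precision matrix is
    returned as well.
    """
    x = np.asarray(snapshot, dtype=float)
    if x.ndim != 2:
        raise ValueError("snapshot must be 2-D (cells x genes)")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 cells to estimate a covariance")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    emp = empirical_covariance(x)
    precision = None
    if penalty == 0:
        k = emp
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = GraphicalLasso(alpha=penalty, assume_centered=False, max_iter=200)
                model.fit(x)
            k = model.covariance_
            precision = model.precision_
            if not np.isfinite(k).all():
                raise FloatingPointError("non-finite glasso output")
        except (FloatingPointError, ValueError):
            k = emp + 1e-6 * np.trace(emp) / x.shape[1] * np.eye(x.shape[1])
            precision = None
    k = (k + k.T) / 2.0
    if not return_precision:
        return k
    if precision is None:
        precision = np.linalg.pinv(k)
    return k, precision


def estimate_covariances(
    snap0: np.ndarray,
    snapt: np.ndarray,
    t: float,
    glasso_penalty: float = DEFAULT_GLASSO_PENALTY,
) -> CovariancePair:
    """Estimate (K0, Kt) from two snapshots measured t time units apart."""
    s0 = np.asarray(snap0, dtype=float)
    st = np.asarray(snapt, dtype=float)
    if s0.ndim != 2 or st.ndim != 2 or s0.shape[1] != st.shape[1]:
        raise ValueError(
            f"snapshots must share the gene axis, got {s0.shape} and {st.shape}"
        )
    return CovariancePair(
        K0=glasso_covariance(s0, glasso_penalty),
        Kt=glasso_covariance(st, glasso_penalty),
        t=t,
    )


def compute_kt_star(
    K0: np.ndarray, grn: GroundTruthGRN | np.ndarray, t: float
) -> np.ndarray:
    """Covariance predicted by the linearized model: (I + tA^T) K0 (I + tA)."""
    a = grn.matrix if isinstance(grn, GroundTruthGRN) else np.asarray(grn, dtype=float)
    k0 = np.asarray(K0, dtype=float)
    if k0.ndim != 2 or k0.shape[0] != k0.shape[1]:
        raise ValueError("K0 must be square")
    if a.shape != k0.shape:
        raise ValueError(f"GRN shape {a.shape} does not match K0 shape {k0.shape}")
    m = np.eye(k0.shape[0]) + t * a
    return m.T @ k0 @ m
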