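"""End-to-end GRN inference from two expression snapshots.

``wendy_infer`` is the plain covariance-matching baseline A0.
``trendy_infer`` is the transformer-enhanced path: the stage-1 TE(k=1)
model refines the measured covariance Kt into Kt', WENDY on (K0, Kt')
yields A1, and the stage-2 TE(k=3) model maps (A1, K0, Kt) to the final
score matrix A2.  All intermediates are returned for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import DEFAULT_GLASSO_PENALTY, estimate_covariances
from .te_model import TEModel
from .wendy_solver import WendyProblem, solve_wendy

__all__ = ["InferredGRN", "TrendyResult", "trendy_infer", "wendy_infer"]


@dataclass
class InferredGRN:
    """Real-valued n x n regulation score matrix.

    scores[i, j] scores the regulation of gene j by gene i.  The diagonal
    is reported as computed but carries no inferential meaning: none of
    the methods here can recover autoregulation.
    """

    scores: np.ndarray
    method_label: str = ""
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("scores must be square")
        if not np.isfinite(s).all():
            raise ValueError("scores contain non-finite entries")
        self.scores = s

    @property
    def n(self) -> int:
        return self.scores.shape[0]


@dataclass
class TrendyResult:
    """A2 plus every intermediate of the TRENDY pipeline."""

    A2: InferredGRN
    A1: np.ndarray
    K0: np.ndarray
    Kt: np.ndarray
    Kt_prime: np.ndarray
    t: float


def wendy_infer(
    snap0: np.ndarray,
    snapt: np.ndarray,
    t: float,
    glasso_penalty: float = DEFAULT_GLASSO_PENALTY,
    gene_names: list[str] | None = None,
) -> InferredGRN:
    """Plain WENDY estimate A0 from two snapshots t time units apart."""
    cov = estimate_covariances(snap0, snapt, t, glasso_penalty)
    result = solve_wendy(WendyProblem(cov.K0, cov.Kt, t))
    return InferredGRN(result.A, method_label="WENDY/A0", gene_names=gene_names)


def trendy_infer(
    snap0: np.ndarray,
    snapt: np.ndarray,
    t: float,
    te1: TEModel,
    te3: TEModel,
    glasso_penalty: float = DEFAULT_GLASSO_PENALTY,
    gene_names: list[str] | None = None,
) -> TrendyResult:
    """TRENDY estimate A2 with intermediates (K0, Kt, Kt', A1)."""
    if te1.config.k != 1:
        raise ValueError("te1 must be a TE(k=1) model")
    if te3.config.k != 3:
        raise ValueError("te3 must be a TE(k=3) model")
    cov = estimate_covariances(snap0, snapt, t, glasso_penalty)
    kt_prime = te1.predict(cov.Kt[None])
    kt_prime = (kt_prime + kt_prime.T) / 2.0  # target Kt* is symmetric
    a1 = solve_wendy(WendyProblem(cov.K0, kt_prime, t)).A
    a2 = te3.predict(np.stack([a1, cov.K0, cov.Kt]))
    return TrendyResult(
        A2=InferredGRN(a2, method_label="TRENDY/A2", gene_names=gene_names),
        A1=a1,
        K0=cov.K0,
        Kt=cov.Kt,
        Kt_prime=kt_prime,
        t=t,
    )
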