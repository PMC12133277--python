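"""Synthetic single-cell expression data under a known regulatory network.

Ground-truth GRNs are signed adjacency matrices with i.i.d. three-point
entries.  Expression dynamics follow a standard nonlinear SDE for the mRNA
count ``X_j`` of gene ``j``::

    dX_j = V * ( beta * prod_i [1 + A_ij * X_i / (X_i + 1)] - theta * X_j ) dt
           + sigma * X_j dW_j

where ``A`` is the signed GRN (entry ``A_ij`` is the effect of gene i on
gene j), the Brownian motions ``W_j`` are independent across genes and
cells, and the Hill-type saturation ``X/(X+1)`` keeps regulation bounded.
Trajectories are integrated by Euler-Maruyama and recorded at fixed times;
cells recorded at different times carry no correspondence, mimicking
destructive single-cell measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroundTruthGRN",
    "SimulationParams",
    "SnapshotDataset",
    "sample_grn",
    "simulate_cells",
    "generate_corpus",
    "derive_seed",
]

_DEFAULT_PROBS = (0.1, 0.8, 0.1)


@dataclass(frozen=True)
class GroundTruthGRN:
    """Signed ground-truth gene regulatory network.

    ``matrix[i, j]`` is −1, 0 or +1: gene i represses / ignores / activates
    gene j.  The diagonal (autoregulation) is sampled like any other entry
    but no inference method in this package attempts to recover it.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"GRN matrix must be square, got shape {m.shape}")
        if m.shape[0] < 2:
            raise ValueError("GRN needs at least 2 genes")
        if not np.isin(m, (-1.0, 0.0, 1.0)).all():
            raise ValueError("GRN entries must be exactly -1, 0 or +1")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the expression SDE and its discretization.

    Defaults are the standard benchmark values: rate scale ``V=30``, basal
    production ``beta=1``, degradation ``theta=0.2``, noise ``sigma=0.1``,
    Euler-Maruyama step 0.01 over the unit time window, states recorded at
    0.0, 0.1, ..., 1.0 for 100 cells per network.
    """

    V: float = 30.0
    beta: float = 1.0
    theta: float = 0.2
    sigma: float = 0.1
    dt: float = 0.01
    t_end: float = 1.0
    record_times: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    n_cells: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if min(self.V, self.beta, self.theta) <= 0:
            raise ValueError("V, beta, theta must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        n_steps = self.t_end / self.dt
        if self.t_end <= 0 or abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("t_end must be a positive multiple of dt")
        for t in self.record_times:
            k = t / self.dt
            if t < -1e-12 or t > self.t_end + 1e-12 or abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"record time {t} must be a multiple of dt within [0, t_end]"
                )

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)


@dataclass
class SnapshotDataset:
    """Per-time-point expression snapshots (cells x genes, unpaired rows).

    Row order within one snapshot is arbitrary and rows at different times
    do not correspond to the same cell.  ``grn`` is attached for synthetic
    data and absent for real data.
    """

    times: list[float]
    snapshots: list[np.ndarray]
    grn: GroundTruthGRN | None = None
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.snapshots):
            raise ValueError("times and snapshots length mismatch")
        ns = {s.shape[1] for s in self.snapshots}
        if len(ns) > 1:
            raise ValueError(f"snapshots disagree on gene count: {sorted(ns)}")
        for s in self.snapshots:
            if (np.asarray(s) < 0).any():
                raise ValueError("expression values must be nonnegative")

    @property
    def n(self) -> int:
        return self.snapshots[0].shape[1]

    def at_time(self, t: float) -> np.ndarray:
        for ti, s in zip(self.times, self.snapshots):
            if abs(ti - t) < 1e-9:
                return s
        raise KeyError(f"no snapshot recorded at t={t}")


def sample_grn(
    n: int,
    probs: tuple[float, float, float] = _DEFAULT_PROBS,
    rng_seed: int | np.random.Generator = 0,
) -> GroundTruthGRN:
    """Draw an n x n signed GRN with i.i.d. entries.

    Each entry (diagonal included) is −1 / 0 / +1 with probabilities
    ``probs``; the default (0.1, 0.8, 0.1) yields sparse networks with
    balanced activation and repression.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be 3 nonnegative values summing to 1")
    rng = np.random.default_rng(rng_seed)
    entries = rng.choice([-1.0, 0.0, 1.0], size=(n, n), p=p)
    return GroundTruthGRN(entries)


def _drift(x: np.ndarray, a: np.ndarray, p: SimulationParams) -> np.ndarray:
    # x: (cells, genes); production term is a product over regulators i
    # of (1 + A_ij * x_i/(x_i+1)) for each target j.
    hill = x / (x + 1.0)  # (cells, n)
    factors = 1.0 + hill[:, :, None] * a[None, :, :]  # (cells, i, j)
    production = p.beta * factors.prod(axis=1)  # (cells, j)
    return p.V * (production - p.theta * x)


def simulate_cells(
    grn: GroundTruthGRN,
    params: SimulationParams | None = None,
    rng_seed: int | np.random.Generator = 0,
    init_high: float | None = None,
    init_state: np.ndarray | None = None,
) -> SnapshotDataset:
    """Integrate the expression SDE for ``params.n_cells`` independent cells.

    Initial states are i.i.d. Uniform(0, 2*beta/theta) per gene per cell
    (spanning the equilibrium beta/theta of the regulation-free system);
    ``init_high`` overrides the upper bound and ``init_state`` fixes the
    full (n_cells, n) starting matrix.  Euler-Maruyama steps are clamped
    at zero: the multiplicative noise sigma*X*dW vanishes at X=0, so the
    clamp only removes discretization overshoot.
    """
    p = params if params is not None else SimulationParams()
    a = grn.matrix
    n = grn.n
    rng = np.random.default_rng(rng_seed)
    if init_state is not None:
        x = np.array(init_state, dtype=float)
        if x.shape != (p.n_cells, n):
            raise ValueError(f"init_state must have shape {(p.n_cells, n)}")
        if (x < 0).any():
            raise ValueError("init_state must be nonnegative")
    else:
        high = init_high if init_high is not None else 2.0 * p.beta / p.theta
        x = rng.uniform(0.0, high, size=(p.n_cells, n))

    record_steps = {round(t / p.dt): t for t in p.record_times}
    snapshots: dict[int, np.ndarray] = {}
    if 0 in record_steps:
        snapshots[0] = x.copy()
    sqrt_dt = np.sqrt(p.dt)
    for step in range(1, p.n_steps + 1):
        dw = rng.standard_normal(size=(p.n_cells, n)) * sqrt_dt
        x = x + _drift(x, a, p) * p.dt + p.sigma * x * dw
        np.clip(x, 0.0, None, out=x)
        if step in record_steps:
            snapshots[step] = x.copy()

    times = sorted(record_steps, key=lambda s: s)
    return SnapshotDataset(
        times=[record_steps[s] for s in times],
        snapshots=[snapshots[s] for s in times],
        grn=grn,
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed from a master seed (stable across runs)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_corpus(
    n_samples: int,
    n: int = 10,
    params: SimulationParams | None = None,
    probs: tuple[float, float, float] = _DEFAULT_PROBS,
    rng_seed: int = 0,
) -> list[tuple[GroundTruthGRN, SnapshotDataset]]:
    """Generate ``n_samples`` independent (ground-truth GRN, snapshots) pairs.

    Per-sample seeds derive deterministically from ``rng_seed``, so the same
    master seed reproduces the corpus bitwise, even under parallel
    generation of disjoint index ranges.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p = params if params is not None else SimulationParams()
    corpus = []
    for i in range(n_samples):
        grn = sample_grn(n, probs, rng_seed=derive_seed(rng_seed, 2 * i))
        data = simulate_cells(grn, p, rng_seed=derive_seed(rng_seed, 2 * i + 1))
        corpus.append((grn, data))
    return corpus
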