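"""Generic transformer enhancement of inferred GRNs.

Any inference method's output score matrix can be refined by a TE(k)
model trained against ground truth on synthetic corpora: the base matrix
is always the first input; optional extra inputs are covariance matrices
(the single-snapshot covariance K for GENIE3-style methods, or the pair
K0/Kt).  tGENIE3 uses k=2 with roles (base_grn, covariance_K);
tSINCERITIES — and the pattern for any externally computed base matrix —
uses k=1 with role (base_grn,).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .covariance import DEFAULT_GLASSO_PENALTY, glasso_covariance, estimate_covariances
from .pipeline import InferredGRN
from .synthetic_data import SnapshotDataset
from .te_model import TEConfig, TEModel, build_te
from .training import TrainConfig, TrainHistory, train_te

__all__ = ["EnhancerSpec", "ROLES", "train_enhancer", "enhance"]

ROLES = ("base_grn", "covariance_K", "covariance_K0", "covariance_Kt")


@dataclass
class EnhancerSpec:
    base_method_label: str
    input_roles: tuple[str, ...]
    te_model: TEModel

    def __post_init__(self) -> None:
        if not self.input_roles or self.input_roles[0] != "base_grn":
            raise ValueError("first input role must be 'base_grn'")
        unknown = set(self.input_roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")
        if self.te_model.config.k != len(self.input_roles):
            raise ValueError(
                f"model k={self.te_model.config.k} but {len(self.input_roles)} roles declared"
            )

    @property
    def k(self) -> int:
        return len(self.input_roles)


def _assemble_inputs(
    roles: tuple[str, ...],
    base: np.ndarray,
    data: SnapshotDataset | None,
    t_pair: tuple[float, float],
    glasso_penalty: float,
    extras: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    mats = []
    cov_pair = None
    for role in roles:
        if extras is not None and role in (extras or {}):
            mats.append(np.asarray(extras[role], dtype=float))
            continue
        if role == "base_grn":
            mats.append(np.asarray(base, dtype=float))
        elif role == "covariance_K":
            if data is None:
                raise ValueError("role covariance_K needs snapshot data or an extra matrix")
            mats.append(glasso_covariance(data.at_time(t_pair[1]), glasso_penalty))
        elif role in ("covariance_K0", "covariance_Kt"):
            if data is None:
                raise ValueError(f"role {role} needs snapshot data or an extra matrix")
            if cov_pair is None:
                cov_pair = estimate_covariances(
                    data.at_time(t_pair[0]), data.at_time(t_pair[1]),
                    t_pair[1] - t_pair[0], glasso_penalty,
                )
            mats.append(cov_pair.K0 if role == "covariance_K0" else cov_pair.Kt)
    return np.stack(mats)


def train_enhancer(
    input_roles: tuple[str, ...],
    corpus,
    base_method: Callable[[SnapshotDataset], InferredGRN | np.ndarray],
    train_config: TrainConfig | None = None,
    te_config: TEConfig | None = None,
    base_method_label: str = "base",
    val_fraction: float = 0.1,
    t_pair: tuple[float, float] = (0.5, 1.0),
    glasso_penalty: float = DEFAULT_GLASSO_PENALTY,
    seed: int = 0,
) -> tuple[EnhancerSpec, "TrainHistory"]:
    """Train a TE(k) enhancer for ``base_method`` on a synthetic corpus.

    Runs the base method on every corpus sample, assembles the declared
    inputs, and fits TE(k) against the true network with the diagonal
    excluded from the loss.
    """
    if not input_roles or input_roles[0] != "base_grn":
        raise ValueError("first input role must be 'base_grn'")
    k = len(input_roles)
    cfg = te_config if te_config is not None else TEConfig(k=k, h=8)
    if cfg.k != k:
        raise ValueError(f"te_config.k={cfg.k} does not match {k} input roles")
    tcfg = train_config if train_config is not None else TrainConfig(seed=seed)

    pairs = []
    for grn, data in corpus:
        truth = grn if grn is not None else data.grn
        if truth is None:
            raise ValueError("corpus samples must carry a ground-truth GRN")
        base = base_method(data)
        base = base.scores if isinstance(base, InferredGRN) else np.asarray(base, float)
        inputs = _assemble_inputs(input_roles, base, data, t_pair, glasso_penalty)
        pairs.append((inputs, truth.matrix))

    n_val = max(1, int(round(len(pairs) * val_fraction)))
    if n_val >= len(pairs):
        raise ValueError("corpus too small to split off a validation set")
    order = np.random.default_rng(seed).permutation(len(pairs))
    val_idx = set(order[:n_val].tolist())
    train_pairs = [p for i, p in enumerate(pairs) if i not in val_idx]
    val_pairs = [p for i, p in enumerate(pairs) if i in val_idx]

    model = build_te(cfg, rng_seed=seed)
    model, history = train_te(model, train_pairs, val_pairs, tcfg)
    spec = EnhancerSpec(base_method_label, tuple(input_roles), model)
    return spec, history


def enhance(
    spec: EnhancerSpec,
    base_grn: InferredGRN | np.ndarray,
    extras: dict[str, np.ndarray] | None = None,
) -> InferredGRN:
    """Deterministic TE forward pass refining a base score matrix.

    ``extras`` supplies the covariance matrices for any non-base roles,
    keyed by role name.  Inputs are never mutated.
    """
    base = base_grn.scores if isinstance(base_grn, InferredGRN) else np.asarray(base_grn, float)
    names = base_grn.gene_names if isinstance(base_grn, InferredGRN) else None
    mats = [base]
    for role in spec.input_roles[1:]:
        if extras is None or role not in extras:
            raise ValueError(f"missing extra input for role '{role}'")
        extra = np.asarray(extras[role], dtype=float)
        if extra.shape != base.shape:
            raise ValueError(f"extra for role '{role}' has shape {extra.shape}, "
                             f"expected {base.shape}")
        mats.append(extra)
    out = spec.te_model.predict(np.stack(mats))
    return InferredGRN(out, method_label=f"t{spec.base_method_label}", gene_names=names)
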