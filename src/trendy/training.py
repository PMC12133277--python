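"""Loss and training loops for TE(k) refiner models.

The loss is mean squared error; when the target is a GRN the diagonal is
excluded (autoregulation is not inferable from snapshot covariances, so
penalizing it would only add noise), while covariance-like targets keep
their meaningful diagonal.  Training uses Adam with early stopping on the
validation loss: if the best validation loss fails to strictly improve for
``patience`` consecutive epochs, training halts and the weights of the
best epoch are restored.

``train_trendy`` runs the full two-stage workflow: stage 1 trains TE(k=1)
to map the measured covariance Kt to the linearized pseudo-target Kt*;
stage 2 pushes each sample through the trained TE(k=1) and the WENDY
solver to obtain A1, then trains TE(k=3) on (A1, K0, Kt) against the true
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import DEFAULT_GLASSO_PENALTY, compute_kt_star, estimate_covariances
from .nn.autograd import Tensor, no_grad
from .nn.optim import Adam
from .te_model import TEConfig, TEModel, build_te
from .wendy_solver import WendyProblem, solve_wendy

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "masked_mse",
    "train_te",
    "train_trendy",
    "prepare_stage1_samples",
]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 0.001
    batch_size: int = 16  # more update steps per epoch pay off at corpus sizes of a few thousand
    loss_excludes_diagonal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("need 0 < patience < max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def epochs_run(self) -> int:
        return len(self.train_losses)

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch]


def masked_mse(pred: np.ndarray, target: np.ndarray, exclude_diagonal: bool = True) -> float:
    """Mean squared error over matrix entries, optionally skipping the diagonal."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    diff = (p - t) ** 2
    if not exclude_diagonal:
        return float(diff.mean())
    n = p.shape[-1]
    if p.shape[-2] != n:
        raise ValueError("matrices must be square")
    mask = 1.0 - np.eye(n)
    return float((diff * mask).sum() / (mask.sum() * diff[..., 0, 0].size))


def _loss_tensor(pred: Tensor, target: np.ndarray, exclude_diagonal: bool) -> Tensor:
    diff = pred - Tensor(target)
    sq = diff * diff
    if not exclude_diagonal:
        return sq.mean()
    b, n, _ = pred.shape
    mask = np.broadcast_to(1.0 - np.eye(n), (b, n, n))
    return (sq * Tensor(mask)).sum() * (1.0 / (b * n * (n - 1)))


def _stack_pairs(pairs, k: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for inputs, target in pairs:
        arr = np.stack([np.asarray(m, dtype=float) for m in inputs]) if isinstance(
            inputs, (list, tuple)
        ) else np.asarray(inputs, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.shape[0] != k:
            raise ValueError(f"sample has {arr.shape[0]} input matrices, model expects {k}")
        xs.append(arr)
        ys.append(np.asarray(target, dtype=float))
    return np.stack(xs), np.stack(ys)


def _eval_loss(model: TEModel, x: np.ndarray, y: np.ndarray,
               exclude_diagonal: bool, batch_size: int) -> float:
    model.eval()
    total, count = 0.0, 0
    with no_grad():
        for lo in range(0, len(x), batch_size):
            xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
            pred = model.forward(xb).data
            total += masked_mse(pred, yb, exclude_diagonal) * len(xb)
            count += len(xb)
    return total / count


def train_te(
    model: TEModel,
    train_pairs,
    val_pairs,
    config: TrainConfig | None = None,
) -> tuple[TEModel, TrainHistory]:
    """Fit a TE(k) model by Adam on masked MSE with early stopping.

    ``train_pairs`` / ``val_pairs`` are sequences of (inputs, target) with
    inputs either a (k, n, n) array or a list of k matrices.  Returns the
    model carrying the best-validation-epoch weights and the history.
    """
    cfg = config if config is not None else TrainConfig()
    if len(train_pairs) == 0 or len(val_pairs) == 0:
        raise ValueError("training and validation sets must be nonempty")
    k = model.config.k
    x_train, y_train = _stack_pairs(train_pairs, k)
    x_val, y_val = _stack_pairs(val_pairs, k)

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] | None = None
    best_val = np.inf
    bad_epochs = 0
    exclude = cfg.loss_excludes_diagonal

    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(x_train))
        epoch_loss, seen = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            pred = model.forward(xb, rng=rng)
            loss = _loss_tensor(pred, yb, exclude)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        history.train_losses.append(epoch_loss / seen)

        val_loss = _eval_loss(model, x_val, y_val, exclude, cfg.batch_size)
        history.val_losses.append(val_loss)
        if val_loss < best_val:  # strict improvement; ties do not reset patience
            best_val = val_loss
            history.best_epoch = epoch
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                history.stopped_early = True
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def prepare_stage1_samples(
    corpus,
    t_pair: tuple[float, float] = (0.5, 1.0),
    glasso_penalty: float = DEFAULT_GLASSO_PENALTY,
):
    """Per corpus sample: estimate (K0, Kt) and build the target Kt*.

    Returns a list of dicts with keys grn, K0, Kt, Kt_star, t.
    """
    out = []
    t0, t1 = t_pair
    for grn, data in corpus:
        if data.grn is None and grn is None:
            raise ValueError("corpus samples must carry a ground-truth GRN")
        truth = grn if grn is not None else data.grn
        cov = estimate_covariances(data.at_time(t0), data.at_time(t1), t1 - t0, glasso_penalty)
        out.append(
            {
                "grn": truth,
                "K0": cov.K0,
                "Kt": cov.Kt,
                "Kt_star": compute_kt_star(cov.K0, truth, cov.t),
                "t": cov.t,
            }
        )
    return out


def _split_val(samples, val_fraction: float, seed: int):
    n_val = max(1, int(round(len(samples) * val_fraction)))
    if n_val >= len(samples):
        raise ValueError("corpus too small to split off a validation set")
    order = np.random.default_rng(seed).permutation(len(samples))
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val


def train_trendy(
    corpus,
    val_corpus=None,
    te1_config: TEConfig | None = None,
    te3_config: TEConfig | None = None,
    train_config: TrainConfig | None = None,
    t_pair: tuple[float, float] = (0.5, 1.0),
    glasso_penalty: float = DEFAULT_GLASSO_PENALTY,
    val_fraction: float = 0.1,
    seed: int = 0,
    verbose: bool = False,
) -> tuple[TEModel, TEModel, dict]:
    """Two-stage TRENDY training.

    Stage 1: TE(k=1), input Kt, target Kt* (diagonal kept in the loss —
    it is a covariance).  Stage 2: A1 = WENDY(K0, TE1(Kt)) per sample,
    then TE(k=3) on inputs (A1, K0, Kt) with target Atrue (diagonal
    excluded).  Returns (te1, te3, info) where info holds both histories
    and the prepared validation samples.
    """
    cfg1 = te1_config if te1_config is not None else TEConfig(k=1, h=4)
    # stage-2 inputs carry heavy-tailed covariance scales across samples;
    # per-matrix standardization keeps early optimization from stalling
    cfg3 = te3_config if te3_config is not None else TEConfig(k=3, h=8, standardize_inputs=True)
    if cfg1.k != 1 or cfg3.k != 3:
        raise ValueError("te1_config must have k=1 and te3_config k=3")
    tcfg = train_config if train_config is not None else TrainConfig(seed=seed)

    samples = prepare_stage1_samples(corpus, t_pair, glasso_penalty)
    if val_corpus is not None:
        train_s = samples
        val_s = prepare_stage1_samples(val_corpus, t_pair, glasso_penalty)
    else:
        train_s, val_s = _split_val(samples, val_fraction, seed)

    te1 = build_te(cfg1, rng_seed=seed)
    stage1_cfg = TrainConfig(
        max_epochs=tcfg.max_epochs,
        patience=tcfg.patience,
        learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size,
        loss_excludes_diagonal=False,
        seed=seed,
    )
    te1, hist1 = train_te(
        te1,
        [(s["Kt"], s["Kt_star"]) for s in train_s],
        [(s["Kt"], s["Kt_star"]) for s in val_s],
        stage1_cfg,
    )
    if verbose:
        print(f"[trendy.training] stage 1 done: best val loss {hist1.best_val_loss:.4g} "
              f"at epoch {hist1.best_epoch + 1}/{hist1.epochs_run}")

    def stage2_pairs(prepared):
        pairs = []
        for s in prepared:
            kt_prime = te1.predict(s["Kt"][None, None])[0]
            kt_prime = (kt_prime + kt_prime.T) / 2.0
            a1 = solve_wendy(WendyProblem(s["K0"], kt_prime, s["t"])).A
            pairs.append((np.stack([a1, s["K0"], s["Kt"]]), s["grn"].matrix))
        return pairs

    train2 = stage2_pairs(train_s)
    val2 = stage2_pairs(val_s)
    te3 = build_te(cfg3, rng_seed=seed + 1)
    stage2_cfg = TrainConfig(
        max_epochs=tcfg.max_epochs,
        patience=tcfg.patience,
        learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size,
        loss_excludes_diagonal=True,
        seed=seed + 1,
    )
    te3, hist3 = train_te(te3, train2, val2, stage2_cfg)
    if verbose:
        print(f"[trendy.training] stage 2 done: best val loss {hist3.best_val_loss:.4g} "
              f"at epoch {hist3.best_epoch + 1}/{hist3.epochs_run}")

    info = {"stage1_history": hist1, "stage2_history": hist3, "val_samples": val_s}
    return te1, te3, info
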