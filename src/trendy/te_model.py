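"""TE(k): transformer-encoder refiner for matrix-valued network data.

A TE(k) model maps k input n x n matrices to one n x n output.  Each
scalar entry is lifted to a d-dimensional token, a learned segment
embedding distinguishes the k input groups (omitted when k=1), and a
deterministic 2-D sinusoidal positional encoding tells the flattened
n^2-token sequence its original (row, column) coordinates.  The groups are
flattened row-major, concatenated on the feature axis to width d*k, passed
through l standard encoder layers, and projected back to one scalar per
matrix position.

No weight depends on the gene count n, so one trained model applies to
matrices of any size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn.autograd import Tensor, concat, no_grad
from .nn.layers import Embedding, Linear, TransformerEncoderLayer

__all__ = ["TEConfig", "TEModel", "positional_encoding_2d", "build_te", "te_forward",
           "save_checkpoint", "load_checkpoint"]

# Exponent scale of the sinusoidal frequencies: omega_j = 10^(-FREQ_SCALE*(j-1)/d).
# Equals the conventional 10000^(-8(j-1)/d) spread over each quarter of d.
PE_FREQ_SCALE = 32.0


@dataclass(frozen=True)
class TEConfig:
    """Hyperparameters of a TE(k) model.

    k is the number of input matrices; d the per-group token dimension
    (divisible by 4, the positional encoding fills d in quarters); l the
    encoder depth; h the attention heads of each encoder layer (which act
    on the concatenated width d*k).
    """

    k: int = 1
    d: int = 64
    l: int = 7
    h: int = 4
    dropout: float = 0.1
    standardize_inputs: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d % 4 != 0:
            raise ValueError("d must be divisible by 4")
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if (self.d * self.k) % self.h != 0:
            raise ValueError("token width d*k must be divisible by h")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def positional_encoding_2d(n: int, d: int, freq_scale: float = PE_FREQ_SCALE) -> np.ndarray:
    """Sinusoidal 2-D positional encoding, shape (n, n, d).

    For 1-based coordinates x (row), y (column) and frequency index
    j = 1..d/4 with omega_j = 10^(-freq_scale*(j-1)/d), the first half of
    the d axis interleaves sin/cos of (y-1)*omega_j and the second half
    interleaves sin/cos of (x-1)*omega_j.  Hence features in the first
    half depend only on the column and those in the second half only on
    the row.
    """
    if d % 4 != 0:
        raise ValueError("d must be divisible by 4")
    j = np.arange(1, d // 4 + 1)
    omega = 10.0 ** (-freq_scale * (j - 1) / d)  # (d/4,)
    coord = np.arange(n, dtype=float)  # (x-1) or (y-1) for 1-based x,y
    phase = coord[:, None] * omega[None, :]  # (n, d/4)

    half = np.empty((n, d // 2))
    half[:, 0::2] = np.sin(phase)
    half[:, 1::2] = np.cos(phase)

    pe = np.empty((n, n, d))
    pe[:, :, : d // 2] = half[None, :, :]  # depends on y (column)
    pe[:, :, d // 2 :] = half[:, None, :]  # depends on x (row)
    return pe


class TEModel(nn.Module):
    """See module docstring; use :func:`build_te` to construct."""

    def __init__(self, config: TEConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d, k = config.d, config.k
        self.input_embed = Linear(1, d, rng)
        self.segment_embed = Embedding(k, d, rng) if k > 1 else None
        self.encoder_layers = [
            TransformerEncoderLayer(d * k, config.h, config.dropout, rng)
            for _ in range(config.l)
        ]
        self.output_proj = Linear(d * k, 1, rng)
        self._pe_cache: dict[int, np.ndarray] = {}

    def _pe(self, n: int) -> np.ndarray:
        if n not in self._pe_cache:
            self._pe_cache[n] = positional_encoding_2d(n, self.config.d)
        return self._pe_cache[n]

    def forward(
        self,
        inputs: np.ndarray,
        rng: np.random.Generator | None = None,
        add_positional: bool = True,
    ) -> Tensor:
        """Run a batch through the model.

        ``inputs`` has shape (batch, k, n, n); returns a Tensor of shape
        (batch, n, n).  ``add_positional`` exists for ablation only.
        """
        x = np.asarray(inputs, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.k or x.shape[2] != x.shape[3]:
            raise ValueError(
                f"expected inputs of shape (batch, {cfg.k}, n, n), got {x.shape}"
            )
        b, _, n, _ = x.shape
        if cfg.standardize_inputs:
            mu = x.mean(axis=(2, 3), keepdims=True)
            sd = x.std(axis=(2, 3), keepdims=True)
            x = (x - mu) / np.maximum(sd, 1e-8)

        pe = Tensor(self._pe(n).reshape(1, n * n, cfg.d)) if add_positional else None
        groups: list[Tensor] = []
        for g in range(cfg.k):
            # scalar -> d tokens, flattened row-major to a length-n^2 sequence
            tokens = Tensor(x[:, g].reshape(b, n * n, 1))
            emb = self.input_embed(tokens)
            if self.segment_embed is not None:
                emb = emb + self.segment_embed(g).reshape(1, 1, cfg.d)
            if pe is not None:
                emb = emb + pe
            groups.append(emb)
        seq = concat(groups, axis=-1) if cfg.k > 1 else groups[0]
        for layer in self.encoder_layers:
            seq = layer(seq, rng)
        out = self.output_proj(seq)
        return out.reshape(b, n, n)

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode forward pass returning ndarray(s)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(inputs).data
        finally:
            if was_training:
                self.train()
        squeeze = np.asarray(inputs).ndim == 3
        return out[0] if squeeze else out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_te(config: TEConfig, rng_seed: int = 0) -> TEModel:
    """Freshly initialized TE(k) model; reproducible under the seed."""
    return TEModel(config, np.random.default_rng(rng_seed))


def te_forward(model: TEModel, inputs, training_mode: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray | Tensor:
    """Functional forward: k matrices (or a (k, n, n) array) -> n x n matrix.

    Evaluation mode (default) is deterministic and returns an ndarray;
    training mode returns the autograd Tensor with dropout active.
    """
    arr = np.stack([np.asarray(m, dtype=float) for m in inputs]) if isinstance(
        inputs, (list, tuple)
    ) else np.asarray(inputs, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("te_forward expects k stacked n x n matrices")
    if not training_mode:
        return model.predict(arr)
    model.train()
    return model.forward(arr, rng=rng)


def save_checkpoint(model: TEModel, path) -> None:
    """Single-archive checkpoint: config JSON + parameter arrays."""
    state = model.state_dict()
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(asdict(model.config)).encode(), dtype=np.uint8
        ),
        **state,
    )


def load_checkpoint(path) -> TEModel:
    with np.load(path) as archive:
        cfg = TEConfig(**json.loads(bytes(archive["__config__"]).decode()))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model = build_te(cfg, rng_seed=0)
    model.load_state_dict(state)
    return model
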