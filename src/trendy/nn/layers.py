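"""Transformer building blocks on top of the autograd core.

Layers follow the post-norm encoder design: each sublayer output is
``LayerNorm(x + Dropout(sublayer(x)))``, the feed-forward block is
Linear-ReLU-Dropout-Linear, and attention is standard scaled dot-product
multi-head self-attention.  Dropout draws from a generator passed at call
time so training runs are reproducible; evaluation passes are
deterministic (dropout off, no tape).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, layer_norm

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "Embedding",
    "TransformerEncoderLayer",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self) -> None:
        self.training = False

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self) -> None:
        self.training = True
        for m in self._submodules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._submodules():
            m.eval()

    def _submodules(self) -> list["Module"]:
        subs: list[Module] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                subs.append(value)
            elif isinstance(value, (list, tuple)):
                subs.extend(v for v in value if isinstance(v, Module))
        return subs

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._collect_state("", state)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._collect_tensors("", own)
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict key mismatch: {sorted(missing)}")
        for key, tensor in own.items():
            arr = np.asarray(state[key], dtype=tensor.data.dtype)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {key}")
            tensor.data = arr.copy()

    def _collect_state(self, prefix: str, out: dict[str, np.ndarray]) -> None:
        tensors: dict[str, Tensor] = {}
        self._collect_tensors(prefix, tensors)
        out.update({k: v.data.copy() for k, v in tensors.items()})

    def _collect_tensors(self, prefix: str, out: dict[str, "Tensor"]) -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                value._collect_tensors(key + ".", out)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_tensors(f"{key}.{i}.", out)


def _xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_xavier_uniform(rng, in_features, out_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias, self.eps)


class Dropout(Module):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Embedding(Module):
    """Lookup table mapping integer ids to learned d-dimensional vectors."""

    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(num_embeddings, dim)), requires_grad=True)

    def __call__(self, idx: int) -> Tensor:
        table = self.weight
        onehot = np.zeros((1, table.data.shape[0]))
        onehot[0, idx] = 1.0
        return Tensor(onehot) @ table  # differentiable row selection


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.attn_dropout = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        b, s, f = x.shape
        h, hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, s, h, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = self.attn_dropout(scores.softmax(axis=-1), rng)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, s, f)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer with ReLU feed-forward of width 4x."""

    def __init__(self, dim: int, n_heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, dropout, rng)
        self.ff1 = Linear(dim, 4 * dim, rng)
        self.ff2 = Linear(4 * dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)
        self.ff_drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x, rng), rng))
        ff = self.ff2(self.ff_drop(self.ff1(x).relu(), rng))
        return self.norm2(x + self.drop2(ff, rng))
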