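"""Reverse-mode automatic differentiation on numpy arrays.

A ``Tensor`` wraps an ndarray and records the operations that produced it;
``Tensor.backward()`` walks the tape in reverse topological order and
accumulates gradients.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.

The op set is exactly what a transformer encoder needs: elementwise
arithmetic, batched matmul, reshape/transpose, reductions, exp/sqrt/relu,
a numerically stable softmax, and concatenation.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "layer_norm", "set_default_dtype", "using_dtype"]

_grad_enabled = True
_dtype = np.dtype(np.float32)


def set_default_dtype(dtype) -> None:
    """Set the compute dtype of the engine (float32 default; float64 for
    e.g. finite-difference gradient verification)."""
    global _dtype
    _dtype = np.dtype(dtype)


@contextlib.contextmanager
def using_dtype(dtype):
    global _dtype
    prev = _dtype
    _dtype = np.dtype(dtype)
    try:
        yield
    finally:
        _dtype = prev


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (used for evaluation passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=_dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if (_grad_enabled and self.requires_grad) else ()
        self._backward = _backward if (_grad_enabled and self.requires_grad) else None

    # ---- bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray, own: bool = False) -> None:
        # `own=True` marks grads freshly allocated by the caller; others may
        # be views into another node's buffer and must be copied on first write
        if self.grad is None:
            self.grad = grad if own and grad.dtype == _dtype else np.array(grad, dtype=_dtype)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=_dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic --------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g, own=True)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape), own=True)

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape), own=True)
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape), own=True
                )

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bwd)

    def __pow__(self, exponent: float) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1), own=True)

        return Tensor(self.data**exponent, _parents=(self,), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape), own=True
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape), own=True
                )

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bwd)

    # ---- shape ops ---------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bwd)

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)

    # ---- reductions --------------------------------------------------

    def sum(self, axis: int | tuple[int, ...] | None = None, keepdims: bool = False) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bwd
        )

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ---- nonlinearities ---------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data, own=True)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data, own=True)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask, own=True)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax as a fused primitive."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)), own=True)

        return Tensor(s, _parents=(self,), _backward=bwd)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis: gain * xhat + bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    centered = x.data - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv_sigma = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv_sigma
    d = x.data.shape[-1]

    def bwd(g: np.ndarray) -> None:
        if gain.requires_grad:
            gain._accumulate(
                (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
            )
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gy = g * gain.data
            x._accumulate(
                inv_sigma
                * (
                    gy
                    - gy.mean(axis=-1, keepdims=True)
                    - xhat * (gy * xhat).mean(axis=-1, keepdims=True)
                )
            )

    return Tensor(
        xhat * gain.data + bias.data, _parents=(x, gain, bias), _backward=bwd
    )


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = list(tensors)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        _parents=tuple(ts),
        _backward=bwd,
    )
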