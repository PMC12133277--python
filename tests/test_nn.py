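"""Autodiff engine: gradients of every op verified against finite
differences, plus optimizer and layer behavior."""

import numpy as np
import pytest

from trendy.nn.autograd import Tensor, concat, layer_norm, no_grad, using_dtype
from trendy.nn.layers import LayerNorm, Linear, TransformerEncoderLayer
from trendy.nn.optim import Adam


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


@pytest.mark.parametrize(
    "name,expr",
    [
        ("add", lambda a, b: (a + b).sum()),
        ("sub", lambda a, b: (a - b).sum()),
        ("mul", lambda a, b: (a * b).sum()),
        ("div", lambda a, b: (a / (b * b + 1.0)).sum()),
        ("matmul", lambda a, b: (a @ b.transpose(0, 2, 1)).sum()),
        ("pow", lambda a, b: ((a * b) ** 3).mean()),
        ("exp", lambda a, b: ((a * 0.3).exp() * b).sum()),
        ("sqrt", lambda a, b: ((a * a + 1.0).sqrt() + b).sum()),
        ("relu", lambda a, b: ((a + b).relu() * a).sum()),
        ("softmax", lambda a, b: (((a @ b.transpose(0, 2, 1)).softmax()) @ b).sum()),
        ("reshape", lambda a, b: (a.reshape(2, 12) @ b.reshape(12, 2)).sum()),
        ("mean", lambda a, b: ((a * b).mean(axis=-1, keepdims=True) * a).sum()),
        ("concat", lambda a, b: (concat([a * b, a + b], axis=-1) ** 2).sum()),
    ],
)
def test_op_gradients_match_finite_differences(name, expr):
    with using_dtype(np.float64):
        rng = np.random.default_rng(hash(name) % 2**31)
        a_val = rng.normal(size=(2, 3, 4))
        b_val = rng.normal(size=(2, 3, 4))
        a = Tensor(a_val, requires_grad=True)
        b = Tensor(b_val, requires_grad=True)
        expr(a, b).backward()
        for t, val in ((a, a_val), (b, b_val)):
            num = numeric_grad(
                lambda x, t=t, val=val: float(
                    expr(
                        Tensor(x if t is a else a_val, requires_grad=True),
                        Tensor(x if t is b else b_val, requires_grad=True),
                    ).data
                ),
                val,
            )
            assert np.allclose(t.grad, num, atol=1e-6), name


def test_broadcast_gradients():
    with using_dtype(np.float64):
        a = Tensor(np.random.default_rng(0).normal(size=(2, 3, 4)), requires_grad=True)
        bias = Tensor(np.random.default_rng(1).normal(size=(4,)), requires_grad=True)
        ((a + bias) * (a * bias)).sum().backward()
        assert a.grad.shape == (2, 3, 4)
        assert bias.grad.shape == (4,)
        num = numeric_grad(
            lambda x: float(((a.detach() + Tensor(x)) * (a.detach() * Tensor(x))).sum().data),
            bias.data.copy(),
        )
        assert np.allclose(bias.grad, num, atol=1e-6)


def test_layer_norm_gradient():
    with using_dtype(np.float64):
        rng = np.random.default_rng(7)
        x_val = rng.normal(size=(2, 5, 8))
        g_val = rng.normal(size=(8,))
        b_val = rng.normal(size=(8,))
        x = Tensor(x_val, requires_grad=True)
        g = Tensor(g_val, requires_grad=True)
        b = Tensor(b_val, requires_grad=True)
        (layer_norm(x, g, b) ** 2).sum().backward()

        def f(which, v):
            args = {"x": x_val, "g": g_val, "b": b_val}
            args[which] = v
            out = layer_norm(Tensor(args["x"]), Tensor(args["g"]), Tensor(args["b"]))
            return float((out ** 2).sum().data)

        for t, key, val in ((x, "x", x_val), (g, "g", g_val), (b, "b", b_val)):
            num = numeric_grad(lambda v, key=key: f(key, v), val.copy())
            assert np.allclose(t.grad, num, atol=1e-5), key


def test_no_grad_suppresses_tape():
    x = Tensor(np.ones(3), requires_grad=True)
    with no_grad():
        y = (x * 2.0).sum()
    assert y._backward is None and y._parents == ()
    y.backward()  # no-op tape: no gradient reaches x
    assert x.grad is None


def test_grad_accumulates_across_uses():
    with using_dtype(np.float64):
        x = Tensor(np.array([2.0]), requires_grad=True)
        y = x * x + x * 3.0  # dy/dx = 2x + 3 = 7
        y.sum().backward()
        assert x.grad[0] == pytest.approx(7.0)


def test_adam_minimizes_quadratic():
    with using_dtype(np.float64):
        x = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([x], lr=0.1)
        for _ in range(500):
            opt.zero_grad()
            ((x - Tensor(np.array([1.0, 2.0]))) ** 2).sum().backward()
            opt.step()
        assert np.allclose(x.data, [1.0, 2.0], atol=1e-3)


def test_encoder_layer_shapes_and_determinism():
    rng = np.random.default_rng(0)
    layer = TransformerEncoderLayer(16, 4, dropout=0.1, rng=rng)
    layer.eval()
    x = Tensor(np.random.default_rng(1).normal(size=(3, 7, 16)))
    with no_grad():
        y1 = layer(x).data
        y2 = layer(x).data
    assert y1.shape == (3, 7, 16)
    assert np.array_equal(y1, y2)


def test_dropout_requires_rng_in_training():
    from trendy.nn.layers import Dropout

    d = Dropout(0.5)
    d.train()
    with pytest.raises(ValueError):
        d(Tensor(np.ones((2, 2))))


def test_linear_state_dict_roundtrip():
    rng = np.random.default_rng(0)
    lin = Linear(4, 3, rng)
    state = lin.state_dict()
    lin2 = Linear(4, 3, np.random.default_rng(99))
    lin2.load_state_dict(state)
    assert np.array_equal(lin.weight.data, lin2.weight.data)
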