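"""Numeric gradient checks for the autodiff core.

Every op the network uses is verified against central differences in
float64; layers are additionally checked through a composed module.
"""

import numpy as np
import pytest

from vesselseg import nn
from vesselseg.nn import functional as F
from vesselseg.nn.tensor import Tensor


def _num_grad(make_loss, t, n=12, eps=1e-6, rng=None):
    rng = rng or np.random.default_rng(0)
    errs = []
    for _ in range(n):
        idx = tuple(int(rng.integers(0, s)) for s in t.data.shape) if t.data.ndim else ()
        old = t.data[idx]
        t.data[idx] = old + eps
        fp = make_loss()
        t.data[idx] = old - eps
        fm = make_loss()
        t.data[idx] = old
        num = (fp - fm) / (2 * eps)
        ana = t.grad[idx]
        errs.append(abs(num - ana) / max(1.0, abs(ana)))
    return max(errs)


OPS = {
    "add": lambda x, y: x + y,
    "sub": lambda x, y: x - y,
    "mul": lambda x, y: x * y,
    "div": lambda x, y: x / (y * y + 1.0),
    "matmul": lambda x, y: F.matmul(x, y.transpose((0, 2, 1))),
    "concat": lambda x, y: F.concatenate([x, y], axis=2),
}


@pytest.mark.parametrize("name", sorted(OPS))
def test_binary_op_gradients(name, rng):
    op = OPS[name]
    x = Tensor(rng.standard_normal((2, 3, 4)), requires_grad=True)
    y = Tensor(rng.standard_normal((2, 3, 4)), requires_grad=True)
    w = rng.standard_normal(op(x, y).shape)
    (op(x, y) * Tensor(w)).sum().backward()

    def loss():
        return float((op(Tensor(x.data), Tensor(y.data)) * Tensor(w)).sum().data)

    assert _num_grad(loss, x, rng=rng) < 1e-6
    assert _num_grad(loss, y, rng=rng) < 1e-6


UNARY = {
    "exp": F.exp,
    "log": lambda t: F.log(t * t + 1.0),
    "sqrt": lambda t: F.sqrt(t * t + 1.0),
    "relu": F.relu,
    "sigmoid": F.sigmoid,
    "hardswish": F.hardswish,
    "softmax": lambda t: F.softmax(t, axis=-1),
    "mean_axis": lambda t: t.mean(axis=(0, 2), keepdims=True),
    "max_axis": lambda t: t.max(axis=1),
    "reshape": lambda t: t.reshape((6, 4)),
    "transpose": lambda t: t.transpose((2, 0, 1)),
    "roll": lambda t: F.roll(t, (1, -2), axis=(1, 2)),
    "getitem": lambda t: t[:, 1:3, ::2],
    "pow": lambda t: (t * t + 0.5) ** -0.5,
    "upsample": lambda t: F.upsample_nearest2(t.reshape((1, 2, 3, 4))),
    "maxpool": lambda t: F.maxpool2d(t.reshape((1, 1, 4, 6))),
}


@pytest.mark.parametrize("name", sorted(UNARY))
def test_unary_op_gradients(name, rng):
    op = UNARY[name]
    x = Tensor(rng.standard_normal((2, 3, 4)), requires_grad=True)
    w = rng.standard_normal(op(Tensor(x.data)).shape)
    (op(x) * Tensor(w)).sum().backward()

    def loss():
        return float((op(Tensor(x.data)) * Tensor(w)).sum().data)

    assert _num_grad(loss, x, rng=rng) < 1e-5


def test_layer_norm_gradients(rng):
    x = Tensor(rng.standard_normal((3, 5, 8)), requires_grad=True)
    g = Tensor(rng.standard_normal(8), requires_grad=True)
    b = Tensor(rng.standard_normal(8), requires_grad=True)
    w = rng.standard_normal((3, 5, 8))
    (F.layer_norm(x, g, b) * Tensor(w)).sum().backward()

    def loss():
        return float((F.layer_norm(Tensor(x.data), Tensor(g.data), Tensor(b.data))
                      * Tensor(w)).sum().data)

    for t in (x, g, b):
        assert _num_grad(loss, t, rng=rng) < 1e-5


def test_batch_norm_gradients(rng):
    x = Tensor(rng.standard_normal((3, 4, 5, 6)), requires_grad=True)
    g = Tensor(rng.standard_normal(4), requires_grad=True)
    b = Tensor(rng.standard_normal(4), requires_grad=True)
    w = rng.standard_normal((3, 4, 5, 6))
    (F.batch_norm(x, g, b) * Tensor(w)).sum().backward()

    def loss():
        return float((F.batch_norm(Tensor(x.data), Tensor(g.data), Tensor(b.data))
                      * Tensor(w)).sum().data)

    for t in (x, g, b):
        assert _num_grad(loss, t, rng=rng) < 1e-5


def test_instance_norm_gradients(rng):
    x = Tensor(rng.standard_normal((3, 4, 5, 6)), requires_grad=True)
    g = Tensor(rng.standard_normal(4), requires_grad=True)
    b = Tensor(rng.standard_normal(4), requires_grad=True)
    w = rng.standard_normal((3, 4, 5, 6))
    (F.instance_norm(x, g, b) * Tensor(w)).sum().backward()

    def loss():
        return float((F.instance_norm(Tensor(x.data), Tensor(g.data), Tensor(b.data))
                      * Tensor(w)).sum().data)

    for t in (x, g, b):
        assert _num_grad(loss, t, rng=rng) < 1e-5


def test_conv2d_gradients_and_value(rng):
    from scipy import signal
    x = rng.standard_normal((2, 3, 9, 10))
    w = rng.standard_normal((4, 3, 3, 3))
    b = rng.standard_normal(4)
    y = F.conv2d(Tensor(x), Tensor(w), Tensor(b)).data
    ref = np.stack([
        np.stack([sum(signal.correlate2d(x[n, c], w[o, c], mode="same")
                      for c in range(3)) + b[o] for o in range(4)])
        for n in range(2)])
    np.testing.assert_allclose(y, ref, atol=1e-10)

    xt = Tensor(x, requires_grad=True)
    wt = Tensor(w, requires_grad=True)
    bt = Tensor(b, requires_grad=True)
    (F.conv2d(xt, wt, bt) ** 2).sum().backward()

    def loss():
        return float((F.conv2d(Tensor(xt.data), Tensor(wt.data), Tensor(bt.data)) ** 2).sum().data)

    for t in (xt, wt, bt):
        assert _num_grad(loss, t, rng=rng) < 1e-5


def test_scalar_constants_do_not_promote_float32():
    x = Tensor(np.ones((2, 2), dtype=np.float32))
    assert (x + 1e-5).dtype == np.float32
    assert (x * 0.5).dtype == np.float32
    assert (1.0 - x).dtype == np.float32
    assert ((x + 0.1) ** -0.5).dtype == np.float32


def test_grad_accumulates_over_reused_tensor(rng):
    x = Tensor(rng.standard_normal(5), requires_grad=True)
    y = (x * x + x).sum()
    y.backward()
    np.testing.assert_allclose(x.grad, 2 * x.data + 1, rtol=1e-12)


def test_adam_minimizes_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_state_dict_roundtrip(rng):
    a = nn.Sequential([nn.Conv2d(2, 3, 3, rng=rng), nn.BatchNorm2d(3), nn.ReLU()])
    b = nn.Sequential([nn.Conv2d(2, 3, 3, rng=np.random.default_rng(99)),
                       nn.BatchNorm2d(3), nn.ReLU()])
    x = Tensor(rng.standard_normal((1, 2, 6, 6)).astype(np.float32))
    a.eval(); b.eval()
    assert not np.allclose(a(x).data, b(x).data)
    b.load_state_dict(a.state_dict())
    np.testing.assert_array_equal(a(x).data, b(x).data)
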