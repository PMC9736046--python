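"""Minimal reverse-mode autodiff over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological order
and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations the segmentation network
needs are provided; each op stores the minimum state required to compute
its vector-Jacobian product (convolution re-derives its im2col buffer in
the backward pass to keep peak memory low).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "pow_", "exp", "log", "sqrt",
    "matmul", "reshape", "transpose", "concatenate", "getitem", "roll",
    "pad_zero", "sum_", "mean", "max_", "relu", "sigmoid", "hardswish",
    "softmax", "batch_norm", "instance_norm", "layer_norm",
    "conv2d", "maxpool2d", "upsample_nearest2",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._prev = tuple(_prev)
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # arithmetic sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return max_(self, axis, keepdims)

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        """Back-propagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._prev))]
        seen.add(id(self))
        # iterative DFS post-order (graphs can be deep for long conv chains)
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                if id(child) not in seen:
                    seen.add(id(child))
                    stack.append((child, iter(child._prev)))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                order.append(node)

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for child, cg in node._backward(g):
                    if cg is None:
                        continue
                    key = id(child)
                    if key in grads:
                        grads[key] = grads[key] + cg
                    else:
                        grads[key] = cg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _pair(a, b) -> tuple[Tensor, Tensor]:
    """Convert operands, letting bare python scalars adopt the tensor dtype
    (mirrors numpy weak promotion, which 0-d arrays would otherwise defeat)."""
    a_scalar = not isinstance(a, Tensor) and np.isscalar(a)
    b_scalar = not isinstance(b, Tensor) and np.isscalar(b)
    a, b = as_tensor(a), as_tensor(b)
    if a_scalar and a.data.dtype != b.data.dtype and a.data.dtype == np.float64:
        a = Tensor(a.data.astype(b.data.dtype))
    if b_scalar and b.data.dtype != a.data.dtype and b.data.dtype == np.float64:
        b = Tensor(b.data.astype(a.data.dtype))
    return a, b


def _needs_tape(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data, prev, backward):
    if _needs_tape(*prev):
        return Tensor(data, _prev=prev, _backward=backward)
    return Tensor(data)


# ----------------------------------------------------------------------
# elementwise arithmetic
# ----------------------------------------------------------------------

def add(a, b):
    a, b = _pair(a, b)
    out = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _make(out, (a, b), backward)


def sub(a, b):
    a, b = _pair(a, b)
    out = a.data - b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(-g, b.data.shape)))

    return _make(out, (a, b), backward)


def mul(a, b):
    a, b = _pair(a, b)
    out = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return _make(out, (a, b), backward)


def div(a, b):
    a, b = _pair(a, b)
    out = a.data / b.data

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.data.shape)),
            (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)),
        )

    return _make(out, (a, b), backward)


def neg(a):
    a = as_tensor(a)
    return _make(-a.data, (a,), lambda g: ((a, -g),))


def pow_(a, p: float):
    a = as_tensor(a)
    out = a.data ** p

    def backward(g):
        return ((a, g * p * a.data ** (p - 1)),)

    return _make(out, (a,), backward)


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)
    return _make(out, (a,), lambda g: ((a, g * out),))


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _make(out, (a,), lambda g: ((a, g * 0.5 / out),))


# ----------------------------------------------------------------------
# linear algebra / shape ops
# ----------------------------------------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return ((a, _unbroadcast(ga, a.data.shape)), (b, _unbroadcast(gb, b.data.shape)))

    return _make(out, (a, b), backward)


def reshape(a, shape):
    a = as_tensor(a)
    out = a.data.reshape(shape)
    return _make(out, (a,), lambda g: ((a, g.reshape(a.data.shape)),))


def transpose(a, axes):
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = a.data.transpose(axes)
    return _make(out, (a,), lambda g: ((a, g.transpose(inv)),))


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return _make(out, tuple(tensors), backward)


def getitem(a, idx):
    a = as_tensor(a)
    out = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return ((a, ga),)

    return _make(out, (a,), backward)


def roll(a, shift, axis):
    a = as_tensor(a)
    out = np.roll(a.data, shift, axis=axis)

    def backward(g):
        if isinstance(shift, tuple):
            inv = tuple(-s for s in shift)
        else:
            inv = -shift
        return ((a, np.roll(g, inv, axis=axis)),)

    return _make(out, (a,), backward)


def pad_zero(a, pad_width):
    """Zero padding; ``pad_width`` in np.pad format."""
    a = as_tensor(a)
    out = np.pad(a.data, pad_width)
    slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, a.data.shape))
    return _make(out, (a,), lambda g: ((a, g[slices]),))


# ----------------------------------------------------------------------
# reductions
# ----------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            ga = np.broadcast_to(g, a.data.shape).copy()
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            ga = np.broadcast_to(g, a.data.shape).copy()
        return ((a, ga),)

    return _make(out, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / out.size

    def backward(g):
        if axis is None:
            ga = np.broadcast_to(g / n, a.data.shape).copy()
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            ga = np.broadcast_to(gg / n, a.data.shape).copy()
        return ((a, ga),)

    return _make(out, (a,), backward)


def max_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            mask = (a.data == out)
            # route through the first maximiser only
            flat = np.zeros(a.data.size, dtype=a.data.dtype)
            flat[int(np.argmax(a.data))] = np.asarray(g).reshape(-1)[0]
            return ((a, flat.reshape(a.data.shape)),)
        ax = axis if axis >= 0 else a.data.ndim + axis
        idx = np.expand_dims(np.argmax(a.data, axis=ax), ax)
        gg = g if keepdims else np.expand_dims(g, ax)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx, np.broadcast_to(gg, idx.shape), axis=ax)
        return ((a, ga),)

    return _make(out, (a,), backward)


# ----------------------------------------------------------------------
# nonlinearities
# ----------------------------------------------------------------------

def relu(a):
    a = as_tensor(a)
    out = np.maximum(a.data, 0)
    return _make(out, (a,), lambda g: ((a, g * (a.data > 0)),))


def sigmoid(a):
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-a.data))
    return _make(out, (a,), lambda g: ((a, g * out * (1.0 - out)),))


def hardswish(a):
    """x * clip(x + 3, 0, 6) / 6."""
    a = as_tensor(a)
    inner = np.clip(a.data + 3.0, 0.0, 6.0)
    out = a.data * inner / 6.0

    def backward(g):
        d = np.where(a.data <= -3.0, 0.0, np.where(a.data >= 3.0, 1.0, (2.0 * a.data + 3.0) / 6.0))
        return ((a, g * d.astype(a.data.dtype)),)

    return _make(out, (a,), backward)


def softmax(a, axis=-1):
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return ((a, out * (g - dot)),)

    return _make(out, (a,), backward)


def batch_norm(a, gamma, beta, eps=1e-5):
    """Fused training-mode batch normalization over axes (0, 2, 3).

    a: (B, C, H, W); gamma, beta: (C,).  Gradients flow through the batch
    statistics.  Fusing keeps one normalized copy instead of the half-dozen
    full-size intermediates a composed implementation would retain.
    """
    a, gamma, beta = as_tensor(a), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv = (1.0 / np.sqrt(var + eps)).astype(a.data.dtype)
    xhat = (a.data - mu) * inv
    C = gamma.data.shape[0]
    out = xhat * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)
    n = a.data.size // C

    def backward(g):
        gg = (g * xhat).sum(axis=axes)
        gb = g.sum(axis=axes)
        gxh = g * gamma.data.reshape(1, C, 1, 1)
        ga = inv / n * (n * gxh
                        - gxh.sum(axis=axes, keepdims=True)
                        - xhat * (gxh * xhat).sum(axis=axes, keepdims=True))
        return ((a, ga.astype(a.data.dtype)), (gamma, gg), (beta, gb))

    return _make(out, (a, gamma, beta), backward)


def instance_norm(a, gamma, beta, eps=1e-5):
    """Fused instance normalization: each (sample, channel) plane of a
    (B, C, H, W) tensor is normalized over its own spatial extent.

    No batch coupling and no running statistics: the transform is the
    same in training and evaluation, which matters when train batches and
    inference tiles have different compositions.
    """
    a, gamma, beta = as_tensor(a), as_tensor(gamma), as_tensor(beta)
    axes = (2, 3)
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv = (1.0 / np.sqrt(var + eps)).astype(a.data.dtype)
    xhat = (a.data - mu) * inv
    C = gamma.data.shape[0]
    out = xhat * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)
    n = a.data.shape[2] * a.data.shape[3]

    def backward(g):
        gg = (g * xhat).sum(axis=(0, 2, 3))
        gb = g.sum(axis=(0, 2, 3))
        gxh = g * gamma.data.reshape(1, C, 1, 1)
        ga = inv / n * (n * gxh
                        - gxh.sum(axis=axes, keepdims=True)
                        - xhat * (gxh * xhat).sum(axis=axes, keepdims=True))
        return ((a, ga.astype(a.data.dtype)), (gamma, gg), (beta, gb))

    return _make(out, (a, gamma, beta), backward)


def layer_norm(a, gamma, beta, eps=1e-5):
    """Normalize over the last axis: gamma * (x - mu)/sigma + beta."""
    a, gamma, beta = as_tensor(a), as_tensor(gamma), as_tensor(beta)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data
    n = a.data.shape[-1]

    def backward(g):
        gg = _unbroadcast(g * xhat, gamma.data.shape)
        gb = _unbroadcast(g, beta.data.shape)
        gx_hat = g * gamma.data
        ga = inv / n * (n * gx_hat
                        - gx_hat.sum(axis=-1, keepdims=True)
                        - xhat * (gx_hat * xhat).sum(axis=-1, keepdims=True))
        return ((a, ga.astype(a.data.dtype)), (gamma, gg), (beta, gb))

    return _make(out, (a, gamma, beta), backward)


# ----------------------------------------------------------------------
# convolution and pooling
# ----------------------------------------------------------------------

_SCRATCH: dict = {}


def _scratch(shape, dtype, tag: str = "") -> np.ndarray:
    """Reusable scratch buffer for convolution temporaries.

    Tap products are strictly transient; reusing one buffer per shape
    avoids re-faulting tens of MB of fresh pages on every conv call.  Safe
    because the tape is walked single-threaded and the buffer never
    escapes the op.  ``tag`` separates buffers that are live simultaneously
    despite sharing a shape.
    """
    key = (shape, np.dtype(dtype).str, tag)
    buf = _SCRATCH.get(key)
    if buf is None:
        if sum(b.nbytes for b in _SCRATCH.values()) > 512 * 2 ** 20:
            _SCRATCH.clear()
        buf = np.empty(shape, dtype=dtype)
        _SCRATCH[key] = buf
    return buf


def _tap_ranges(k: int, p: int, H: int, W: int):
    """Per-tap output/input slice pairs for shift-accumulate convolution."""
    ranges = []
    for kh in range(k):
        for kw in range(k):
            dh, dw = kh - p, kw - p
            i0, i1 = max(0, -dh), min(H, H - dh)
            j0, j1 = max(0, -dw), min(W, W - dw)
            out_sl = (slice(i0, i1), slice(j0, j1))
            in_sl = (slice(i0 + dh, i1 + dh), slice(j0 + dw, j1 + dw))
            ranges.append((out_sl, in_sl))
    return ranges


def conv2d(x, w, b=None):
    """Same-padding stride-1 2-D convolution (cross-correlation).

    x: (B, Cin, H, W); w: (Cout, Cin, k, k) with k odd; b: (Cout,) or None.
    Implemented as one GEMM over all kernel taps followed by shifted
    accumulation — identical arithmetic to im2col but without building the
    k^2-replicated column matrix.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    B, Cin, H, W = x.data.shape
    Cout, Cin_w, k, k2 = w.data.shape
    if Cin != Cin_w or k != k2 or k % 2 != 1:
        raise ValueError(f"incompatible conv shapes {x.data.shape} / {w.data.shape}")
    p = k // 2
    xflat = np.ascontiguousarray(x.data).reshape(B, Cin, H * W)
    if k == 1:
        out = np.matmul(w.data.reshape(Cout, Cin), xflat).reshape(B, Cout, H, W)
    else:
        # per-tap GEMM + shifted accumulation into the output; one small
        # reused scratch keeps peak memory at a single (B, Cout, H*W) buffer
        t = _scratch((B, Cout, H * W), xflat.dtype)
        out = np.zeros((B, Cout, H, W), dtype=xflat.dtype)
        for tap, (out_sl, in_sl) in enumerate(_tap_ranges(k, p, H, W)):
            kh, kw = divmod(tap, k)
            np.matmul(w.data[:, :, kh, kw], xflat, out=t)
            tv = t.reshape(B, Cout, H, W)
            out[:, :, out_sl[0], out_sl[1]] += tv[:, :, in_sl[0], in_sl[1]]
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)

    def backward(g):
        if k == 1:
            gmat = g.reshape(B, Cout, H * W)
            gw = np.matmul(gmat, xflat.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape)
            gx = np.matmul(w.data.reshape(Cout, Cin).T, gmat).reshape(B, Cin, H, W)
        else:
            gflat = np.ascontiguousarray(g).reshape(B, Cout, H * W)
            gview = gflat.reshape(B, Cout, H, W)
            xd = x.data.reshape(B, Cin, H, W)
            gx = np.zeros((B, Cin, H, W), dtype=g.dtype)
            gw = np.empty_like(w.data)
            s = _scratch((B, Cin, H * W), gflat.dtype)
            xbuf = _scratch((B, Cin, H, W), gflat.dtype, tag="xb")
            for tap, (out_sl, in_sl) in enumerate(_tap_ranges(k, p, H, W)):
                kh, kw = divmod(tap, k)
                np.matmul(w.data[:, :, kh, kw].T, gflat, out=s)
                sv = s.reshape(B, Cin, H, W)
                gx[:, :, in_sl[0], in_sl[1]] += sv[:, :, out_sl[0], out_sl[1]]
                xbuf.fill(0)
                xbuf[:, :, out_sl[0], out_sl[1]] = xd[:, :, in_sl[0], in_sl[1]]
                gw[:, :, kh, kw] = np.matmul(
                    gview.reshape(B, Cout, H * W),
                    xbuf.reshape(B, Cin, H * W).transpose(0, 2, 1)).sum(axis=0)
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    prev = (x, w) if b is None else (x, w, b)
    return _make(out, prev, backward)


def maxpool2d(x):
    """2x2 max pooling, stride 2; spatial dims must be even."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2d needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        return ((x, gx),)

    return _make(out, (x,), backward)


def upsample_nearest2(x):
    """Nearest-neighbour 2x spatial upsampling."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        gx = g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
        return ((x, gx),)

    return _make(out, (x,), backward)
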