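"""Attention blocks for the main segmentation sub-network.

Two blocks are the substance here:

* **Adaptive coordinate attention (ACA)** — each channel is encoded along
  rows and columns by 1-D *average* and *maximum* pooling.  The averages
  capture smooth directional context; the maxima keep thin, high-contrast
  structures (capillaries) from being washed out.  The two encodings pass
  through a shared bottleneck transform and are recombined with learnable
  scalar weights ``g1, g2`` before per-direction projections produce
  sigmoid gates ``f_h`` (per height) and ``f_w`` (per width); the input is
  rescaled elementwise by both gates.

* **Gated self-attention (GSA)** — windowed multi-head self-attention in
  which the relative position bias ``B`` enters the logits multiplied by a
  learnable scalar gate ``ga``:  ``softmax(QK^T/sqrt(d) + ga*B)V``.  On
  small datasets the bias table is the hardest part to train; the gate
  lets the model fade it out instead of being hurt by a half-trained
  table.  Blocks alternate unshifted and cyclically shifted window
  partitions so information crosses window borders.

Plain squeeze-and-excitation (SE), average-only coordinate attention (CA)
and an ungated window-attention block (SW) are provided with the same
interfaces: they are the ablation baselines, and double as reference
implementations in tests (ACA with ``g2=0`` reduces to CA; the gate frozen
at 1 reduces GSA to SW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "DirectionalEncoding", "aca_encode", "aca_apply",
    "AdaptiveCoordinateAttention", "CoordinateAttention", "SqueezeExcitation",
    "relative_position_index", "window_partition", "window_reverse",
    "attention_core", "PatchSelfAttention", "GSABlock", "baseline_blocks",
]


# ----------------------------------------------------------------------
# adaptive coordinate attention
# ----------------------------------------------------------------------

@dataclass
class DirectionalEncoding:
    """The four 1-D pooled descriptors of a (B, C, H, W) feature map."""

    k_w_avg: Tensor  # (B, C, W): average over height at each width position
    k_w_max: Tensor
    k_h_avg: Tensor  # (B, C, H): average over width at each height position
    k_h_max: Tensor


def _batched(x) -> tuple[Tensor, bool]:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.ndim == 3:
        return t.reshape((1,) + t.shape), True
    if t.ndim != 4:
        raise ValueError(f"expected (C,H,W) or (B,C,H,W), got shape {t.shape}")
    return t, False


def aca_encode(T) -> DirectionalEncoding:
    """Directional pooling: exact means and maxima along each spatial axis."""
    t, _ = _batched(T)
    B, C, H, W = t.shape
    if H < 1 or W < 1:
        raise ValueError("empty spatial dimensions")
    return DirectionalEncoding(
        k_w_avg=t.mean(axis=2), k_w_max=t.max(axis=2),
        k_h_avg=t.mean(axis=3), k_h_max=t.max(axis=3),
    )


def aca_apply(T, f_h, f_w):
    """y[c, i, j] = T[c, i, j] * f_h[c, i] * f_w[c, j] (batched broadcast)."""
    t, squeeze = _batched(T)
    fh = f_h if isinstance(f_h, Tensor) else Tensor(np.asarray(f_h))
    fw = f_w if isinstance(f_w, Tensor) else Tensor(np.asarray(f_w))
    if fh.ndim == 2:
        fh = fh.reshape((1,) + fh.shape)
    if fw.ndim == 2:
        fw = fw.reshape((1,) + fw.shape)
    B, C, H, W = t.shape
    if fh.shape[-2:] != (C, H) or fw.shape[-2:] != (C, W):
        raise ValueError("gate shapes inconsistent with the feature map")
    y = t * fh.reshape((fh.shape[0], C, H, 1)) * fw.reshape((fw.shape[0], C, 1, W))
    return y.reshape((C, H, W)) if squeeze else y


class AdaptiveCoordinateAttention(nn.Module):
    """ACA block: dual-pooled directional encodings, adaptively mixed.

    ``g1`` and ``g2`` (both initialized at 0.5) weight the average- and
    max-pooled branches; they are unconstrained per-module scalars.  The
    bottleneck activation is hard-swish; the final gates are sigmoids.
    """

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cr = max(1, math.ceil(channels / reduction))
        self.channels, self.reduction = channels, reduction
        self.f1 = nn.Conv2d(channels, cr, kernel=1, rng=rng, dtype=dtype)
        self.fh = nn.Conv2d(cr, channels, kernel=1, rng=rng, dtype=dtype)
        self.fw = nn.Conv2d(cr, channels, kernel=1, rng=rng, dtype=dtype)
        self.g1 = nn.Parameter(np.asarray(0.5, dtype=dtype))
        self.g2 = nn.Parameter(np.asarray(0.5, dtype=dtype))

    def _branch(self, k_h: Tensor, k_w: Tensor) -> Tensor:
        """Concatenate [k_h, k_w] spatially, bottleneck-transform, activate."""
        cat = F.concatenate([k_h, k_w], axis=2)          # (B, C, H+W)
        cat = cat.reshape(cat.shape[:2] + (1,) + cat.shape[2:])
        return F.hardswish(self.f1(cat))                  # (B, C/r, 1, H+W)

    def weights(self, enc: DirectionalEncoding) -> tuple[Tensor, Tensor]:
        """Directional sigmoid gates (f_h, f_w) from an encoding."""
        H = enc.k_h_avg.shape[-1]
        W = enc.k_w_avg.shape[-1]
        za = self._branch(enc.k_h_avg, enc.k_w_avg)
        zm = self._branch(enc.k_h_max, enc.k_w_max)
        z_h = self.g1 * za[:, :, :, :H] + self.g2 * zm[:, :, :, :H]
        z_w = self.g1 * za[:, :, :, H:] + self.g2 * zm[:, :, :, H:]
        f_h = F.sigmoid(self.fh(z_h))                     # (B, C, 1, H)
        f_w = F.sigmoid(self.fw(z_w))
        B = f_h.shape[0]
        return (f_h.reshape((B, self.channels, H)),
                f_w.reshape((B, self.channels, W)))

    def forward(self, x):
        t, squeeze = _batched(x)
        f_h, f_w = self.weights(aca_encode(t))
        y = aca_apply(t, f_h, f_w)
        return y.reshape(y.shape[1:]) if squeeze else y


class CoordinateAttention(nn.Module):
    """Classical coordinate attention: average pooling only, no branch mix."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cr = max(1, math.ceil(channels / reduction))
        self.channels = channels
        self.f1 = nn.Conv2d(channels, cr, kernel=1, rng=rng, dtype=dtype)
        self.fh = nn.Conv2d(cr, channels, kernel=1, rng=rng, dtype=dtype)
        self.fw = nn.Conv2d(cr, channels, kernel=1, rng=rng, dtype=dtype)

    def forward(self, x):
        t, squeeze = _batched(x)
        B, C, H, W = t.shape
        enc = aca_encode(t)
        cat = F.concatenate([enc.k_h_avg, enc.k_w_avg], axis=2)
        cat = cat.reshape((B, C, 1, H + W))
        z = F.hardswish(self.f1(cat))
        f_h = F.sigmoid(self.fh(z[:, :, :, :H])).reshape((B, C, H))
        f_w = F.sigmoid(self.fw(z[:, :, :, H:])).reshape((B, C, W))
        y = aca_apply(t, f_h, f_w)
        return y.reshape(y.shape[1:]) if squeeze else y


class SqueezeExcitation(nn.Module):
    """Global-average-pool channel gating (the standard SE block)."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cr = max(1, math.ceil(channels / reduction))
        self.fc1 = nn.Linear(channels, cr, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(cr, channels, rng=rng, dtype=dtype)

    def forward(self, x):
        t, _ = _batched(x)
        B, C, H, W = t.shape
        pooled = t.mean(axis=(2, 3))                      # (B, C)
        gate = F.sigmoid(self.fc2(F.relu(self.fc1(pooled))))
        return t * gate.reshape((B, C, 1, 1))


# ----------------------------------------------------------------------
# gated windowed self-attention
# ----------------------------------------------------------------------

def relative_position_index(M: int) -> np.ndarray:
    """(M^2, M^2) index map into a (2M-1)^2 relative-coordinate bias table.

    Token pairs with equal relative displacement map to the same entry.
    """
    coords = np.stack(np.meshgrid(np.arange(M), np.arange(M), indexing="ij"), axis=0)
    flat = coords.reshape(2, -1)                          # (2, M^2)
    rel = flat[:, :, None] - flat[:, None, :]             # (2, M^2, M^2)
    rel = rel + (M - 1)
    return (rel[0] * (2 * M - 1) + rel[1]).astype(np.int64)


def window_partition(x: Tensor, M: int, shifted: bool = False):
    """(B, C, H, W) -> (B*nW, M^2, C) token blocks.

    H and W must be divisible by M.  When ``shifted``, a cyclic roll by
    ``-M//2`` along both spatial axes precedes partitioning (inverted by
    :func:`window_reverse`).
    """
    B, C, H, W = x.shape
    if H % M or W % M:
        raise ValueError(f"spatial dims {H}x{W} not divisible by window {M}")
    if M > H or M > W:
        raise ValueError("window larger than the feature map")
    if shifted:
        sh = M // 2
        x = F.roll(x, (-sh, -sh), axis=(2, 3))
    t = x.reshape((B, C, H // M, M, W // M, M))
    t = t.transpose((0, 2, 4, 3, 5, 1))                   # (B, nH, nW, M, M, C)
    return t.reshape((B * (H // M) * (W // M), M * M, C))


def window_reverse(tokens: Tensor, M: int, spatial: tuple[int, int],
                   shifted: bool = False) -> Tensor:
    """Inverse of :func:`window_partition`; bit-exact layout restoration."""
    H, W = spatial
    nH, nW = H // M, W // M
    Bn, N, C = tokens.shape
    B = Bn // (nH * nW)
    t = tokens.reshape((B, nH, nW, M, M, C))
    t = t.transpose((0, 5, 1, 3, 2, 4))                   # (B, C, nH, M, nW, M)
    x = t.reshape((B, C, H, W))
    if shifted:
        sh = M // 2
        x = F.roll(x, (sh, sh), axis=(2, 3))
    return x


def attention_core(q, k, v, bias, ga):
    """softmax(q k^T / sqrt(d) + ga * bias) v, softmax over the key axis.

    q, k, v: (..., N, d); bias: broadcastable to the (..., N, N) logits;
    ga: scalar (Tensor or float).
    """
    q = q if isinstance(q, Tensor) else Tensor(np.asarray(q))
    k = k if isinstance(k, Tensor) else Tensor(np.asarray(k))
    v = v if isinstance(v, Tensor) else Tensor(np.asarray(v))
    d = q.shape[-1]
    if d == 0:
        raise ValueError("key/query dimension must be positive")
    logits = F.matmul(q, k.transpose(tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2)))
    logits = logits * (1.0 / math.sqrt(d))
    if bias is not None:
        b = bias if isinstance(bias, Tensor) else Tensor(np.asarray(bias))
        logits = logits + ga * b
    attn = F.softmax(logits, axis=-1)
    return F.matmul(attn, v), attn


class PatchSelfAttention(nn.Module):
    """Multi-head window attention with a gated relative position bias.

    ``gate_mode='learnable'`` gives the gated block (``ga`` trainable,
    initialized at 1 so the bias starts on); ``'fixed'`` freezes ``ga`` at
    1, which is the ungated ablation baseline.
    """

    def __init__(self, dim: int, window: int, heads: int = 1,
                 gate_mode: str = "learnable",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        rng = rng or np.random.default_rng(0)
        self.dim, self.window, self.heads = dim, window, heads
        self.head_dim = dim // heads
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng, dtype=dtype)
        self.proj = nn.Linear(dim, dim, rng=rng, dtype=dtype)
        table = (rng.standard_normal(((2 * window - 1) ** 2, heads)) * 0.02).astype(dtype)
        self.bias_table = nn.Parameter(table)
        self.rel_index = relative_position_index(window)
        if gate_mode == "learnable":
            self.ga = nn.Parameter(np.asarray(1.0, dtype=dtype))
        elif gate_mode == "fixed":
            self.ga = Tensor(np.asarray(1.0, dtype=dtype))  # constant, not a parameter
        else:
            raise ValueError(f"unknown gate_mode {gate_mode!r}")
        self.gate_mode = gate_mode

    def gathered_bias(self) -> Tensor:
        """(heads, N, N) bias gathered from the table via the index map."""
        N = self.window ** 2
        b = self.bias_table[self.rel_index.reshape(-1)]   # (N*N, heads)
        return b.reshape((N, N, self.heads)).transpose((2, 0, 1))

    def forward(self, tokens: Tensor) -> Tensor:
        Bw, N, C = tokens.shape
        h, dh = self.heads, self.head_dim
        qkv = self.qkv(tokens)                            # (Bw, N, 3C)
        qkv = qkv.reshape((Bw, N, 3, h, dh)).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]                  # (Bw, h, N, dh)
        bias = self.gathered_bias().reshape((1, h, N, N))
        out, _ = attention_core(q, k, v, bias, self.ga)
        out = out.transpose((0, 2, 1, 3)).reshape((Bw, N, C))
        return self.proj(out)


class _Mlp(nn.Module):
    def __init__(self, dim: int, ratio: int, rng, dtype):
        super().__init__()
        self.fc1 = nn.Linear(dim, ratio * dim, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(ratio * dim, dim, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.fc2(F.relu(self.fc1(x)))


class GSABlock(nn.Module):
    """Gated self-attention block: unshifted then shifted PSA/MLP pair.

    Sequence per pair: pre-norm attention with residual, then pre-norm
    2-layer MLP with residual; the second pair partitions cyclically
    shifted windows so neighbouring windows exchange information.
    """

    def __init__(self, dim: int, window: int, heads: int = 1, mlp_ratio: int = 4,
                 gate_mode: str = "learnable",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dim, self.window = dim, window
        self.ln1 = nn.LayerNorm(dim, dtype=dtype)
        self.psa1 = PatchSelfAttention(dim, window, heads, gate_mode, rng, dtype)
        self.ln2 = nn.LayerNorm(dim, dtype=dtype)
        self.mlp1 = _Mlp(dim, mlp_ratio, rng, dtype)
        self.ln3 = nn.LayerNorm(dim, dtype=dtype)
        self.psa2 = PatchSelfAttention(dim, window, heads, gate_mode, rng, dtype)
        self.ln4 = nn.LayerNorm(dim, dtype=dtype)
        self.mlp2 = _Mlp(dim, mlp_ratio, rng, dtype)

    def _pair(self, x: Tensor, psa, ln_a, ln_m, mlp, shifted: bool) -> Tensor:
        B, C, H, W = x.shape
        t = window_partition(x, self.window, shifted)
        t = psa(ln_a(t)) + t
        t = mlp(ln_m(t)) + t
        return window_reverse(t, self.window, (H, W), shifted)

    def forward(self, x: Tensor) -> Tensor:
        x = self._pair(x, self.psa1, self.ln1, self.ln2, self.mlp1, shifted=False)
        x = self._pair(x, self.psa2, self.ln3, self.ln4, self.mlp2, shifted=True)
        return x


def baseline_blocks(channels: int, window: int = 6, heads: int = 1,
                    reduction: int = 8, rng: np.random.Generator | None = None,
                    dtype=np.float32) -> dict:
    """SE / CA / SW ablation blocks sharing the ACA/GSA interfaces."""
    rng = rng or np.random.default_rng(0)
    return {
        "SE": SqueezeExcitation(channels, reduction, rng=rng, dtype=dtype),
        "CA": CoordinateAttention(channels, reduction, rng=rng, dtype=dtype),
        "SW": GSABlock(channels, window, heads, gate_mode="fixed", rng=rng, dtype=dtype),
    }
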