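"""Attention blocks against independent loop/stagewise oracles, and the
reductions to their ablation baselines (SE / CA / ungated window attention)."""

import math

import numpy as np
import pytest

from vesselseg.attention import (aca_encode, aca_apply, AdaptiveCoordinateAttention,
                                 CoordinateAttention, SqueezeExcitation,
                                 relative_position_index, window_partition,
                                 window_reverse, attention_core,
                                 PatchSelfAttention, GSABlock, baseline_blocks)
from vesselseg.nn.tensor import Tensor


# ----------------------------------------------------------------------
# oracles (plain numpy, written straight from the defining formulas)
# ----------------------------------------------------------------------

def _hardswish(x):
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _encode_loops(T):
    C, H, W = T.shape
    k_w_avg = np.array([[T[c, :, w].sum() / H for w in range(W)] for c in range(C)])
    k_w_max = np.array([[max(T[c, i, w] for i in range(H)) for w in range(W)] for c in range(C)])
    k_h_avg = np.array([[T[c, h, :].sum() / W for h in range(H)] for c in range(C)])
    k_h_max = np.array([[max(T[c, h, j] for j in range(W)) for h in range(H)] for c in range(C)])
    return k_w_avg, k_w_max, k_h_avg, k_h_max


def _aca_oracle(T, f1_w, f1_b, fh_w, fh_b, fw_w, fw_b, g1, g2):
    """Full directional-attention chain evaluated stage by stage."""
    C, H, W = T.shape
    k_w_avg, k_w_max, k_h_avg, k_h_max = _encode_loops(T)
    cat_a = np.concatenate([k_h_avg, k_w_avg], axis=1)     # (C, H+W)
    cat_m = np.concatenate([k_h_max, k_w_max], axis=1)
    za = _hardswish(np.einsum("rc,cs->rs", f1_w, cat_a) + f1_b[:, None])
    zm = _hardswish(np.einsum("rc,cs->rs", f1_w, cat_m) + f1_b[:, None])
    z_h = g1 * za[:, :H] + g2 * zm[:, :H]
    z_w = g1 * za[:, H:] + g2 * zm[:, H:]
    f_h = _sigmoid(np.einsum("cr,rs->cs", fh_w, z_h) + fh_b[:, None])
    f_w = _sigmoid(np.einsum("cr,rs->cs", fw_w, z_w) + fw_b[:, None])
    y = np.empty_like(T)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                y[c, i, j] = T[c, i, j] * f_h[c, i] * f_w[c, j]
    return y, f_h, f_w


def _attention_oracle(Q, K, V, B, ga):
    N, d = Q.shape
    out = np.empty_like(V)
    for i in range(N):
        logits = np.array([Q[i] @ K[j] / math.sqrt(d) + ga * B[i, j] for j in range(N)])
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        out[i] = a @ V
    return out


def _aca_params(module):
    return (module.f1.weight.data[:, :, 0, 0], module.f1.bias.data,
            module.fh.weight.data[:, :, 0, 0], module.fh.bias.data,
            module.fw.weight.data[:, :, 0, 0], module.fw.bias.data)


# ----------------------------------------------------------------------
# directional encoding
# ----------------------------------------------------------------------

def test_encode_hand_example():
    T = np.array([[[1.0, 2.0], [3.0, 4.0]]])
    enc = aca_encode(T)
    np.testing.assert_allclose(enc.k_w_avg.data[0], [[2.0, 3.0]])
    np.testing.assert_allclose(enc.k_w_max.data[0], [[3.0, 4.0]])
    np.testing.assert_allclose(enc.k_h_avg.data[0], [[1.5, 3.5]])
    np.testing.assert_allclose(enc.k_h_max.data[0], [[2.0, 4.0]])


def test_encode_constant_input():
    enc = aca_encode(np.full((2, 3, 4), 3.0))
    for arr in (enc.k_w_avg, enc.k_w_max, enc.k_h_avg, enc.k_h_max):
        np.testing.assert_allclose(arr.data, 3.0)


def test_encode_matches_loop_oracle(rng):
    for _ in range(20):
        T = rng.standard_normal((int(rng.integers(1, 4)),
                                 int(rng.integers(1, 6)),
                                 int(rng.integers(1, 6))))
        enc = aca_encode(T)
        kwa, kwm, kha, khm = _encode_loops(T)
        np.testing.assert_allclose(enc.k_w_avg.data[0], kwa, atol=1e-12)
        np.testing.assert_allclose(enc.k_w_max.data[0], kwm, atol=1e-12)
        np.testing.assert_allclose(enc.k_h_avg.data[0], kha, atol=1e-12)
        np.testing.assert_allclose(enc.k_h_max.data[0], khm, atol=1e-12)
        assert (enc.k_w_max.data >= enc.k_w_avg.data - 1e-12).all()
        assert (enc.k_h_max.data >= enc.k_h_avg.data - 1e-12).all()


def test_max_encoding_invariant_to_dominated_pixels(rng):
    T = rng.standard_normal((1, 4, 4))
    T[0, 2, :] += 50.0  # one dominant row
    enc1 = aca_encode(T.copy())
    T2 = T.copy()
    T2[0, 0, :] -= rng.random(4)  # perturb dominated pixels only
    enc2 = aca_encode(T2)
    np.testing.assert_array_equal(enc1.k_w_max.data, enc2.k_w_max.data)


# ----------------------------------------------------------------------
# the ACA chain
# ----------------------------------------------------------------------

def test_aca_apply_cases(rng):
    T = rng.standard_normal((2, 3, 4))
    y = aca_apply(T, np.full((2, 3), 0.5), np.full((2, 4), 0.5))
    np.testing.assert_allclose(y.data, T / 4.0, atol=1e-12)
    f_h = np.ones((1, 2))
    f_h[0, 1] = 0.0
    y = aca_apply(rng.standard_normal((1, 2, 2)), f_h, np.ones((1, 2)))
    np.testing.assert_allclose(y.data[0, 1], 0.0)


def test_aca_forward_matches_stagewise_oracle(rng):
    for _ in range(10):
        C, H, W = 3, int(rng.integers(2, 6)), int(rng.integers(2, 6))
        mod = AdaptiveCoordinateAttention(C, reduction=2,
                                          rng=np.random.default_rng(int(rng.integers(1 << 30))),
                                          dtype=np.float64)
        mod.g1.data = np.asarray(float(rng.random()))
        mod.g2.data = np.asarray(float(rng.random()))
        T = rng.standard_normal((C, H, W))
        got = mod(T).data
        want, f_h, f_w = _aca_oracle(T, *_aca_params(mod),
                                     float(mod.g1.data), float(mod.g2.data))
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)
        assert ((0 < f_h) & (f_h < 1)).all() and ((0 < f_w) & (f_w < 1)).all()


def test_aca_gating_preserves_sign(rng):
    mod = AdaptiveCoordinateAttention(2, rng=rng, dtype=np.float64)
    T = rng.standard_normal((2, 5, 5))
    y = mod(T).data
    assert (np.sign(y) == np.sign(T))[np.abs(T) > 1e-9].all()
    assert y.shape == T.shape


def test_aca_with_g2_zero_equals_ca_baseline(rng):
    """Dropping the max branch must reproduce classical coordinate attention
    exactly, given shared transform weights."""
    aca = AdaptiveCoordinateAttention(4, reduction=2, rng=np.random.default_rng(0),
                                      dtype=np.float64)
    ca = CoordinateAttention(4, reduction=2, rng=np.random.default_rng(1),
                             dtype=np.float64)
    for src, dst in ((aca.f1, ca.f1), (aca.fh, ca.fh), (aca.fw, ca.fw)):
        dst.weight.data = src.weight.data.copy()
        dst.bias.data = src.bias.data.copy()
    aca.g1.data = np.asarray(1.0)
    aca.g2.data = np.asarray(0.0)
    T = rng.standard_normal((2, 4, 6, 5))
    np.testing.assert_array_equal(aca(T).data, ca(T).data)


def test_se_constant_input_uniform_scaling(rng):
    se = SqueezeExcitation(3, reduction=1, rng=rng, dtype=np.float64)
    T = np.full((1, 3, 4, 4), 2.0)
    y = se(T).data
    for c in range(3):
        assert np.ptp(y[0, c]) == pytest.approx(0.0, abs=1e-12)


# ----------------------------------------------------------------------
# windowed self-attention
# ----------------------------------------------------------------------

def test_window_partition_roundtrip(rng):
    x = Tensor(rng.standard_normal((2, 3, 8, 8)))
    for shifted in (False, True):
        t = window_partition(x, 4, shifted)
        back = window_reverse(t, 4, (8, 8), shifted)
        np.testing.assert_array_equal(back.data, x.data)


def test_window_partition_hand_indices():
    x = Tensor(np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4))
    t = window_partition(x, 2, shifted=False)
    assert t.shape == (4, 4, 1)
    np.testing.assert_array_equal(t.data[0, :, 0], [0, 1, 4, 5])
    np.testing.assert_array_equal(t.data[1, :, 0], [2, 3, 6, 7])
    np.testing.assert_array_equal(t.data[3, :, 0], [10, 11, 14, 15])


def test_double_shift_is_identity(rng):
    x = rng.standard_normal((1, 2, 4, 4))
    rolled = np.roll(np.roll(x, -2, axis=2), -2, axis=3)
    np.testing.assert_array_equal(np.roll(np.roll(rolled, -2, axis=2), -2, axis=3), x)


def test_relative_position_index_sharing():
    M = 3
    idx = relative_position_index(M)
    assert idx.shape == (9, 9)
    assert idx.max() == (2 * M - 1) ** 2 - 1
    # equal displacement -> equal table entry: token (0,0)->(1,1) vs (1,1)->(2,2)
    assert idx[0, 4] == idx[4, 8]
    # and the map is symmetric under displacement negation pairs
    assert idx[4, 0] == idx[8, 4]


def test_attention_core_gate_off_equals_plain_sdpa(rng):
    Q = rng.standard_normal((5, 4))
    K = rng.standard_normal((5, 4))
    V = rng.standard_normal((5, 4))
    B = rng.standard_normal((5, 5))
    gated, _ = attention_core(Q, K, V, B, 0.0)
    plain, _ = attention_core(Q, K, V, None, 0.0)
    np.testing.assert_array_equal(gated.data, plain.data)


def test_attention_core_uniform_when_logits_zero(rng):
    V = rng.standard_normal((6, 3))
    out, attn = attention_core(np.zeros((6, 3)), np.zeros((6, 3)), V, None, 0.0)
    np.testing.assert_allclose(out.data, np.tile(V.mean(axis=0), (6, 1)), atol=1e-12)
    np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)


def test_attention_core_matches_loop_oracle(rng):
    for _ in range(25):
        N, d = int(rng.integers(2, 6)), int(rng.integers(1, 5))
        Q, K, V = (rng.standard_normal((N, d)) for _ in range(3))
        B = rng.standard_normal((N, N))
        ga = float(rng.standard_normal())
        got, attn = attention_core(Q, K, V, B, ga)
        np.testing.assert_allclose(got.data, _attention_oracle(Q, K, V, B, ga),
                                   rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_core_rejects_zero_dim():
    with pytest.raises(ValueError):
        attention_core(np.zeros((2, 0)), np.zeros((2, 0)), np.zeros((2, 0)), None, 0.0)


def test_psa_bias_gathered_from_table(rng):
    psa = PatchSelfAttention(4, window=2, heads=2, rng=rng, dtype=np.float64)
    bias = psa.gathered_bias().data
    idx = relative_position_index(2)
    for h in range(2):
        np.testing.assert_array_equal(bias[h], psa.bias_table.data[idx, h])


def test_gsa_block_identity_when_outputs_zeroed(rng):
    blk = GSABlock(4, window=2, heads=1, rng=rng, dtype=np.float64)
    for psa in (blk.psa1, blk.psa2):
        psa.proj.weight.data[:] = 0.0
        psa.proj.bias.data[:] = 0.0
    for mlp in (blk.mlp1, blk.mlp2):
        mlp.fc2.weight.data[:] = 0.0
        mlp.fc2.bias.data[:] = 0.0
    x = rng.standard_normal((1, 4, 4, 4))
    np.testing.assert_array_equal(blk(Tensor(x)).data, x)


def test_gsa_block_shape_contract(rng):
    blk = GSABlock(6, window=3, heads=2, rng=rng, dtype=np.float64)
    x = rng.standard_normal((2, 6, 6, 6))
    assert blk(Tensor(x)).shape == x.shape


def test_gsa_gate_zero_equals_biasfree_window_attention(rng):
    psa = PatchSelfAttention(4, window=2, heads=1, rng=rng, dtype=np.float64)
    tokens = Tensor(rng.standard_normal((3, 4, 4)))
    psa.ga.data = np.asarray(0.0)
    gated = psa(tokens).data
    # oracle: same weights, bias term removed entirely
    h, dh = 1, 4
    qkv = tokens.data @ psa.qkv.weight.data + psa.qkv.bias.data
    q, k, v = qkv[..., :4], qkv[..., 4:8], qkv[..., 8:]
    plain = np.empty_like(v)
    for b in range(3):
        logits = q[b] @ k[b].T / math.sqrt(dh)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        plain[b] = (e / e.sum(axis=-1, keepdims=True)) @ v[b]
    plain = plain @ psa.proj.weight.data + psa.proj.bias.data
    np.testing.assert_allclose(gated, plain, rtol=1e-9, atol=1e-12)


def test_gsa_gate_frozen_one_equals_sw_baseline(rng):
    gsa = GSABlock(4, window=2, heads=1, gate_mode="learnable",
                   rng=np.random.default_rng(0), dtype=np.float64)
    sw = GSABlock(4, window=2, heads=1, gate_mode="fixed",
                  rng=np.random.default_rng(5), dtype=np.float64)
    shared = {k: v for k, v in gsa.state_dict().items() if not k.endswith(".ga")}
    sw.load_state_dict(shared)  # ga stays at its init of 1.0 == the frozen gate
    x = Tensor(rng.standard_normal((1, 4, 4, 4)))
    np.testing.assert_array_equal(gsa(x).data, sw(x).data)
    # the fixed gate exposes no learnable ga
    assert "psa1.ga" not in dict(sw.named_parameters())
    assert "psa1.ga" in dict(gsa.named_parameters())


def test_baseline_blocks_interfaces(rng):
    blocks = baseline_blocks(8, window=2, rng=rng, dtype=np.float64)
    x = rng.standard_normal((1, 8, 4, 4))
    for name in ("SE", "CA"):
        assert blocks[name](x).shape == x.shape
    assert blocks["SW"](Tensor(x)).shape == x.shape
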