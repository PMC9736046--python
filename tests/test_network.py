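"""Model assembly: sub-network contracts, fusion/correction oracles,
six-patch forward bundle, and the static compute profile."""

import numpy as np
import pytest

from vesselseg.network import (ModelConfig, CollabPatchNet, count_flops_params,
                               save_checkpoint, load_checkpoint, SOBEL_X)
from vesselseg.patch_engine import PatchGeometry
from vesselseg.nn.tensor import Tensor


GEO = PatchGeometry(s=24, l=48)


def _model(**kw):
    kw.setdefault("channels", (4, 8))
    kw.setdefault("geometry", GEO)
    return CollabPatchNet(ModelConfig(**kw))


def _inputs(rng, B=2, collaborative=True):
    small = rng.random((B, 1, GEO.s, GEO.s), dtype=np.float32)
    larges = rng.random((B, 5, 1, GEO.l, GEO.l), dtype=np.float32) if collaborative else None
    return small, larges


class TestConfig:
    def test_channel_ladder_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ModelConfig(channels=(8, 8), geometry=GEO)

    def test_patch_not_divisible_by_stride(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(channels=(4, 8, 16, 32), geometry=PatchGeometry(s=30, l=60))

    def test_auto_window_divides_both_bottlenecks(self):
        cfg = ModelConfig(channels=(4, 8, 16), geometry=PatchGeometry(s=72, l=144))
        M = cfg.resolved_window()
        assert (72 // 4) % M == 0 and (144 // 4) % M == 0


class TestPreSegment:
    def test_probability_range_and_shape(self, tiny_model, rng):
        small, _ = _inputs(rng)
        feat, prob = tiny_model.pre_segment(small)
        assert prob.shape == (2, 1, GEO.s, GEO.s)
        assert feat.shape == (2, 4, GEO.s, GEO.s)
        assert 0.0 <= prob.data.min() and prob.data.max() <= 1.0

    def test_fully_convolutional_size_doubling(self, tiny_model, rng):
        x1 = rng.random((1, 1, 24, 24), dtype=np.float32)
        x2 = rng.random((1, 1, 48, 48), dtype=np.float32)
        _, p1 = tiny_model.pre_segment(x1)
        _, p2 = tiny_model.pre_segment(x2)
        assert p1.shape[-1] * 2 == p2.shape[-1]

    def test_rejects_indivisible_input(self, tiny_model, rng):
        with pytest.raises(ValueError, match="divisible"):
            tiny_model.pre_segment(rng.random((1, 1, 25, 25), dtype=np.float32))


class TestEdgeBranch:
    def test_constant_input_sobel_response_zero(self, tiny_model):
        x = Tensor(np.full((1, 1, 24, 24), 0.7, dtype=np.float32))
        first = tiny_model.edge.first_layer(x).data
        # interior only: zero padding makes the image border itself an edge
        np.testing.assert_allclose(first[0, :2, 1:-1, 1:-1], 0.0, atol=1e-6)

    def test_step_edge_stronger_than_flat(self, tiny_model):
        img = np.zeros((1, 1, 24, 24), dtype=np.float32)
        img[..., 12:] = 1.0  # vertical step edge at column 12
        first = tiny_model.edge.first_layer(Tensor(img)).data
        sobel = np.abs(first[0, :2])
        on_edge = sobel[:, :, 11:13].mean()
        off_edge = sobel[:, :, :8].mean()
        assert on_edge > 10 * (off_edge + 1e-9)

    def test_output_contract(self, tiny_model, rng):
        small, _ = _inputs(rng)
        e = tiny_model.edge_branch(small)
        assert e.shape == (2, 1, GEO.s, GEO.s)
        assert 0.0 <= e.data.min() and e.data.max() <= 1.0

    def test_sobel_kernels_installed(self, tiny_model):
        np.testing.assert_allclose(tiny_model.edge.c1.weight.data[0, 0], SOBEL_X, atol=1e-7)
        np.testing.assert_allclose(tiny_model.edge.c1.weight.data[1, 0], SOBEL_X.T, atol=1e-7)


class TestFusion:
    def test_identical_inputs_order_invariant(self, rng):
        m = _model()
        f = rng.random((1, 4, GEO.l, GEO.l), dtype=np.float32)
        stacked = Tensor(np.concatenate([f] * 5, axis=0))
        out1 = m.fusion(stacked).data
        out2 = m.fusion(stacked).data
        np.testing.assert_array_equal(out1, out2)
        assert out1.shape == (1, m.config.fusion_out, GEO.s, GEO.s)

    def test_zero_inputs_zero_bias_gives_zero(self, rng):
        m = _model()
        m.fusion.shared.bias.data[:] = 0
        m.fusion.proj.bias.data[:] = 0
        z = Tensor(np.zeros((5, 4, GEO.l, GEO.l), dtype=np.float32))
        np.testing.assert_allclose(m.fusion(z).data, 0.0, atol=1e-7)

    def test_stagewise_oracle_single_channel(self, rng):
        """Hand-evaluate: shared conv on each cut region -> concat -> SE gate
        -> 1x1 projection."""
        from vesselseg.nn import functional as F
        m = _model()
        m.astype(np.float64)
        feats = rng.standard_normal((5, 4, GEO.l, GEO.l))
        got = m.fusion(Tensor(feats)).data
        pieces = []
        for i, (r, c) in enumerate(GEO.placements):
            cut_f = feats[i:i + 1, :, r:r + GEO.s, c:c + GEO.s]
            pieces.append(F.conv2d(Tensor(cut_f), m.fusion.shared.weight,
                                   m.fusion.shared.bias).data)
        cat = np.concatenate(pieces, axis=1)
        gated = m.fusion.gate.se(Tensor(cat)).data
        want = F.conv2d(Tensor(gated), m.fusion.proj.weight, m.fusion.proj.bias).data
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


class TestCorrection:
    def test_ablation_path_keeps_shape_contract(self, rng):
        m = _model(use_collaborative=False)
        small, _ = _inputs(rng, collaborative=False)
        bundle = m.forward(small, None)
        assert bundle.seg_small.shape == (2, 1, GEO.s, GEO.s)
        assert bundle.seg_larges is None

    def test_cut_alignment_uses_recorded_offsets(self, rng):
        m = _model()
        m.eval()
        small, larges = _inputs(rng)
        bundle = m.forward(small, larges)
        assert bundle.corrected.shape == (2, 5 * m.config.corr_mid, GEO.s, GEO.s)
        assert bundle.seg_larges.shape == (10, 1, GEO.l, GEO.l)


class TestForward:
    def test_bundle_contracts(self, tiny_model, rng):
        small, larges = _inputs(rng)
        b = tiny_model.forward(small, larges)
        for prob in (b.seg_small, b.pre_prob_small, b.edge_map, b.pre_probs_large,
                     b.seg_larges):
            assert 0.0 <= prob.data.min() and prob.data.max() <= 1.0
        assert b.seg_small.shape == (2, 1, GEO.s, GEO.s)
        assert b.fused.shape[2:] == (GEO.s, GEO.s)

    def test_missing_larges_rejected_when_collaborative(self, tiny_model, rng):
        small, _ = _inputs(rng)
        with pytest.raises(ValueError, match="large"):
            tiny_model.forward(small, None)

    def test_batch_independence_in_eval(self, tiny_model, rng):
        small, larges = _inputs(rng, B=3)
        b = tiny_model.forward(small, larges)
        perm = [2, 0, 1]
        bp = tiny_model.forward(small[perm], larges[perm])
        np.testing.assert_allclose(bp.seg_small.data, b.seg_small.data[perm],
                                   rtol=1e-5, atol=1e-7)

    def test_eval_forward_deterministic(self, tiny_model, rng):
        small, larges = _inputs(rng)
        a = tiny_model.forward(small, larges).seg_small.data
        b = tiny_model.forward(small, larges).seg_small.data
        np.testing.assert_array_equal(a, b)

    def test_neutralized_attention_equals_plain_network(self, rng):
        """Disabling every attention block must reduce the model to the plain
        two-stage baseline with the same convolution weights."""
        att = _model(channel_attention="aca", self_attention="gsa", seed=3)
        plain = _model(channel_attention="none", self_attention="none", seed=9)
        plain_names = set(dict(plain.named_parameters()))
        shared = {k: v for k, v in att.state_dict().items()
                  if k in plain_names or k.endswith(("running_mean", "running_var"))}
        plain.load_state_dict(shared)
        for blk in att.main.attns:
            blk.enabled = False
        if att.main.bottleneck is not None:
            att.main.bottleneck.enabled = False
        att.eval(); plain.eval()
        rng2 = np.random.default_rng(11)
        small, larges = _inputs(rng2)
        np.testing.assert_array_equal(att.forward(small, larges).seg_small.data,
                                      plain.forward(small, larges).seg_small.data)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        m = _model(seed=7)
        m.eval()
        small, larges = _inputs(rng)
        ref = m.forward(small, larges).seg_small.data
        path = str(tmp_path / "ck.npz")
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        m2.eval()
        np.testing.assert_array_equal(m2.forward(small, larges).seg_small.data, ref)


class TestComputeProfile:
    def test_single_conv_closed_form(self):
        from vesselseg.network import _conv_macs
        assert _conv_macs(1, 32, 3, 72, 72) == 9 * 1 * 32 * 72 * 72
        # parameters of a lone 3x3 conv 1->32: 32*9 + 32 bias
        from vesselseg import nn
        conv = nn.Conv2d(1, 32, 3)
        assert sum(p.data.size for p in conv.parameters()) == 320

    def test_params_independent_of_input_size(self):
        cfg = ModelConfig(channels=(4, 8), geometry=GEO)
        _, p1, _ = count_flops_params(cfg, mode="single")
        _, p2, _ = count_flops_params(cfg, mode="whole_image", image_shape=(96, 96))
        assert p1 == p2

    def test_patch_regime_far_cheaper_than_whole_image(self):
        cfg = ModelConfig(channels=(32, 64, 128, 256),
                          geometry=PatchGeometry(s=72, l=144))
        collab, _, _ = count_flops_params(cfg, mode="collaborative_marginal")
        single, _, _ = count_flops_params(cfg, mode="single")
        whole, _, _ = count_flops_params(cfg, mode="whole_image", image_shape=(584, 565))
        assert collab < 0.05 * whole
        assert single < collab < 1.10 * single
        total, _, _ = count_flops_params(cfg, mode="collaborative_total")
        assert total > 5 * single  # the five large passes dominate total cost
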