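"""Two-stage multi-feature segmentation network with collaborative patches.

The model cascades two U-Net sub-networks.  The *pre-segmentation*
sub-network produces a rough vessel probability and a feature map for each
of the six patches (one small target patch, five large neighbourhood
patches).  An *associated-information fusion* module extracts, from the
five large-patch pre-features, the neighbourhood context the small patch
lost at its borders, aligned to the target region by the geometry's cut
operator.  The *main* sub-network — U-Net plus adaptive coordinate
attention after each encoder block and a gated self-attention block at the
bottleneck — refines the segmentation; an *associated-information
correction* head re-extracts neighbourhood context from the main-stage
large-patch features and merges it with the small-patch feature to produce
the final probability map.  A shallow learnable edge branch (Sobel-pair
initialised) feeds a vessel-edge map into the main encoder input.

Both sub-networks are fully convolutional and share their weights across
small and large patches.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor
from .attention import (AdaptiveCoordinateAttention, CoordinateAttention,
                        SqueezeExcitation, GSABlock)
from .patch_engine import PatchGeometry

__all__ = ["ModelConfig", "ForwardBundle", "CollabPatchNet",
           "count_flops_params", "save_checkpoint", "load_checkpoint"]


def _auto_window(small_feat: int, large_feat: int, preferred: int = 6) -> int:
    """Largest window <= preferred dividing both bottleneck sides."""
    for m in range(min(preferred, small_feat), 0, -1):
        if small_feat % m == 0 and large_feat % m == 0:
            return m
    return 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration.

    ``channels`` is the encoder ladder (strictly increasing); the decoder
    mirrors it.  ``channel_attention`` selects the per-encoder-stage block
    in the main sub-network ('aca' | 'se' | 'ca' | 'none'); the
    ``self_attention`` block sits at the main bottleneck
    ('gsa' | 'sw' | 'none').  ``window=0`` picks the largest size <= 6 that
    divides both small- and large-patch bottleneck maps.
    """

    channels: tuple = (32, 64, 128, 256)
    geometry: PatchGeometry = field(default_factory=PatchGeometry)
    channel_attention: str = "aca"
    self_attention: str = "gsa"
    use_edge_branch: bool = True
    use_collaborative: bool = True
    reduction: int = 8
    window: int = 0
    mlp_ratio: int = 4
    fusion_mid: int = 8       # shared 3x3 conv output channels, fusion module
    fusion_out: int = 16      # fused associated-feature channels fed to the main net
    corr_mid: int = 8         # shared 3x3 conv output channels, correction head
    pre_input: str = "features"   # 'features' | 'probability' (what fusion consumes)
    seed: int = 0

    def __post_init__(self):
        ch = tuple(self.channels)
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError("channel ladder must be strictly increasing")
        if self.channel_attention not in ("aca", "se", "ca", "none"):
            raise ValueError(f"unknown channel_attention {self.channel_attention!r}")
        if self.self_attention not in ("gsa", "sw", "none"):
            raise ValueError(f"unknown self_attention {self.self_attention!r}")
        if self.pre_input not in ("features", "probability"):
            raise ValueError(f"unknown pre_input {self.pre_input!r}")
        ds = self.downsample
        g = self.geometry
        if g.s % ds or g.l % ds:
            raise ValueError(
                f"patch sides {g.s}/{g.l} not divisible by the network stride {ds}")
        object.__setattr__(self, "channels", ch)

    @property
    def depth(self) -> int:
        return len(self.channels)

    @property
    def downsample(self) -> int:
        return 2 ** (self.depth - 1)

    def resolved_window(self) -> int:
        if self.window:
            return self.window
        g = self.geometry
        return _auto_window(g.s // self.downsample, g.l // self.downsample)

    @property
    def pre_channels(self) -> int:
        """Channels of the pre-segmentation output consumed downstream."""
        return 1 if self.pre_input == "probability" else self.channels[0]

    @property
    def main_in_channels(self) -> int:
        # patch + pre feature + fused context (zeros when non-collaborative) + edge
        return 1 + self.pre_channels + self.fusion_out + 1


@dataclass
class ForwardBundle:
    """All tensors produced by one collaborative forward pass."""

    pre_feat_small: Tensor
    pre_prob_small: Tensor
    edge_map: Tensor | None
    fused: Tensor                 # associated-information feature, s-aligned
    main_feat_small: Tensor
    seg_small: Tensor             # final small-patch probability
    pre_probs_large: Tensor | None = None   # (5B, 1, l, l)
    main_feats_large: Tensor | None = None  # (5B, C0, l, l)
    corrected: Tensor | None = None
    seg_larges: Tensor | None = None        # (5B, 1, l, l) auxiliary heads


class ConvBlock(nn.Module):
    """(Conv3x3 - InstanceNorm - ReLU) x 2.

    Instance normalization rather than batch normalization: train batches
    mix 72- and 144-pixel patches with different statistics, and inference
    tiles whole images, so any batch-statistic normalizer would behave
    differently between training and evaluation.
    """

    def __init__(self, in_ch, out_ch, rng, dtype=np.float32):
        super().__init__()
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng=rng, dtype=dtype)
        self.b1 = nn.InstanceNorm2d(out_ch, dtype=dtype)
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng, dtype=dtype)
        self.b2 = nn.InstanceNorm2d(out_ch, dtype=dtype)

    def forward(self, x):
        x = F.relu(self.b1(self.c1(x)))
        return F.relu(self.b2(self.c2(x)))


class UNet(nn.Module):
    """Encoder-decoder with skip connections; optional per-stage attention
    and an optional extra block at the bottleneck."""

    def __init__(self, in_ch, channels, rng, dtype=np.float32,
                 attn_factory=None, bottleneck=None, with_head=True):
        super().__init__()
        depth = len(channels)
        self.depth = depth
        self.enc = nn.ModuleList()
        self.attns = nn.ModuleList()
        prev = in_ch
        for i, c in enumerate(channels):
            self.enc.append(ConvBlock(prev, c, rng, dtype))
            attn = attn_factory(c, i) if attn_factory else None
            self.attns.append(attn if attn is not None else nn.Module())
            prev = c
        self.bottleneck = bottleneck
        self.dec = nn.ModuleList()
        for i in range(depth - 2, -1, -1):
            self.dec.append(ConvBlock(channels[i + 1] + channels[i], channels[i], rng, dtype))
        self.head = nn.Conv2d(channels[0], 1, 1, rng=rng, dtype=dtype) if with_head else None

    def forward(self, x):
        if x.shape[-1] % (2 ** (self.depth - 1)) or x.shape[-2] % (2 ** (self.depth - 1)):
            raise ValueError(
                f"input spatial size {x.shape[-2:]} not divisible by 2^{self.depth - 1}")
        skips = []
        for i in range(self.depth):
            if i:
                x = F.maxpool2d(x)
            x = self.enc[i](x)
            attn = self.attns[i]
            if isinstance(attn, nn.Module) and hasattr(attn, "forward") and getattr(attn, "enabled", True):
                x = attn(x)
            skips.append(x)
        if self.bottleneck is not None and getattr(self.bottleneck, "enabled", True):
            x = self.bottleneck(x)
        for j, block in enumerate(self.dec):
            skip = skips[self.depth - 2 - j]
            x = F.upsample_nearest2(x)
            x = block(F.concatenate([skip, x], axis=1))
        prob = F.sigmoid(self.head(x)) if self.head is not None else None
        return x, prob


SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64) / 4.0


class EdgeBranch(nn.Module):
    """Shallow learnable edge extractor; first layer starts from Sobel pairs."""

    def __init__(self, rng, dtype=np.float32, width: int = 4):
        super().__init__()
        self.c1 = nn.Conv2d(1, width, 3, rng=rng, dtype=dtype)
        w = self.c1.weight.data.copy()
        w[0, 0] = SOBEL_X
        w[1, 0] = SOBEL_X.T
        self.c1.weight.data = w.astype(dtype)
        self.c2 = nn.Conv2d(width, 2 * width, 3, rng=rng, dtype=dtype)
        self.c3 = nn.Conv2d(2 * width, 1, 3, rng=rng, dtype=dtype)

    def first_layer(self, x):
        return self.c1(x)

    def forward(self, x):
        h = F.relu(self.c1(x))
        h = F.relu(self.c2(h))
        return F.sigmoid(self.c3(h))


class _ChannelGate(nn.Module):
    """Global-pool channel attention used inside fusion/correction heads."""

    def __init__(self, channels, rng, dtype=np.float32, reduction: int = 4):
        super().__init__()
        self.se = SqueezeExcitation(channels, reduction, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.se(x)


class AssociatedFusion(nn.Module):
    """Fuse the five large-patch pre-segmentation features into an s-aligned
    associated-information feature: shared 3x3 conv on each cut region,
    channel concatenation, channel attention, 1x1 projection."""

    def __init__(self, in_ch, mid, out, geometry: PatchGeometry, rng, dtype=np.float32):
        super().__init__()
        self.geometry = geometry
        self.shared = nn.Conv2d(in_ch, mid, 3, rng=rng, dtype=dtype)
        self.gate = _ChannelGate(5 * mid, rng, dtype)
        self.proj = nn.Conv2d(5 * mid, out, 1, rng=rng, dtype=dtype)

    def forward(self, larges_feat: Tensor) -> Tensor:
        """larges_feat: (5B, C, l, l) stacked in placement-major order."""
        g = self.geometry
        B5 = larges_feat.shape[0]
        B = B5 // 5
        pieces = []
        for i, off in enumerate(g.placements):
            fi = larges_feat[i * B:(i + 1) * B]
            fi = fi[:, :, off[0]:off[0] + g.s, off[1]:off[1] + g.s]
            pieces.append(self.shared(fi))
        cat = F.concatenate(pieces, axis=1)
        return self.proj(self.gate(cat))


class CorrectionHead(nn.Module):
    """Associated-information correction + final segmentation.

    Each main-stage large-patch feature is cut to the target region and
    passed through a shared 3x3 conv; the five results are concatenated,
    channel-gated into the correction feature, concatenated with the
    small-patch main feature and reduced by a 3x3 then 1x1 convolution to
    the final probability.  A shared 1x1 head on the uncut large features
    provides the auxiliary large-patch segmentations.
    """

    def __init__(self, feat_ch, mid, geometry: PatchGeometry, rng, dtype=np.float32):
        super().__init__()
        self.geometry = geometry
        self.mid = mid
        self.shared = nn.Conv2d(feat_ch, mid, 3, rng=rng, dtype=dtype)
        self.gate = _ChannelGate(5 * mid, rng, dtype)
        self.aux_head = nn.Conv2d(feat_ch, 1, 1, rng=rng, dtype=dtype)
        self.merge = nn.Conv2d(feat_ch + 5 * mid, feat_ch, 3, rng=rng, dtype=dtype)
        self.head = nn.Conv2d(feat_ch, 1, 1, rng=rng, dtype=dtype)

    def forward(self, f_ms: Tensor, main_larges: Tensor | None):
        g = self.geometry
        B = f_ms.shape[0]
        if main_larges is None:
            z = Tensor(np.zeros((B, 5 * self.mid, g.s, g.s), dtype=f_ms.dtype))
            seg_larges = None
            f_mlt = z
        else:
            pieces = []
            for i, off in enumerate(g.placements):
                fi = main_larges[i * B:(i + 1) * B]
                fi = fi[:, :, off[0]:off[0] + g.s, off[1]:off[1] + g.s]
                pieces.append(self.shared(fi))
            f_mlt = self.gate(F.concatenate(pieces, axis=1))
            seg_larges = F.sigmoid(self.aux_head(main_larges))
        merged = self.merge(F.concatenate([f_ms, f_mlt], axis=1))
        seg_small = F.sigmoid(self.head(F.relu(merged)))
        return seg_small, seg_larges, f_mlt


class CollabPatchNet(nn.Module):
    """The full two-stage collaborative-patch segmentation model."""

    def __init__(self, config: ModelConfig, dtype=np.float32):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        self.pre = UNet(1, ch, rng, dtype, with_head=True)
        self.edge = EdgeBranch(rng, dtype) if config.use_edge_branch else None
        self.fusion = AssociatedFusion(config.pre_channels, config.fusion_mid,
                                       config.fusion_out, config.geometry, rng, dtype)

        def attn_factory(c, stage):
            kind = config.channel_attention
            if kind == "aca":
                return AdaptiveCoordinateAttention(c, config.reduction, rng=rng, dtype=dtype)
            if kind == "se":
                return SqueezeExcitation(c, config.reduction, rng=rng, dtype=dtype)
            if kind == "ca":
                return CoordinateAttention(c, config.reduction, rng=rng, dtype=dtype)
            return None

        bott = None
        if config.self_attention != "none":
            M = config.resolved_window()
            ds = config.downsample
            if (config.geometry.s // ds) % M or (config.geometry.l // ds) % M:
                raise ValueError(
                    f"window {M} does not divide the bottleneck maps "
                    f"{config.geometry.s // ds}/{config.geometry.l // ds}")
            heads = max(1, ch[-1] // 32)
            gate = "learnable" if config.self_attention == "gsa" else "fixed"
            bott = GSABlock(ch[-1], M, heads, config.mlp_ratio, gate, rng, dtype)
        self.main = UNet(config.main_in_channels, ch, rng, dtype,
                         attn_factory=attn_factory, bottleneck=bott, with_head=False)
        self.correction = CorrectionHead(ch[0], config.corr_mid, config.geometry, rng, dtype)

    # -- stage ops ------------------------------------------------------
    def pre_segment(self, patch):
        """Rough segmentation: last decoder feature + sigmoid probability."""
        x = patch if isinstance(patch, Tensor) else Tensor(np.asarray(patch))
        return self.pre(x)

    def edge_branch(self, patch):
        if self.edge is None:
            return None
        x = patch if isinstance(patch, Tensor) else Tensor(np.asarray(patch))
        return self.edge(x)

    def _pre_out(self, feat, prob):
        return prob if self.config.pre_input == "probability" else feat

    def forward(self, small, larges=None) -> ForwardBundle:
        """Run the six-patch forward pass.

        small: (B, 1, s, s); larges: (B, 5, 1, l, l) (required when the
        collaborative path is enabled).
        """
        cfg = self.config
        g = cfg.geometry
        small = small if isinstance(small, Tensor) else Tensor(np.asarray(small))
        B = small.shape[0]
        f_ps, p_ps = self.pre(small)
        edge_s = self.edge(small) if self.edge is not None else None

        collaborative = cfg.use_collaborative and larges is not None
        if cfg.use_collaborative and larges is None:
            raise ValueError("collaborative model requires the five large patches")

        if collaborative:
            lt = larges if isinstance(larges, Tensor) else Tensor(np.asarray(larges))
            # placement-major stacking: patch i of every sample is contiguous
            lt = lt.transpose((1, 0, 2, 3, 4)).reshape((5 * B, 1, g.l, g.l))
            f_pl, p_pl = self.pre(lt)
            edge_l = self.edge(lt) if self.edge is not None else None
            fused = self.fusion(self._pre_out(f_pl, p_pl))
        else:
            lt = f_pl = p_pl = edge_l = None
            fused = Tensor(np.zeros((B, cfg.fusion_out, g.s, g.s), dtype=small.dtype))

        def main_input(img, pre_out, fused_feat, edge_map, side):
            parts = [img, pre_out]
            if fused_feat is None:
                fused_feat = Tensor(np.zeros((img.shape[0], cfg.fusion_out, side, side),
                                             dtype=img.dtype))
            parts.append(fused_feat)
            if edge_map is None:
                edge_map = Tensor(np.zeros((img.shape[0], 1, side, side), dtype=img.dtype))
            parts.append(edge_map)
            return F.concatenate(parts, axis=1)

        f_ms, _ = self.main(main_input(small, self._pre_out(f_ps, p_ps), fused, edge_s, g.s))
        if collaborative:
            f_ml, _ = self.main(main_input(lt, self._pre_out(f_pl, p_pl), None, edge_l, g.l))
        else:
            f_ml = None
        seg_small, seg_larges, f_mlt = self.correction(f_ms, f_ml)
        return ForwardBundle(
            pre_feat_small=f_ps, pre_prob_small=p_ps, edge_map=edge_s,
            fused=fused, main_feat_small=f_ms, seg_small=seg_small,
            pre_probs_large=p_pl, main_feats_large=f_ml,
            corrected=f_mlt, seg_larges=seg_larges,
        )


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(model: CollabPatchNet, path: str) -> None:
    """Write weights as .npz with a JSON sidecar recording the config."""
    state = model.state_dict()
    np.savez(path, **state)
    side = {k: v for k, v in asdict(model.config).items()}
    side["geometry"] = {"s": model.config.geometry.s, "l": model.config.geometry.l,
                        "placements": [list(p) for p in model.config.geometry.placements]}
    with open(path + ".json", "w") as fh:
        json.dump(side, fh, indent=2)


def load_checkpoint(path: str) -> CollabPatchNet:
    with open(path + ".json") as fh:
        side = json.load(fh)
    geo = side.pop("geometry")
    side["channels"] = tuple(side["channels"])
    side["geometry"] = PatchGeometry(
        s=geo["s"], l=geo["l"], placements=tuple(tuple(p) for p in geo["placements"]))
    model = CollabPatchNet(ModelConfig(**side))
    npz = path if path.endswith(".npz") or os.path.exists(path) else path + ".npz"
    with np.load(npz) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


# ----------------------------------------------------------------------
# static compute profile
# ----------------------------------------------------------------------

def _conv_macs(cin, cout, k, h, w):
    return k * k * cin * cout * h * w


def _block_macs(cin, cout, h, w):
    return _conv_macs(cin, cout, 3, h, w) + _conv_macs(cout, cout, 3, h, w)


def _unet_macs(in_ch, channels, h, w, cfg: ModelConfig | None = None,
               with_attention: bool = False, with_head: bool = True):
    macs = 0
    acts = 0
    depth = len(channels)
    hh, ww = h, w
    prev = in_ch
    for i, c in enumerate(channels):
        if i:
            hh, ww = hh // 2, ww // 2
        macs += _block_macs(prev, c, hh, ww)
        acts += 2 * c * hh * ww
        if with_attention and cfg is not None:
            macs += _attention_macs(cfg, c, hh, ww)
            if i == depth - 1:
                macs += _self_attention_macs(cfg, c, hh, ww)
        prev = c
    for i in range(depth - 2, -1, -1):
        hh, ww = hh * 2, ww * 2
        macs += _block_macs(channels[i + 1] + channels[i], channels[i], hh, ww)
        acts += 2 * channels[i] * hh * ww
    if with_head:
        macs += _conv_macs(channels[0], 1, 1, h, w)
    return macs, acts


def _attention_macs(cfg: ModelConfig, c, h, w):
    if cfg.channel_attention == "none":
        return 0
    cr = max(1, math.ceil(c / cfg.reduction))
    if cfg.channel_attention == "se":
        return 2 * c * cr
    n = 2 if cfg.channel_attention == "aca" else 1   # avg (+ max) branches
    macs = n * (h + w) * c * cr                       # shared bottleneck transform
    macs += (h + w) * cr * c                          # per-direction projections
    macs += c * h * w                                 # gating multiply
    return macs


def _self_attention_macs(cfg: ModelConfig, c, h, w):
    if cfg.self_attention == "none":
        return 0
    M = cfg.resolved_window()
    n = h * w
    per_pair = n * c * 3 * c + n * c * c              # qkv + proj
    per_pair += 2 * n * (M * M) * c                   # logits + weighted sum
    per_pair += 2 * n * c * cfg.mlp_ratio * c         # 2-layer MLP
    return 2 * per_pair


def _edge_macs(h, w, width=4):
    return (_conv_macs(1, width, 3, h, w) + _conv_macs(width, 2 * width, 3, h, w)
            + _conv_macs(2 * width, 1, 3, h, w))


def _fusion_macs(cfg: ModelConfig):
    s = cfg.geometry.s
    m = 5 * _conv_macs(cfg.pre_channels, cfg.fusion_mid, 3, s, s)
    m += 2 * (5 * cfg.fusion_mid) * max(1, (5 * cfg.fusion_mid) // 4)   # channel gate
    m += _conv_macs(5 * cfg.fusion_mid, cfg.fusion_out, 1, s, s)
    return m


def _correction_macs(cfg: ModelConfig, collaborative: bool, aux_hw=None):
    s = cfg.geometry.s
    c0 = cfg.channels[0]
    m = _conv_macs(c0 + 5 * cfg.corr_mid, c0, 3, s, s) + _conv_macs(c0, 1, 1, s, s)
    if collaborative:
        m += 5 * _conv_macs(c0, cfg.corr_mid, 3, s, s)
        m += 2 * (5 * cfg.corr_mid) * max(1, (5 * cfg.corr_mid) // 4)
        if aux_hw:
            m += 5 * _conv_macs(c0, 1, 1, *aux_hw)
    return m


def count_flops_params(config: ModelConfig, mode: str = "collaborative_marginal",
                       image_shape: tuple[int, int] = (584, 565)):
    """Static multiply-accumulate / parameter / activation-memory counts.

    Modes:
      * ``single`` — one small patch through pre + edge + main + final head.
      * ``collaborative_marginal`` — ``single`` plus the fusion and
        correction modules, which operate on target-region-sized features.
        This marginal accounting reflects the *model* cost of the
        collaborative strategy when large-patch feature extraction is
        shared across neighbouring targets in tiled inference.
      * ``collaborative_total`` — every operation of one six-patch forward,
        including the five large-patch passes through both sub-networks.
      * ``whole_image`` — the whole-graph alternative: one end-to-end pass
        over ``image_shape`` (padded up to the network stride).

    Returns ``(macs, n_params, activation_bytes)``; parameters are counted
    from a built model and are independent of input size.
    """
    g = config.geometry
    ch = config.channels
    model = CollabPatchNet(config)
    n_params = model.n_parameters()

    def patch_cost(side):
        pre, a1 = _unet_macs(1, ch, side, side, with_head=True)
        main, a2 = _unet_macs(config.main_in_channels, ch, side, side,
                              cfg=config, with_attention=True, with_head=False)
        e = _edge_macs(side, side) if config.use_edge_branch else 0
        return pre + main + e, a1 + a2

    small_macs, small_act = patch_cost(g.s)
    if mode == "single":
        macs = small_macs + _correction_macs(config, collaborative=False)
        act = small_act
    elif mode == "collaborative_marginal":
        macs = small_macs + _fusion_macs(config) + _correction_macs(config, True)
        act = small_act + 2 * 5 * config.fusion_mid * g.s * g.s
    elif mode == "collaborative_total":
        large_macs, large_act = patch_cost(g.l)
        macs = (small_macs + 5 * large_macs + _fusion_macs(config)
                + _correction_macs(config, True, aux_hw=(g.l, g.l)))
        act = small_act + 5 * large_act
    elif mode == "whole_image":
        ds = config.downsample
        H = math.ceil(image_shape[0] / ds) * ds
        W = math.ceil(image_shape[1] / ds) * ds
        pre, a1 = _unet_macs(1, ch, H, W, with_head=True)
        main, a2 = _unet_macs(config.main_in_channels, ch, H, W,
                              cfg=config, with_attention=True, with_head=False)
        e = _edge_macs(H, W) if config.use_edge_branch else 0
        macs = pre + main + e + _conv_macs(ch[0] + 5 * config.corr_mid, ch[0], 3, H, W) \
            + _conv_macs(ch[0], 1, 1, H, W)
        act = a1 + a2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return int(macs), int(n_params), int(act * 4)
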