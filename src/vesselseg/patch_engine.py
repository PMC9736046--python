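"""Collaborative patch geometry: one small target patch plus five large
neighbourhood patches, together with training-grid sampling, the ``cut``
operator that extracts the target region from a feature map, and tiled
full-image inference with mean stitching.

Conventions (fixed once for cut/stitch correctness): all coordinates are
0-based, row-major ``(row, col)``; patch ranges are half-open.  Border
targets are realised through reflective padding of width ``l - s`` so the
five large patches exist for every valid target origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatchGeometry", "PatchSet", "default_placements",
    "extract_collaborative", "cut", "sample_training_grid", "stitch",
]


def default_placements(s: int, l: int) -> list[tuple[int, int]]:
    """Five offsets of the target region inside a large patch: centre + four corners.

    With one placement per corner and one central, every side of the target's
    neighbourhood is represented no matter where the target lies in the image.
    """
    if l < s + 2:
        # five pairwise-distinct placements need at least a 3x3 offset lattice
        raise ValueError(f"large patch side l={l} must exceed small side s={s} by >= 2")
    d = l - s
    c = d // 2
    return [(c, c), (0, 0), (0, d), (d, 0), (d, d)]


@dataclass(frozen=True)
class PatchGeometry:
    """Geometry of a collaborative patch set.

    s, l: small/large patch sides in pixels (l > s); placements: the five
    (row, col) offsets of the target region's top-left corner inside each
    large patch.
    """

    s: int = 72
    l: int = 144
    placements: tuple = ()

    def __post_init__(self):
        if self.l <= self.s:
            raise ValueError(f"require l > s, got s={self.s}, l={self.l}")
        placements = tuple(self.placements) or tuple(default_placements(self.s, self.l))
        object.__setattr__(self, "placements", placements)
        if len(placements) != 5:
            raise ValueError("exactly five large-patch placements are required")
        if len(set(placements)) != 5:
            raise ValueError("placements must be pairwise distinct")
        d = self.l - self.s
        for (r, c) in placements:
            if not (0 <= r <= d and 0 <= c <= d):
                raise ValueError(f"placement {(r, c)} outside [0, {d}]^2")

    @property
    def pad(self) -> int:
        return self.l - self.s


@dataclass
class PatchSet:
    """One small target patch and its five large collaborative patches."""

    small: np.ndarray                 # (s, s)
    larges: np.ndarray                # (5, l, l)
    target_origin: tuple[int, int]    # in source-image coordinates
    offsets: tuple = field(default_factory=tuple)

    def validate(self):
        s = self.small.shape[0]
        for i, (r, c) in enumerate(self.offsets):
            if not np.array_equal(self.larges[i, r:r + s, c:c + s], self.small):
                raise ValueError(f"large patch {i} does not contain the small patch at {(r, c)}")


def extract_collaborative(image: np.ndarray, target_origin: tuple[int, int],
                          geometry: PatchGeometry) -> PatchSet:
    """Extract the small patch at ``target_origin`` and five large patches.

    ``image`` is a 2-D (preprocessed) array.  The small patch is the
    ``s x s`` window at ``target_origin``; each large patch contains that
    window at its recorded offset, realised via reflective padding near
    borders so the construction never fails for a valid origin.
    """
    if image.ndim != 2:
        raise ValueError("extract_collaborative expects a 2-D image")
    H, W = image.shape
    s, l, P = geometry.s, geometry.l, geometry.pad
    r0, c0 = target_origin
    if not (0 <= r0 <= H - s and 0 <= c0 <= W - s):
        raise ValueError(f"target origin {target_origin} outside image of shape {image.shape}")
    padded = np.pad(image, P, mode="reflect")
    small = image[r0:r0 + s, c0:c0 + s]
    larges = np.empty((5, l, l), dtype=image.dtype)
    for i, (orr, orc) in enumerate(geometry.placements):
        top = r0 + P - orr
        left = c0 + P - orc
        larges[i] = padded[top:top + l, left:left + l]
    return PatchSet(small=small.copy(), larges=larges,
                    target_origin=(r0, c0), offsets=geometry.placements)


def cut(feature: np.ndarray, offset: tuple[int, int], s: int, feature_stride: int = 1) -> np.ndarray:
    """Cut the target region out of a (C, l', l') feature map.

    ``offset`` and ``s`` are in input-pixel units; they are rescaled by
    ``feature_stride`` (the cumulative downsampling of the feature map) and
    must divide evenly — a geometry incompatible with the network stride is
    a build-time error, not a per-batch one.  Pure indexing, no interpolation.
    """
    r, c = offset
    if r % feature_stride or c % feature_stride or s % feature_stride:
        raise ValueError(
            f"offset {offset} / side {s} not divisible by feature stride {feature_stride}")
    r_, c_, s_ = r // feature_stride, c // feature_stride, s // feature_stride
    if feature.ndim == 2:
        return feature[r_:r_ + s_, c_:c_ + s_]
    return feature[..., r_:r_ + s_, c_:c_ + s_]


def sample_training_grid(image_shape: tuple[int, int], s: int, stride: int,
                         rng: np.random.Generator | None = None,
                         n_random: int = 0,
                         fov: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Target origins for training: a regular grid plus random origins.

    The grid steps by ``stride`` and always includes a final clamped row and
    column so the image is fully covered; random origins are sampled
    uniformly inside the FOV bounding box (whole image if ``fov`` is None).
    """
    H, W = image_shape[:2]
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if H < s or W < s:
        raise ValueError(f"image {image_shape} smaller than patch side {s}")

    def axis_positions(n):
        pos = list(range(0, n - s + 1, stride))
        if pos[-1] != n - s:
            pos.append(n - s)
        return pos

    origins = [(r, c) for r in axis_positions(H) for c in axis_positions(W)]
    if n_random > 0:
        if rng is None:
            raise ValueError("rng required when n_random > 0")
        if fov is not None and fov.any():
            rows, cols = np.nonzero(fov)
            r_lo, r_hi = rows.min(), rows.max()
            c_lo, c_hi = cols.min(), cols.max()
        else:
            r_lo, r_hi, c_lo, c_hi = 0, H - 1, 0, W - 1
        r_lo = min(r_lo, H - s)
        c_lo = min(c_lo, W - s)
        r_hi = min(r_hi, H - s)
        c_hi = min(c_hi, W - s)
        for _ in range(n_random):
            origins.append((int(rng.integers(r_lo, r_hi + 1)),
                            int(rng.integers(c_lo, c_hi + 1))))
    return origins


def stitch(predictions, image_shape: tuple[int, int]) -> np.ndarray:
    """Average overlapping patch predictions into a full probability map.

    ``predictions`` is an iterable of ``(target_origin, patch)`` with square
    patches; every image pixel must be covered by at least one patch.
    """
    H, W = image_shape[:2]
    acc = np.zeros((H, W), dtype=np.float64)
    cnt = np.zeros((H, W), dtype=np.int64)
    for (r, c), patch in predictions:
        s = patch.shape[0]
        if r < 0 or c < 0 or r + s > H or c + s > W:
            raise ValueError(f"patch at {(r, c)} of side {s} exceeds image {image_shape}")
        acc[r:r + s, c:c + s] += patch
        cnt[r:r + s, c:c + s] += 1
    if (cnt == 0).any():
        first = tuple(int(v) for v in np.argwhere(cnt == 0)[0])
        raise ValueError(f"uncovered pixel at {first}")
    return acc / cnt
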