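"""Fundus preprocessing: graying, CLAHE, gamma correction, augmentations.

The network consumes a single channel.  The green channel is the default
graying mode because vessels have their highest contrast there in fundus
photography; CIE luminance is available as an alternative.  Contrast is
then enhanced with contrast-limited adaptive histogram equalization and a
gamma curve.  Training-time augmentations apply the identical geometric
transform to image, ground truth and FOV; random erase perturbs the image
only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = ["PreprocessConfig", "to_gray", "clahe", "gamma_correct", "augment", "preprocess_image"]

_LUMA = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class PreprocessConfig:
    gray_mode: str = "green"          # "green" | "luminance"
    clahe_clip_limit: float = 2.0     # on the conventional 0-100 scale; /100 internally
    clahe_tile: int = 8               # tiles per image side
    gamma: float = 1.2
    rotate: bool = True
    rotate_any_angle: bool = False    # opt-in: arbitrary-angle with nearest-neighbour masks
    erase: bool = True
    flip_ud: bool = True
    flip_lr: bool = True
    erase_area: tuple = (0.02, 0.08)  # fraction of patch area
    rng_seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.clahe_tile < 1:
            raise ValueError("clahe_tile must be >= 1")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.gray_mode not in ("green", "luminance"):
            raise ValueError(f"unknown gray_mode {self.gray_mode!r}")


def to_gray(image: np.ndarray, mode: str = "green") -> np.ndarray:
    """H x W x 3 (uint8 or [0,1] float) -> single channel in [0, 1]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 input, got {image.shape}")
    img = image.astype(np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    if mode == "green":
        return img[:, :, 1]
    if mode == "luminance":
        r, g, b = _LUMA
        return r * img[:, :, 0] + g * img[:, :, 1] + b * img[:, :, 2]
    raise ValueError(f"unknown gray mode {mode!r}")


def clahe(image: np.ndarray, clip_limit: float = 2.0, tile: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image.

    ``clip_limit`` uses the conventional 0-100 scale (2.0 is a typical
    fundus setting) and is mapped to the [0,1] fraction the underlying
    implementation expects.  Deterministic; a constant image is returned
    unchanged (degenerate histogram).
    """
    if image.ndim != 2:
        raise ValueError("clahe expects a 2-D image")
    H, W = image.shape
    if tile < 1 or H // tile < 1 or W // tile < 1:
        raise ValueError(f"tile grid {tile} too fine for image {image.shape}")
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:
        return image.copy()
    kernel = (max(1, H // tile), max(1, W // tile))
    out = exposure.equalize_adapthist(np.clip(image, 0.0, 1.0),
                                      kernel_size=kernel,
                                      clip_limit=clip_limit / 100.0)
    return out.astype(np.float64)


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise power curve ``image ** gamma`` on a [0,1] image."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.clip(image, 0.0, 1.0) ** gamma


def preprocess_image(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full pipeline: gray -> CLAHE -> gamma; returns H x W float in [0,1]."""
    config = config or PreprocessConfig()
    g = to_gray(image, config.gray_mode)
    g = clahe(g, config.clahe_clip_limit, config.clahe_tile)
    return gamma_correct(g, config.gamma)


def _erase(image: np.ndarray, rng: np.random.Generator, area: tuple) -> np.ndarray:
    H, W = image.shape
    frac = rng.uniform(*area)
    aspect = rng.uniform(0.5, 2.0)
    h = max(1, int(round(np.sqrt(frac * H * W * aspect))))
    w = max(1, int(round(np.sqrt(frac * H * W / aspect))))
    h, w = min(h, H), min(w, W)
    r = int(rng.integers(0, H - h + 1))
    c = int(rng.integers(0, W - w + 1))
    out = image.copy()
    out[r:r + h, c:c + w] = image.mean()
    return out


def augment(image: np.ndarray, vessel_gt: np.ndarray | None, fov: np.ndarray | None,
            config: PreprocessConfig, rng: np.random.Generator):
    """Apply the configured random augmentations.

    The same geometric transform (flips, rotation) is applied to image,
    ground truth and FOV; random erase sets a rectangle of the image to its
    mean intensity and never touches the masks.  Deterministic for a given
    generator state.
    """
    arrays = [image, vessel_gt, fov]
    for a in arrays[1:]:
        if a is not None and a.shape != image.shape:
            raise ValueError("augment inputs must share a shape")

    def geo(f):
        return [f(a) if a is not None else None for a in arrays]

    if config.flip_ud and rng.random() < 0.5:
        arrays = geo(lambda a: a[::-1].copy())
    if config.flip_lr and rng.random() < 0.5:
        arrays = geo(lambda a: a[:, ::-1].copy())
    if config.rotate and rng.random() < 0.5:
        if config.rotate_any_angle:
            angle = float(rng.uniform(0.0, 360.0))
            arrays = [ndimage.rotate(arrays[0], angle, reshape=False, order=1, mode="reflect"),
                      *(ndimage.rotate(a, angle, reshape=False, order=0, mode="constant")
                        if a is not None else None for a in arrays[1:])]
        else:
            k = int(rng.integers(1, 4))
            arrays = geo(lambda a: np.rot90(a, k).copy())
    if config.erase:
        if rng.random() < 0.5:
            arrays[0] = _erase(arrays[0], rng, config.erase_area)
    return tuple(arrays)
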