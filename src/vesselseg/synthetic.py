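"""Synthetic fundus-like images with exact vessel ground truth.

The generator emulates the two properties of fundus photographs that drive
the segmentation design: dark curvilinear branching vessels of tapering
width on a brighter textured background (green-channel polarity), and a
circular field of view on a dark surround.  Trees grow from points near
the disc margin as jittered random walks that fork recursively; the ground
truth is by construction exactly the set of pixels painted by the
width-tapering centerline, so image and annotation can never disagree.

It does not attempt photorealism: there is no optic disc, no lesions and
no illumination gradient, so results on this data bound plumbing and
learning behaviour, not clinical performance.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import ndimage

from .imaging_io import ImageRecord, save_mask

__all__ = ["SyntheticVesselSpec", "generate", "edge_from_gt",
           "suite_records", "make_fixture_suite", "load_suite"]


@dataclass(frozen=True)
class SyntheticVesselSpec:
    image_size: tuple = (192, 192)
    n_trees: int = 6
    branch_depth: int = 3
    root_width: float = 3.0
    width_decay: float = 0.72
    tortuosity: float = 0.18          # std of per-step heading jitter, radians
    vessel_contrast: float = 0.45     # intensity drop on vessel pixels
    background_noise_sigma: float = 0.04
    background_mean: float = 0.55
    blur_sigma: float = 1.0
    fov_radius_fraction: float = 0.94
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.vessel_contrast <= 1.0):
            raise ValueError("vessel_contrast must lie in (0, 1]")
        if not (0.0 < self.fov_radius_fraction <= 1.0):
            raise ValueError("fov_radius_fraction must lie in (0, 1]")
        if self.n_trees < 1 or self.branch_depth < 1:
            raise ValueError("need at least one tree and branch depth >= 1")


def edge_from_gt(vessel_gt: np.ndarray) -> np.ndarray:
    """Morphological gradient (3x3 dilation minus erosion) of a binary mask."""
    st = np.ones((3, 3), dtype=bool)
    dil = ndimage.binary_dilation(vessel_gt.astype(bool), structure=st)
    ero = ndimage.binary_erosion(vessel_gt.astype(bool), structure=st)
    return (dil & ~ero).astype(np.uint8)


def _paint_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    H, W = mask.shape
    rad = max(0.5, radius)
    r0, r1 = max(0, int(r - rad - 1)), min(H, int(r + rad + 2))
    c0, c1 = max(0, int(c - rad - 1)), min(W, int(c + rad + 2))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy - r) ** 2 + (xx - c) ** 2 <= rad * rad


def _grow_branch(mask, pos, heading, width, depth, spec, rng, center, fov_radius):
    """Random-walk one branch, then fork into two children."""
    H, W = mask.shape
    step = 1.5
    n_steps = int(rng.integers(18, 34))
    r, c = pos
    for _ in range(n_steps):
        heading += rng.normal(0.0, spec.tortuosity)
        r += step * np.sin(heading)
        c += step * np.cos(heading)
        if (r - center[0]) ** 2 + (c - center[1]) ** 2 > (fov_radius - width) ** 2:
            return
        _paint_disk(mask, r, c, width / 2.0)
    if depth > 1 and width * spec.width_decay >= 0.5:
        split = rng.uniform(0.35, 0.75)
        for sign in (-1.0, 1.0):
            _grow_branch(mask, (r, c), heading + sign * split,
                         width * spec.width_decay, depth - 1, spec, rng,
                         center, fov_radius)


def generate(spec: SyntheticVesselSpec) -> ImageRecord:
    """Generate one synthetic record; fully determined by ``spec.seed``.

    Returns an :class:`ImageRecord` whose ``image`` is H x W x 3 uint8,
    with ``vessel_gt``, ``fov`` and ``edge_gt`` filled in.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    center = ((H - 1) / 2.0, (W - 1) / 2.0)
    fov_radius = spec.fov_radius_fraction * min(H, W) / 2.0

    yy, xx = np.ogrid[:H, :W]
    fov = (((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= fov_radius ** 2).astype(np.uint8)

    gt = np.zeros((H, W), dtype=bool)
    for _ in range(spec.n_trees):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rr = 0.75 * fov_radius
        pos = (center[0] + rr * np.sin(theta), center[1] + rr * np.cos(theta))
        heading = theta + np.pi + rng.normal(0.0, 0.5)  # roughly inward
        _grow_branch(gt, pos, heading, spec.root_width, spec.branch_depth,
                     spec, rng, center, fov_radius)
    gt &= fov.astype(bool)
    if not gt.any():
        raise ValueError("spec produced zero vessel pixels")

    bg = spec.background_mean + rng.normal(0.0, spec.background_noise_sigma, (H, W))
    img = np.clip(bg - spec.vessel_contrast * gt, 0.0, 1.0)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    img = np.clip(img, 0.0, 1.0) * fov
    rgb = np.round(np.stack([img] * 3, axis=-1) * 255).astype(np.uint8)

    return ImageRecord(image=rgb, vessel_gt=gt.astype(np.uint8), fov=fov,
                       id=f"synth-{spec.seed}", edge_gt=edge_from_gt(gt))


def _suite_specs(base: SyntheticVesselSpec, n_train: int, n_test: int):
    """Per-image specs: a fine-vessel subset (thin roots) is always included."""
    out = []
    for i in range(n_train + n_test):
        split = "train" if i < n_train else "test"
        spec = replace(base, seed=base.seed + i)
        if split == "train" and i % 3 == 2:
            spec = replace(spec, root_width=1.8, n_trees=base.n_trees + 2)
        out.append((f"{split}_{i:02d}", split, spec))
    return out


def suite_records(n_train: int = 12, n_test: int = 4,
                  base_spec: SyntheticVesselSpec | None = None):
    """The fixture suite as in-memory records (no files): (train, test)."""
    base = base_spec or SyntheticVesselSpec()
    train, test = [], []
    for name, split, spec in _suite_specs(base, n_train, n_test):
        rec = generate(spec)
        rec.id = name
        (train if split == "train" else test).append(rec)
    return train, test


def make_fixture_suite(out_dir: str, n_train: int = 12, n_test: int = 4,
                       base_spec: SyntheticVesselSpec | None = None) -> dict:
    """Write a miniature DRIVE-style dataset and a JSON manifest.

    Layout: ``images/{id}.png``, ``gt/{id}_gt.png``, ``fov/{id}_fov.png``
    under ``out_dir``, plus ``manifest.json`` recording every per-image
    spec so the suite can be regenerated bit-identically.
    """
    base = base_spec or SyntheticVesselSpec()
    for sub in ("images", "gt", "fov"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    manifest = {"n_train": n_train, "n_test": n_test, "images": []}
    import imageio.v3 as iio
    for name, split, spec in _suite_specs(base, n_train, n_test):
        rec = generate(spec)
        img_path = os.path.join(out_dir, "images", f"{name}.png")
        iio.imwrite(img_path, rec.image)
        save_mask(os.path.join(out_dir, "gt", f"{name}_gt.png"), rec.vessel_gt)
        save_mask(os.path.join(out_dir, "fov", f"{name}_fov.png"), rec.fov)
        digest = hashlib.sha256(rec.image.tobytes() + rec.vessel_gt.tobytes()).hexdigest()[:16]
        manifest["images"].append({"id": name, "split": split,
                                   "spec": asdict(spec), "sha256_16": digest})
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_suite(out_dir: str) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Regenerate the suite's records from its manifest (no image decoding)."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    train, test = [], []
    for entry in manifest["images"]:
        spec_d = dict(entry["spec"])
        spec_d["image_size"] = tuple(spec_d["image_size"])
        rec = generate(SyntheticVesselSpec(**spec_d))
        rec.id = entry["id"]
        (train if entry["split"] == "train" else test).append(rec)
    return train, test
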