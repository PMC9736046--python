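"""Reading and writing fundus images, vessel annotations and FOV masks.

Supports the per-image file layout used by the public retinal datasets
(DRIVE/STARE style): an RGB photograph, a binary vessel annotation and a
binary field-of-view mask per image, as PNG/TIFF/GIF/PPM files.  Masks are
binarized at the 8-bit midpoint (127) on read since the public annotations
are near-binary and the midpoint is robust to anti-aliasing.  When no FOV
mask file exists, :func:`estimate_fov` provides an intensity-threshold
estimate (largest bright connected component, morphologically closed).
"""

from __future__ import annotations

import glob
import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = ["ImageRecord", "load_record", "save_mask", "save_probability_map",
           "estimate_fov", "discover_dataset"]

MASK_THRESHOLD = 127


@dataclass
class ImageRecord:
    """One fundus image with its vessel ground truth and FOV mask.

    ``image`` is H x W x 3 uint8 on read; preprocessing replaces it with an
    H x W float array in [0, 1].  ``vessel_gt`` may be None at inference.
    All arrays share the same height/width; masks hold only {0, 1}.
    """

    image: np.ndarray
    fov: np.ndarray
    vessel_gt: np.ndarray | None = None
    id: str = ""
    edge_gt: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        hw = self.image.shape[:2]
        for name in ("vessel_gt", "fov", "edge_gt"):
            m = getattr(self, name)
            if m is None:
                continue
            if m.shape != hw:
                raise ValueError(f"{name} shape {m.shape} does not match image {hw}")
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} is not binary (values {vals[:5]}...)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def _read_image(path: str) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    return np.asarray(arr)


def _read_mask(path: str, expect_shape: tuple[int, int]) -> np.ndarray:
    arr = _read_image(path)
    if arr.ndim == 3:  # some annotations ship as RGB(A); any channel carries the bit
        arr = arr[..., 0]
    if arr.shape != expect_shape:
        raise ValueError(f"mask {path!r} shape {arr.shape} does not match image {expect_shape}")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    if arr.max(initial=0) <= 1:
        return (arr > 0).astype(np.uint8)
    return (arr > MASK_THRESHOLD).astype(np.uint8)


def load_record(image_path: str, gt_path: str | None = None,
                fov_path: str | None = None, id: str | None = None) -> ImageRecord:
    """Load one image with optional ground truth and FOV mask files.

    Grayscale photographs are replicated to three channels; a missing FOV
    file falls back to :func:`estimate_fov`.
    """
    img = _read_image(image_path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    elif img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"image {image_path!r} has unsupported shape {img.shape}")
    if img.dtype != np.uint8:
        img = np.clip(img.astype(np.float64) / max(1.0, float(img.max())) * 255.0, 0, 255).astype(np.uint8)
    hw = img.shape[:2]
    gt = _read_mask(gt_path, hw) if gt_path else None
    fov = _read_mask(fov_path, hw) if fov_path else estimate_fov(img)
    rec_id = id if id is not None else os.path.splitext(os.path.basename(image_path))[0]
    return ImageRecord(image=img, vessel_gt=gt, fov=fov, id=rec_id)


def estimate_fov(image: np.ndarray, threshold_fraction: float = 0.1,
                 closing_radius: int = 5, channel: str = "red") -> np.ndarray:
    """Estimate the circular field of view from image intensities.

    Thresholds the red channel (or luminance) at ``threshold_fraction`` of
    its maximum, keeps the largest connected component and closes small
    holes on its boundary.  This is plumbing for datasets that ship no FOV
    file; the estimate only gates which pixels enter evaluation.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        plane = img[:, :, 0] if channel == "red" else img.mean(axis=2)
    else:
        plane = img
    peak = plane.max()
    if peak <= 0:
        warnings.warn("estimate_fov: all-dark image, returning empty mask")
        return np.zeros(plane.shape, dtype=np.uint8)
    mask = plane > threshold_fraction * peak
    if not mask.any():
        warnings.warn("estimate_fov: no pixel above threshold, returning empty mask")
        return np.zeros(plane.shape, dtype=np.uint8)
    labels = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    # closing can merge nearby specks; keep a single component
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
    return mask.astype(np.uint8)


def save_mask(path: str, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit image (0/255)."""
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def save_probability_map(path: str, prob: np.ndarray) -> None:
    """Write a [0,1] probability map as a 16-bit PNG."""
    arr = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 65535).astype(np.uint16))


def discover_dataset(image_glob: str, gt_template: str | None = None,
                     fov_template: str | None = None) -> list[ImageRecord]:
    """Load every image matching ``image_glob``.

    ``gt_template``/``fov_template`` are format strings receiving the image
    basename stem, e.g. ``"gt/{stem}_gt.png"``; a template whose file is
    missing raises, except the FOV template which falls back to estimation.
    """
    paths = sorted(glob.glob(image_glob))
    if not paths:
        raise FileNotFoundError(f"no images match {image_glob!r}")
    records = []
    for p in paths:
        stem = os.path.splitext(os.path.basename(p))[0]
        gt_path = gt_template.format(stem=stem) if gt_template else None
        fov_path = fov_template.format(stem=stem) if fov_template else None
        if gt_path and not os.path.exists(gt_path):
            raise FileNotFoundError(f"ground truth {gt_path!r} missing for {p!r}")
        if fov_path and not os.path.exists(fov_path):
            fov_path = None
        records.append(load_record(p, gt_path, fov_path, id=stem))
    return records
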