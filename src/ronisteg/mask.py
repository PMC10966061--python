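"""Significant/insignificant masks: the deterministic segmenter stand-in,
an adapter for externally computed masks, and the IoU / NCC comparisons.

A mask labels diagnostically relevant pixels 1 and background 0; embedding
only ever touches 0-labelled pixels. The built-in provider is an intensity
threshold followed by morphological cleanup. The cleanup is what makes the
provider *stable*: re-running it on a stego image must reproduce the cover's
mask exactly, otherwise the extractor's tile plan drifts. Closing fills pin
holes inside organs; the subsequent opening deletes every structure thinner
than ~2*opening_radius px - which includes any embedded 4x4 tile, no matter
how strongly the quantizer brightened it - and the component-size filter
drops residues of rare tile clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import opening as _opening

from .errors import AlignmentError, DegenerateRangeError
from .image_io import MedicalImage

__all__ = [
    "BinaryMask",
    "threshold_mask",
    "external_mask_adapter",
    "compute_iou",
    "compute_ncc",
    "DEFAULT_REL_THRESHOLD",
    "DEFAULT_CLOSING_RADIUS",
    "DEFAULT_OPENING_RADIUS",
    "DEFAULT_MIN_COMPONENT_PX",
    "DEFAULT_SCALE_PERCENTILE",
]

DEFAULT_REL_THRESHOLD = 0.05
DEFAULT_CLOSING_RADIUS = 5
DEFAULT_OPENING_RADIUS = 3
DEFAULT_MIN_COMPONENT_PX = 128
DEFAULT_SCALE_PERCENTILE = 90.0


@dataclass
class BinaryMask:
    """Per-pixel labels: 1 = significant (object), 0 = insignificant."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.labels = np.ascontiguousarray(arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def significant_fraction(self) -> float:
        return float(self.labels.mean())


def threshold_mask(
    img: MedicalImage,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
    scale_percentile: float = DEFAULT_SCALE_PERCENTILE,
) -> BinaryMask:
    """Deterministic mask provider (stand-in for a trained segmenter).

    Pixels whose scaled intensity exceeds ``rel_threshold`` are candidate
    foreground; closing (radius ``closing_radius``) fills holes, opening
    (radius ``opening_radius``) removes thin/bright clutter such as
    embedding perturbation, and components below ``min_component_px``
    pixels are dropped. An all-background image yields an all-zero mask.

    The intensity scale is ``(v - min) / (P - min)`` with P the
    ``scale_percentile``-th percentile of the pixel values (falling back to
    the maximum when the percentile collapses onto the minimum). A
    percentile is used instead of the maximum because the scale must be a
    property of the anatomy, not of a handful of extreme pixels: embedding
    or salt noise can raise the maximum without changing the objects, and a
    provider whose labels moved in response would hand the extractor a
    different tile plan than the embedder used.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    pix = img.pixels.astype(np.float64)
    lo = float(pix.min())
    ref = float(np.percentile(pix, scale_percentile))
    if ref <= lo:
        ref = float(pix.max())
    if ref <= lo:
        # a constant frame has no objects
        return BinaryMask(np.zeros(img.shape, dtype=np.uint8))
    fg = (pix - lo) / (ref - lo) > rel_threshold
    if closing_radius > 0:
        fg = _closing(fg, disk(closing_radius))
    if opening_radius > 0:
        fg = _opening(fg, disk(opening_radius))
    if min_component_px > 0:
        labeled, n = ndimage.label(fg)
        if n:
            sizes = np.bincount(labeled.ravel())
            keep = sizes >= min_component_px
            keep[0] = False
            fg = keep[labeled]
    return BinaryMask(fg.astype(np.uint8))


def external_mask_adapter(mask_image: str | Path, shape: tuple[int, int]) -> BinaryMask:
    """Load a mask produced by an external segmenter (e.g. a trained model).

    Any grayscale image of the given shape is accepted; nonzero pixels map
    to 1. This is the slot where a real Mask-RCNN-style prediction enters
    the pipeline in place of :func:`threshold_mask`.
    """
    from PIL import Image as PILImage

    arr = np.asarray(PILImage.open(mask_image).convert("I"))
    if arr.shape != tuple(shape):
        raise AlignmentError(f"mask shape {arr.shape} does not match image shape {tuple(shape)}")
    return BinaryMask((arr != 0).astype(np.uint8))


def compute_iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union of two masks, in [0, 1].

    Two empty masks agree that nothing is significant, so their IoU is
    defined as 1.
    """
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    aa = a.labels.astype(bool)
    bb = b.labels.astype(bool)
    union = np.count_nonzero(aa | bb)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(aa & bb) / union)


def compute_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson-style normalized cross-correlation over all pixels.

    ``NCC = sum((A-mu_A)(B-mu_B)) / (sqrt(sum (A-mu_A)^2) sqrt(sum (B-mu_B)^2))``,
    in [-1, 1]; 1 means the arrays agree up to a positive affine rescale.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise AlignmentError(f"array shapes differ: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(np.sum(da * da))
    nb = np.sqrt(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        raise DegenerateRangeError("NCC is undefined for a constant array")
    return float(np.sum(da * db) / (na * nb))
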