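"""Tissue segmentation by global intensity thresholding.

The per-tissue intensity laws are separable by construction, so segmentation
is a fixed partition of the 8-bit range: background below 30, fat in
[30, 120), glandular in [120, 226), and high intensities in [226, 255].
High-intensity pixels are disambiguated by position: peripheral (within a
thin band of the breast boundary) pixels are skin, central ones ligament.
Range endpoints are half-open, so 120 is glandular and 226 is skin/ligament.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .phantom import BACKGROUND, FAT, GLANDULAR, SKIN, LIGAMENT


@dataclasses.dataclass(frozen=True)
class SegmentationThresholds:
    """Half-open intensity partition of [0, 255] plus the skin-band width."""

    background_max: int = 30   # exclusive upper bound of background
    fat_max: int = 120         # fat: [background_max, fat_max)
    glandular_max: int = 226   # glandular: [fat_max, glandular_max)
    skin_band_width: int = 4   # px from the breast boundary counted as skin

    def __post_init__(self) -> None:
        if not (0 < self.background_max < self.fat_max < self.glandular_max <= 255):
            raise ValueError("thresholds must be increasing within [0, 255]")
        if self.skin_band_width < 1:
            raise ValueError("skin_band_width must be >= 1")


class NoBreastRegionError(ValueError):
    """Raised when an image contains no foreground after thresholding."""


def segment(image: np.ndarray,
            thresholds: SegmentationThresholds | None = None,
            require_foreground: bool = False) -> np.ndarray:
    """Label every pixel of an 8-bit grayscale image with a tissue code.

    The breast region is the largest connected component of above-background
    pixels; smaller specks are relabeled background.  Returns an (H, W)
    uint8 map with the 0..4 coding of :mod:`phantombench.phantom`.

    Everything below the background threshold is allocated background, so an
    image with no above-threshold pixel yields an all-background map (with a
    warning); pass ``require_foreground=True`` to make that an explicit
    :class:`NoBreastRegionError` instead.
    """
    t = thresholds or SegmentationThresholds()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.dtype != np.uint8:
        if img.max(initial=0) > 255 or img.min(initial=0) < 0:
            raise ValueError("expected 8-bit intensities in [0, 255]")
        img = img.astype(np.uint8)

    fg = img >= t.background_max
    if not fg.any():
        msg = "no breast region: all pixels below background threshold"
        if require_foreground:
            raise NoBreastRegionError(msg)
        warnings.warn(msg)
        return np.zeros(img.shape, dtype=np.uint8)
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))

    out = np.zeros(img.shape, dtype=np.uint8)
    out[fg & (img < t.fat_max)] = FAT
    out[fg & (img >= t.fat_max) & (img < t.glandular_max)] = GLANDULAR

    high = fg & (img >= t.glandular_max)
    if high.any():
        dist = ndimage.distance_transform_edt(fg)
        peripheral = dist <= t.skin_band_width
        out[high & peripheral] = SKIN
        out[high & ~peripheral] = LIGAMENT
    return out


def fg_boundary_mask(label_map: np.ndarray, dilation_radius: int = 2) -> np.ndarray:
    """Binary mask of the fat-glandular tissue interface, dilated.

    A pixel belongs to the raw interface when it is glandular with an
    8-adjacent fat neighbor or vice versa (morphological gradient restricted
    to the two tissues); the mask is then dilated by ``dilation_radius`` so
    that small positional jitter does not destroy mask overlap.
    """
    lm = np.asarray(label_map)
    g = lm == GLANDULAR
    f = lm == FAT
    if not g.any() or not f.any():
        return np.zeros(lm.shape, dtype=bool)
    st = ndimage.generate_binary_structure(2, 2)  # 8-connectivity
    boundary = (g & ndimage.binary_dilation(f, st)) | (f & ndimage.binary_dilation(g, st))
    if dilation_radius > 0:
        boundary = ndimage.binary_dilation(boundary, st, iterations=dilation_radius)
    return boundary


def breast_mask(label_map: np.ndarray) -> np.ndarray:
    """Foreground (any tissue) mask of a segmented map."""
    return np.asarray(label_map) > BACKGROUND
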