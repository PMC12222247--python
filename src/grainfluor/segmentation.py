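"""Regions of interest: whole grain section and grain outer tissues.

The whole-section ROI comes from a fixed low threshold on the 8-bit
sum-of-intensity image followed by square-element opening and closing.
The outer-tissue ROI merges two Otsu thresholds — one on the full
11-channel sum, one on a UV-dominated sum avoiding red emission — and
is cleaned with disk-element morphology before keeping the largest
region.  All structuring-element sizes are expressed at full mosaic
resolution (3500 px wide) and scaled to the working grid.

A "size" is the side length of a square element and the radius of a
disk element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .assembly import MultispectralImage
from .channels import UV_SUM_CHANNELS

#: Grid width of the full-resolution stitched mosaic the default
#: element sizes refer to.
REFERENCE_WIDTH = 3500

# Default sizes at full resolution.
SECTION_THRESHOLD = 2
SECTION_OPEN_SIZE = 51
SECTION_CLOSE_SIZE = 150
OUTER_OPEN1_SIZE = 1
OUTER_DILATE_SIZE = 8
OUTER_OPEN2_SIZE = 12


class DegenerateInputError(ValueError):
    """Raised when a threshold is undefined (e.g. constant image)."""


@dataclass
class RoiMask:
    """Binary pixel set naming which pixels enter fitting/quantification."""

    mask: np.ndarray
    kind: str                     # "whole_section" | "outer_tissues"
    params_used: dict

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def scaled_size(size: float, grid_width: int,
                reference_width: int = REFERENCE_WIDTH) -> int:
    """Structuring-element size rescaled to the working grid (>= 1)."""
    return max(1, int(round(size * grid_width / reference_width)))


def _largest_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    labels = measure.label(mask, connectivity=connectivity)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def segment_section(
    sum8: np.ndarray,
    threshold: int = SECTION_THRESHOLD,
    open_size: int | None = None,
    close_size: int | None = None,
    keep_largest: bool = True,
) -> RoiMask:
    """Segment the whole grain section from the 8-bit sum image.

    A common gray-level threshold (default 2) is followed by opening
    and closing with square elements (defaults 51 and 150 at full
    resolution, scaled to the grid).  The threshold can be overridden
    per image where the common value is inappropriate.
    """
    sum8 = np.asarray(sum8)
    if sum8.dtype != np.uint8:
        raise ValueError("sum image must be 8-bit")
    W = sum8.shape[1]
    open_size = open_size or scaled_size(SECTION_OPEN_SIZE, W)
    close_size = close_size or scaled_size(SECTION_CLOSE_SIZE, W)
    if open_size < 1 or close_size < 1:
        raise ValueError("structuring-element sizes must be >= 1")

    mask = sum8 > threshold
    mask = morphology.opening(mask, morphology.footprint_rectangle(
        (open_size, open_size)))
    mask = morphology.closing(mask, morphology.footprint_rectangle(
        (close_size, close_size)))
    if keep_largest:
        mask = _largest_component(mask)
    return RoiMask(
        mask=mask,
        kind="whole_section",
        params_used={
            "threshold": int(threshold),
            "open_size": int(open_size),
            "close_size": int(close_size),
            "keep_largest": keep_largest,
        },
    )


def _rescale_to_8bit(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rescale a sum image to 8 bits over the masked pixels."""
    lo = values[mask].min()
    hi = values[mask].max()
    if hi <= lo:
        raise DegenerateInputError("image constant over the section mask")
    v8 = np.zeros(values.shape, dtype=np.uint8)
    v8[mask] = np.rint((values[mask] - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return v8


def segment_outer_tissues(
    image: MultispectralImage,
    section: RoiMask,
    t1_override: int | None = None,
    t2_override: int | None = None,
    open1_size: int | None = None,
    dilate_size: int | None = None,
    open2_size: int | None = None,
) -> RoiMask:
    """Segment the grain outer tissues within the whole-section ROI.

    Two Otsu thresholds are computed on 8-bit rescalings over the
    section pixels: T1 on the 11-channel intensity sum and T2 on the
    sum of U1b, U1g, U2b, U2g and BLg (avoiding red emission).  Pixels
    at or above either threshold form the raw region, which is cleaned
    by disk opening (size 1), dilation (size 8) and opening (size 12),
    all scaled to the grid, before the largest connected region is
    kept.  Thresholds (8-bit units) and sizes can be overridden,
    mirroring the manual checking step of the workflow.
    """
    if section.n_pixels == 0:
        raise ValueError("section mask is empty")
    W = image.shape[1]
    open1_size = open1_size or scaled_size(OUTER_OPEN1_SIZE, W)
    dilate_size = dilate_size or scaled_size(OUTER_DILATE_SIZE, W)
    open2_size = open2_size or scaled_size(OUTER_OPEN2_SIZE, W)

    smask = section.mask
    sum11_8 = _rescale_to_8bit(image.channel_sum(), smask)
    sumuv_8 = _rescale_to_8bit(image.channel_sum(UV_SUM_CHANNELS), smask)
    t1 = int(threshold_otsu(sum11_8[smask])) if t1_override is None \
        else int(t1_override)
    t2 = int(threshold_otsu(sumuv_8[smask])) if t2_override is None \
        else int(t2_override)

    raw = smask & ((sum11_8 >= t1) | (sumuv_8 >= t2))
    mask = morphology.opening(raw, morphology.disk(open1_size))
    mask = morphology.dilation(mask, morphology.disk(dilate_size))
    mask = morphology.opening(mask, morphology.disk(open2_size))
    mask = _largest_component(mask)
    return RoiMask(
        mask=mask,
        kind="outer_tissues",
        params_used={
            "t1": t1,
            "t2": t2,
            "t1_overridden": t1_override is not None,
            "t2_overridden": t2_override is not None,
            "open1_size": int(open1_size),
            "dilate_size": int(dilate_size),
            "open2_size": int(open2_size),
        },
    )


def section_area(mask: RoiMask | np.ndarray, pixel_size: float) -> float:
    """Section surface area in mm^2 from pixel count and pixel size (µm)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    return float(m.sum()) * pixel_size**2 * 1e-6


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard index of two binary masks (1.0 when both are empty)."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
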