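"""Assembly of the 11-channel cube and per-channel background correction.

The four RGB filter acquisitions are merged into a 12-channel cube in
canonical order, the reflection-contaminated U1 red plane is dropped,
and a channel-wise additive background — estimated from signal-free
rectangles — is subtracted.  Two renderings support inspection and
segmentation: the "sum of fluorescence intensity" gray image and the
gamma-corrected RGB composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    CHANNELS_11,
    CHANNELS_12,
    COMPOSITE_BLUE,
    COMPOSITE_GREEN,
    COMPOSITE_RED,
    FILTER_PLANES,
    FILTERS,
    REFLECTION_CHANNEL,
    VISIBLE_FILTERS,
    channel_indices,
)
from .synthetic import RawFilterImage


@dataclass
class MultispectralImage:
    """Pixel grid x 11 ordered fluorescence channels (counts >= 0)."""

    data: np.ndarray                       # float (H, W, 11)
    channels: tuple[str, ...] = CHANNELS_11
    pixel_size: float | None = None        # µm per pixel
    provenance: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channels):
            raise ValueError("data shape does not match the channel list")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channels.index(name)]

    def channel_sum(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        if names is None:
            return self.data.sum(axis=2)
        return self.data[..., channel_indices(names, self.channels)].sum(axis=2)


@dataclass
class BackgroundVector:
    """Per-channel additive offset estimated from signal-free regions."""

    values: np.ndarray
    n_regions_used: int
    channels: tuple[str, ...] = CHANNELS_11

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.channels),):
            raise ValueError("background length must match the channel list")
        if np.any(self.values < 0):
            raise ValueError("background offsets must be nonnegative")


def assemble_multispectral(
    acquisition: dict[str, RawFilterImage],
    visible_gain: float = 1.0,
    pixel_size: float | None = None,
    provenance: str | None = None,
    return_intermediate: bool = False,
):
    """Merge four RGB filter acquisitions into the 11-channel cube.

    The Blue and Green filter planes are multiplied by ``visible_gain``
    before merging (they are acquired dimmer than the UV ones); the
    intermediate cube carries all 12 planes in canonical order and the
    final cube drops U1r.
    """
    if visible_gain <= 0:
        raise ValueError("visible_gain must be positive")
    missing = [f for f in FILTERS if f not in acquisition]
    if missing:
        raise ValueError(f"missing filter acquisition(s): {missing}")
    shapes = {acquisition[f].rgb_planes.shape for f in FILTERS}
    if len(shapes) != 1:
        raise ValueError("filter acquisitions have mismatched shapes")

    H, W = acquisition[FILTERS[0]].rgb_planes.shape[1:]
    cube12 = np.empty((H, W, len(CHANNELS_12)), dtype=np.float64)
    for filt in FILTERS:
        gain = visible_gain if filt in VISIBLE_FILTERS else 1.0
        planes = acquisition[filt].rgb_planes.astype(np.float64) * gain
        for plane, chan in zip(planes, FILTER_PLANES[filt]):
            cube12[..., CHANNELS_12.index(chan)] = plane

    keep = [i for i, c in enumerate(CHANNELS_12) if c != REFLECTION_CHANNEL]
    image = MultispectralImage(
        data=cube12[..., keep],
        channels=CHANNELS_11,
        pixel_size=pixel_size,
        provenance=provenance,
    )
    if return_intermediate:
        return image, cube12
    return image


Region = tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


def estimate_background(
    images: list[MultispectralImage],
    regions: list[Region],
) -> BackgroundVector:
    """Mean intensity per channel over every region of every image.

    Mirrors the manual procedure of selecting a few signal-free
    rectangles on a handful of acquisitions: each region is read on
    each supplied image and the per-channel average over all of them is
    the background estimate.
    """
    if not images:
        raise ValueError("at least one image is required")
    if not regions:
        raise ValueError("at least one region is required")
    total = np.zeros(len(CHANNELS_11))
    count = 0
    for img in images:
        H, W = img.shape
        for (r0, r1, c0, c1) in regions:
            if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
                raise ValueError(f"region {(r0, r1, c0, c1)} outside grid")
            patch = img.data[r0:r1, c0:c1, :]
            total += patch.sum(axis=(0, 1))
            count += patch.shape[0] * patch.shape[1]
    return BackgroundVector(
        values=total / count,
        n_regions_used=len(images) * len(regions),
    )


def subtract_background(
    image: MultispectralImage, bg: BackgroundVector
) -> MultispectralImage:
    """Subtract the per-channel offset, clamping at zero.

    Fluorescence counts are nonnegative; downstream sums and Otsu
    thresholds assume it, so negative residuals are clipped.
    """
    if bg.channels != image.channels:
        raise ValueError("channel lists of image and background differ")
    return MultispectralImage(
        data=np.clip(image.data - bg.values, 0.0, None),
        channels=image.channels,
        pixel_size=image.pixel_size,
        provenance=image.provenance,
    )


def sum_intensity_image(image: MultispectralImage) -> np.ndarray:
    """Per-pixel sum over the 11 channels, rescaled to 8 bits.

    The [0, max] range of the sum is mapped linearly onto [0, 255] and
    rounded; an all-zero image stays all zero.
    """
    if image.data.size == 0:
        raise ValueError("empty image")
    total = image.channel_sum()
    peak = total.max()
    if peak <= 0:
        return np.zeros(total.shape, dtype=np.uint8)
    return np.rint(total / peak * 255.0).astype(np.uint8)


def composite_rgb(
    image: MultispectralImage,
    min_val: float = 0.0,
    max_val: float = 11000.0,
    gamma: float = 0.5,
) -> np.ndarray:
    """RGB composite of the cube for visual comparison.

    R averages the red-emission channels (U2r, BLr, GRr), G the green
    ones (U1g, U2g, BLg) and B the UV blue ones (U1b, U2b); baseline
    channels carry no signal and are left out.  Each plane is clipped
    to the common [min_val, max_val] window, normalized, raised to
    ``gamma`` (default 0.5, enhancing low intensities) and scaled to
    8 bits.
    """
    if max_val <= min_val:
        raise ValueError("max_val must exceed min_val")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    planes = []
    for names in (COMPOSITE_RED, COMPOSITE_GREEN, COMPOSITE_BLUE):
        mean = image.channel_sum(names) / len(names)
        norm = (np.clip(mean, min_val, max_val) - min_val) / (max_val - min_val)
        planes.append(np.rint(norm**gamma * 255.0).astype(np.uint8))
    return np.stack(planes, axis=-1)
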