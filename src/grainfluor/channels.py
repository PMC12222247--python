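"""Canonical channel layout of the multispectral fluorescence cube.

One acquisition consists of four RGB images taken through four
excitation/emission filter cubes: two UV excitations (U1, U2) and two
visible excitations (Blue, BL; Green, GR).  Merging the red, green and
blue planes of the four acquisitions gives a 12-channel cube ordered
from high to low wavelength within each filter block.  The U1 red plane
is contaminated by the excitation Rayleigh band reflection and is
dropped, leaving the 11 working channels.

The per-pixel vector over the 11 channels is called a *pseudo-spectrum*.
No photon can be emitted below the excitation wavelength, so BLb, GRb
and GRg carry no signal; they are kept in the pseudo-spectrum as a
baseline.
"""

from __future__ import annotations

FILTERS: tuple[str, ...] = ("U1", "U2", "BL", "GR")

#: All 12 planes in canonical cube order (blue, green, red per filter).
CHANNELS_12: tuple[str, ...] = (
    "U1b", "U1g", "U1r",
    "U2b", "U2g", "U2r",
    "BLb", "BLg", "BLr",
    "GRb", "GRg", "GRr",
)

#: Channel removed because of excitation-band reflection.
REFLECTION_CHANNEL = "U1r"

#: The 11 working channels of the final cube.
CHANNELS_11: tuple[str, ...] = tuple(
    c for c in CHANNELS_12 if c != REFLECTION_CHANNEL
)

#: Channels below their excitation wavelength: baseline, no signal.
BASELINE_CHANNELS: tuple[str, ...] = ("BLb", "GRb", "GRg")

#: Red-emission channels (chlorophyll signature).
RED_EMISSION_CHANNELS: tuple[str, ...] = ("U2r", "BLr", "GRr")

#: Channels entering the second (red-avoiding) outer-tissue threshold.
UV_SUM_CHANNELS: tuple[str, ...] = ("U1b", "U1g", "U2b", "U2g", "BLg")

#: Composite rendering: plane -> contributing channels (U1r excluded).
COMPOSITE_RED: tuple[str, ...] = ("U2r", "BLr", "GRr")
COMPOSITE_GREEN: tuple[str, ...] = ("U1g", "U2g", "BLg")
COMPOSITE_BLUE: tuple[str, ...] = ("U1b", "U2b")

#: RGB plane names of each raw filter image, in (R, G, B) page order.
FILTER_PLANES: dict[str, tuple[str, str, str]] = {
    "U1": ("U1r", "U1g", "U1b"),
    "U2": ("U2r", "U2g", "U2b"),
    "BL": ("BLr", "BLg", "BLb"),
    "GR": ("GRr", "GRg", "GRb"),
}

#: Filters whose planes are rescaled by the visible gain before merging.
VISIBLE_FILTERS: tuple[str, ...] = ("BL", "GR")

#: 14-bit camera: largest representable count.
MAX_COUNT: int = 2**14 - 1

N_GRAY_LEVELS: int = MAX_COUNT + 1


def channel_index(name: str, channels: tuple[str, ...] = CHANNELS_11) -> int:
    """Index of a channel name within a channel tuple."""
    try:
        return channels.index(name)
    except ValueError as exc:  # pragma: no cover - defensive
        raise KeyError(f"unknown channel {name!r}") from exc


def channel_indices(
    names: tuple[str, ...], channels: tuple[str, ...] = CHANNELS_11
) -> list[int]:
    return [channel_index(n, channels) for n in names]
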