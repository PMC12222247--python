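"""Reading and writing of the pipeline's on-disk artefacts.

Raw filter acquisitions are 3-page 16-bit TIFFs (R, G, B planes), the
assembled cube an 11-page 32-bit float TIFF with a JSON sidecar naming
the channels, masks 8-bit 0/255 TIFFs with a JSON of the parameters
used, and composites 8-bit PNGs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile

from .channels import CHANNELS_11


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_json(path: str | Path, obj: Any) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


# -- raw filter acquisitions -------------------------------------------------

def write_raw_filter(path: str | Path, rgb_planes: np.ndarray) -> None:
    """Write the three 14-bit planes of one filter acquisition."""
    planes = np.asarray(rgb_planes)
    if planes.ndim != 3 or planes.shape[0] != 3:
        raise ValueError("rgb_planes must have shape (3, H, W)")
    tifffile.imwrite(path, planes.astype(np.uint16), photometric="minisblack")


def read_raw_filter(path: str | Path) -> np.ndarray:
    planes = tifffile.imread(path)
    if planes.ndim != 3 or planes.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-page (R,G,B) TIFF")
    return planes


# -- multispectral cubes -----------------------------------------------------

def write_multispectral(
    path: str | Path,
    data: np.ndarray,
    channels: tuple[str, ...] = CHANNELS_11,
    pixel_size: float | None = None,
    provenance: str | None = None,
) -> None:
    """Write a (H, W, C) cube as a C-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    cube = np.asarray(data, dtype=np.float32)
    if cube.ndim != 3 or cube.shape[2] != len(channels):
        raise ValueError("cube shape does not match the channel list")
    stack = np.moveaxis(cube, 2, 0)
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        description=json.dumps({"channels": list(channels)}),
    )
    write_json(_sidecar(path), {
        "channels": list(channels),
        "pixel_size_um": pixel_size,
        "provenance": provenance,
    })


def read_multispectral(path: str | Path):
    """Read a cube written by :func:`write_multispectral`.

    Returns ``(data, channels, meta)`` with ``data`` of shape (H, W, C).
    """
    path = Path(path)
    stack = tifffile.imread(path)
    meta = read_json(_sidecar(path))
    channels = tuple(meta["channels"])
    if stack.shape[0] != len(channels):
        raise ValueError(f"{path}: page count does not match sidecar channels")
    return np.moveaxis(stack, 0, 2), channels, meta


# -- label maps and masks ----------------------------------------------------

def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8),
                     photometric="minisblack")


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(path: str | Path, mask: np.ndarray,
               params: dict | None = None) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)),
                     photometric="minisblack")
    if params is not None:
        write_json(_sidecar(Path(path)), params)


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0


# -- 8-bit renderings ---------------------------------------------------------

def write_png(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))
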