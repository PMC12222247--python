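"""PCA of a series of large multispectral images ("large PCA").

The series is never loaded at once.  Each image is unfolded to a pixel
x channel table X_i restricted to its ROI, and three local statistics
are accumulated: the pixel count, the sum of pseudo-spectra (local
contribution to the global mean) and the cross-product matrix X_i'X_i
(local contribution to the global variance-covariance matrix).  The
merged statistics give the global mean m and covariance

    C = (sum_i X_i'X_i - N m m') / (N - 1),

whose eigendecomposition yields eigenvalues and loadings common to the
whole series.  Scores are computed per image as (x - m) L and refolded
onto the pixel grid; 8-bit renderings share per-component bounds
derived from the eigenvalues so score images are comparable across the
series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .assembly import MultispectralImage
from .channels import CHANNELS_11
from .segmentation import RoiMask


@dataclass
class AccumulatedStats:
    """Streaming sufficient statistics of the pixel population."""

    n_pixels: int
    sum_vector: np.ndarray          # (C,)
    crossprod: np.ndarray           # (C, C), symmetric PSD
    n_images: int
    channels: tuple[str, ...] = CHANNELS_11

    @classmethod
    def empty(cls, channels: tuple[str, ...] = CHANNELS_11):
        c = len(channels)
        return cls(0, np.zeros(c), np.zeros((c, c)), 0, channels)

    @classmethod
    def from_image(cls, image: MultispectralImage, mask: RoiMask | np.ndarray):
        m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
        if m.shape != image.shape:
            raise ValueError("mask and image grids differ")
        X = image.data[m]            # (n, C) float64
        if X.shape[0] == 0:
            raise ValueError("mask selects no pixels")
        return cls(
            n_pixels=X.shape[0],
            sum_vector=X.sum(axis=0),
            crossprod=X.T @ X,
            n_images=1,
            channels=image.channels,
        )

    def merge(self, other: "AccumulatedStats") -> "AccumulatedStats":
        if self.channels != other.channels:
            raise ValueError("channel lists differ")
        return AccumulatedStats(
            n_pixels=self.n_pixels + other.n_pixels,
            sum_vector=self.sum_vector + other.sum_vector,
            crossprod=self.crossprod + other.crossprod,
            n_images=self.n_images + other.n_images,
            channels=self.channels,
        )

    def __add__(self, other: "AccumulatedStats") -> "AccumulatedStats":
        return self.merge(other)


def _pairwise_reduce(items: list[AccumulatedStats]) -> AccumulatedStats:
    """Pairwise (tree) summation of per-image contributions.

    Limits floating-point drift relative to a left-to-right fold when
    the series is long.
    """
    while len(items) > 1:
        items = [
            items[i].merge(items[i + 1]) if i + 1 < len(items) else items[i]
            for i in range(0, len(items), 2)
        ]
    return items[0]


def accumulate_statistics(
    series: Iterable[tuple[MultispectralImage, RoiMask | np.ndarray]],
) -> AccumulatedStats:
    """Single pass over (image, ROI mask) pairs.

    The result is independent of image order (up to floating-point
    reassociation at the 1e-10 relative level).
    """
    parts = [AccumulatedStats.from_image(img, mask) for img, mask in series]
    if not parts:
        raise ValueError("empty series")
    return _pairwise_reduce(parts)


@dataclass
class PcaModel:
    """Global mean pseudo-spectrum, eigenvalues and common loadings."""

    mean: np.ndarray                # (C,)
    eigenvalues: np.ndarray         # (C,), descending
    loadings: np.ndarray            # (C, C), columns are loadings
    explained: np.ndarray           # (C,), percent of total variance
    n_pixels: int
    n_images: int
    channels: tuple[str, ...] = CHANNELS_11

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "mean": self.mean.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings_row_major": self.loadings.tolist(),
            "explained_pct": self.explained.tolist(),
            "n_pixels": self.n_pixels,
            "n_images": self.n_images,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(
            mean=np.asarray(d["mean"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            loadings=np.asarray(d["loadings_row_major"]),
            explained=np.asarray(d["explained_pct"]),
            n_pixels=int(d["n_pixels"]),
            n_images=int(d["n_images"]),
            channels=tuple(d["channels"]),
        )


def _canonicalize_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each loading so its largest-magnitude entry is negative.

    With raw-intensity covariance PCA the first loading is then
    all-negative (an intensity contrast), matching the conventional
    reading of score images where bright tissue appears dark.
    """
    out = loadings.copy()
    for k in range(out.shape[1]):
        j = np.argmax(np.abs(out[:, k]))
        if out[j, k] > 0:
            out[:, k] = -out[:, k]
    return out


def finalize_pca(stats: AccumulatedStats) -> PcaModel:
    """Eigendecomposition of the global variance-covariance matrix.

    Covariance uses the N-1 divisor (explained-variance percentages
    are divisor-invariant).  Channels are not standardized: the
    analysis operates on raw fluorescence counts, so component 1
    captures overall intensity.
    """
    if stats.n_pixels < 2:
        raise ValueError("need at least two pixels")
    if not (np.all(np.isfinite(stats.sum_vector))
            and np.all(np.isfinite(stats.crossprod))):
        raise ValueError("non-finite accumulated statistics")
    N = stats.n_pixels
    m = stats.sum_vector / N
    cov = (stats.crossprod - N * np.outer(m, m)) / (N - 1)
    cov = (cov + cov.T) / 2.0
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = _canonicalize_signs(eigvec[:, order])
    total = eigval.sum()
    explained = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    return PcaModel(
        mean=m,
        eigenvalues=eigval,
        loadings=eigvec,
        explained=explained,
        n_pixels=N,
        n_images=stats.n_images,
        channels=stats.channels,
    )


@dataclass
class ScoreImage:
    """One component's scores refolded onto the pixel grid.

    Values are NaN outside the ROI.  ``bounds`` records the common
    8-bit scaling window of the component across the series.
    """

    component: int
    values: np.ndarray              # float (H, W), NaN outside ROI
    image_id: str | None = None
    bounds: tuple[float, float] | None = None

    def roi_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def project_scores(
    image: MultispectralImage,
    mask: RoiMask | np.ndarray,
    model: PcaModel,
    component: int,
    image_id: str | None = None,
) -> ScoreImage:
    """Score image of one component: (pseudo-spectrum - m) . L[:, k]."""
    if model.channels != image.channels:
        raise ValueError("model and image channel lists differ")
    if not (0 <= component < model.n_components):
        raise ValueError(f"component {component} out of range")
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    values = np.full(image.shape, np.nan)
    X = image.data[m] - model.mean
    values[m] = X @ model.loadings[:, component]
    return ScoreImage(component=component, values=values,
                      image_id=image_id or image.provenance)


def project_all_scores(
    image: MultispectralImage,
    mask: RoiMask | np.ndarray,
    model: PcaModel,
) -> np.ndarray:
    """All-component score table of the ROI pixels, shape (n, C)."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    return (image.data[m] - model.mean) @ model.loadings


def score_bounds(model: PcaModel, component: int,
                 spread: float = 3.0) -> tuple[float, float]:
    """Common 8-bit window of a component: +/- spread * sqrt(lambda_k)."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    half = spread * float(np.sqrt(max(model.eigenvalues[component], 0.0)))
    return (-half, half)


def score_to_8bit(
    score: ScoreImage,
    model: PcaModel,
    spread: float = 3.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render a score image on the series-common 8-bit gray scale.

    The window is derived from the component's eigenvalue, so every
    image of the series shares it; a zero score maps to mid-gray 128
    (rounding half up).  Pixels outside the ROI render as 0.
    """
    lo, hi = score_bounds(model, score.component, spread)
    if hi <= lo:
        if np.any(np.nan_to_num(score.values) != 0):
            raise ValueError("zero eigenvalue with nonzero scores")
        return (np.zeros(score.values.shape, dtype=np.uint8), (lo, hi))
    clipped = np.clip(score.values, lo, hi)
    gray = np.floor((clipped - lo) / (hi - lo) * 255.0 + 0.5)
    gray = np.nan_to_num(gray, nan=0.0)
    return gray.astype(np.uint8), (lo, hi)


def iter_score_arrays(
    series: Iterable[tuple[MultispectralImage, RoiMask | np.ndarray]],
    model: PcaModel,
    component: int,
) -> Iterator[np.ndarray]:
    """Stream per-image 1-D arrays of one component's ROI scores."""
    for image, mask in series:
        m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
        X = image.data[m] - model.mean
        yield X @ model.loadings[:, component]


def dominant_component(
    model: PcaModel,
    channel_names: tuple[str, ...],
    n_candidates: int = 5,
) -> int:
    """Component (among the leading ones) with the largest loading
    energy on the given channels.

    Used to identify, e.g., the red-emission (chlorophyll-like) or the
    BLg (lignin-like) contrast without relying on a fixed index.
    """
    idx = [model.channels.index(c) for c in channel_names]
    k_max = min(n_candidates, model.n_components)
    energy = [
        float(np.sum(model.loadings[idx, k] ** 2)) for k in range(k_max)
    ]
    return int(np.argmax(energy))
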