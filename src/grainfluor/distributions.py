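"""Percentile-binned score distributions and the similarity map.

To compare score images quantitatively, the pooled scores of one
component over the whole series are first histogrammed on a large
number of a-priori linear bins (default 10,000).  Percentiles of that
global distribution (default every 1%) define new, variable-width bins
holding equal shares of the pooled pixels; per-image relative-frequency
distributions on those shared bins then reveal which images concentrate
the contrasted pixels.  A small ordinary PCA of the stacked
distribution vectors yields the similarity map on which developmental
stages can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .large_pca import ScoreImage
from .segmentation import RoiMask

ScoreSource = Callable[[], Iterable[np.ndarray]]


@dataclass
class GlobalHistogram:
    """Pooled fine-grained histogram of one component's scores."""

    component: int
    edges: np.ndarray               # (n_bins + 1,), strictly increasing
    counts: np.ndarray              # (n_bins,), int64
    degenerate: bool = False        # all pooled scores identical

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def _as_source(scores) -> ScoreSource:
    if callable(scores):
        return scores
    arrays = [np.asarray(a, dtype=float).ravel() for a in scores]
    return lambda: arrays


def global_histogram(scores, n_bins: int = 10_000,
                     component: int = 0) -> GlobalHistogram:
    """Two-pass streaming histogram over all ROI pixels of the series.

    ``scores`` is either a callable returning a fresh iterable of 1-D
    score arrays (one per image) or a reusable sequence of arrays.
    Pass one finds the global min/max, pass two fills the counts, so
    the full pixel population is never held at once.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    source = _as_source(scores)

    lo, hi, n_seen = np.inf, -np.inf, 0
    for arr in source():
        arr = np.asarray(arr, dtype=float).ravel()
        if arr.size == 0:
            continue
        lo = min(lo, float(arr.min()))
        hi = max(hi, float(arr.max()))
        n_seen += arr.size
    if n_seen == 0:
        raise ValueError("empty score stream")

    if hi <= lo:  # all scores identical: a single degenerate bin
        return GlobalHistogram(
            component=component,
            edges=np.array([lo, lo]),
            counts=np.array([n_seen], dtype=np.int64),
            degenerate=True,
        )

    edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for arr in source():
        arr = np.asarray(arr, dtype=float).ravel()
        if arr.size:
            counts += np.histogram(arr, bins=edges)[0]
    return GlobalHistogram(component=component, edges=edges, counts=counts)


@dataclass
class PercentileBins:
    """Variable-width bins at percentiles of the global distribution."""

    component: int
    edges: np.ndarray               # (n_bins + 1,), strictly increasing
    percentiles: np.ndarray         # the percentile levels retained

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def percentile_edges(hist: GlobalHistogram,
                     step_percent: float = 1.0) -> PercentileBins:
    """Bin edges at percentiles 0, step, 2*step, ..., 100.

    Percentiles are estimated from the fine histogram by linear
    interpolation within each fine bin; duplicate edges (massive ties
    or empty spans) are merged, so the result may hold fewer than
    100/step bins.
    """
    if not (0 < step_percent <= 50):
        raise ValueError("step_percent must lie in (0, 50]")
    levels = np.arange(0.0, 100.0 + step_percent / 2, step_percent)
    if levels[-1] < 100.0:
        levels = np.append(levels, 100.0)

    if hist.degenerate:
        v = hist.edges[0]
        return PercentileBins(
            component=hist.component,
            edges=np.array([v, v]),
            percentiles=np.array([0.0, 100.0]),
        )

    N = hist.n_total
    cum = np.concatenate([[0], np.cumsum(hist.counts)])
    widths = np.diff(hist.edges)
    edges = []
    for p in levels:
        target = p / 100.0 * N
        if target <= 0:
            edges.append(hist.edges[0])
            continue
        if target >= N:
            edges.append(hist.edges[-1])
            continue
        j = int(np.searchsorted(cum, target, side="left"))  # 1..n_bins
        inside = hist.counts[j - 1]
        frac = (target - cum[j - 1]) / inside if inside > 0 else 0.0
        edges.append(hist.edges[j - 1] + frac * widths[j - 1])
    edges = np.asarray(edges)

    keep = np.concatenate([[True], np.diff(edges) > 0])
    keep[0] = True
    # always retain the final edge (global max)
    merged = edges[keep]
    if merged[-1] < edges[-1]:
        merged = np.append(merged, edges[-1])
        kept_levels = np.append(levels[keep], 100.0)
    else:
        kept_levels = levels[keep]
    return PercentileBins(
        component=hist.component,
        edges=merged,
        percentiles=kept_levels,
    )


@dataclass
class ScoreDistribution:
    """Per-image relative frequencies on the shared percentile bins."""

    image_id: str
    component: int
    frequencies: np.ndarray
    stage: int | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f < 0):
            raise ValueError("frequencies must be nonnegative")
        self.frequencies = f


def observed_distribution(
    score: ScoreImage | np.ndarray,
    mask: RoiMask | np.ndarray | None,
    bins: PercentileBins,
    image_id: str = "",
    stage: int | None = None,
) -> ScoreDistribution:
    """Relative score frequencies of one image on the shared bins.

    Bin intervals are half-open [e_i, e_i+1) with the last closed.
    Scores are clipped into the global span first, so an image whose
    extremes sit exactly on the global bounds is fully counted.
    """
    if isinstance(score, ScoreImage):
        values = score.roi_values()
        if mask is not None:
            m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
            values = score.values[m & np.isfinite(score.values)]
        component = score.component
        image_id = image_id or (score.image_id or "")
    else:
        values = np.asarray(score, dtype=float).ravel()
        component = bins.component
    if values.size == 0:
        raise ValueError("empty ROI")

    if bins.n_bins == 1 and bins.edges[0] == bins.edges[-1]:
        freq = np.array([1.0])
    else:
        clipped = np.clip(values, bins.edges[0], bins.edges[-1])
        counts = np.histogram(clipped, bins=bins.edges)[0]
        freq = counts / values.size
    return ScoreDistribution(
        image_id=image_id, component=component, frequencies=freq, stage=stage
    )


def average_by_stage(
    distributions: list[ScoreDistribution],
) -> pd.DataFrame:
    """Unweighted per-stage mean of the frequency vectors.

    Returns a DataFrame indexed by stage; every row sums to 1 (means
    of convex vectors stay convex).
    """
    if not distributions:
        raise ValueError("no distributions supplied")
    for d in distributions:
        if d.stage is None:
            raise ValueError(f"distribution {d.image_id!r} has no stage label")
    stages = sorted({d.stage for d in distributions})
    rows = {
        s: np.mean(
            [d.frequencies for d in distributions if d.stage == s], axis=0
        )
        for s in stages
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class SimilarityMap:
    """Images placed on the leading axes of the distribution PCA."""

    coordinates: np.ndarray         # (n_images, n_components), centered
    image_ids: list[str]
    stages: list[int | None]
    explained_pct: np.ndarray
    stage_means: pd.DataFrame | None = None

    def stage_centroids(self, axis: int = 0) -> pd.Series:
        df = pd.DataFrame({
            "stage": self.stages,
            "coord": self.coordinates[:, axis],
        })
        return df.groupby("stage")["coord"].mean()


def meta_pca(
    distributions: list[ScoreDistribution],
    n_components: int = 2,
) -> SimilarityMap:
    """Ordinary covariance PCA of the stacked distribution vectors.

    Column-centered, unscaled: the similarity map coordinates are the
    projections of each image's distribution on the leading axes.
    """
    if len(distributions) < 2:
        raise ValueError("need at least two images")
    matrix = np.vstack([d.frequencies for d in distributions])
    if matrix.shape[1] < 2:
        raise ValueError("need at least two bins")
    k = min(n_components, len(distributions) - 1, matrix.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(matrix)
    stage_means = None
    if all(d.stage is not None for d in distributions):
        stage_means = average_by_stage(distributions)
    return SimilarityMap(
        coordinates=coords,
        image_ids=[d.image_id for d in distributions],
        stages=[d.stage for d in distributions],
        explained_pct=100.0 * pca.explained_variance_ratio_,
        stage_means=stage_means,
    )


def spatial_cv(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Spatial coefficient of variation (sd/mean) over an ROI.

    Quantifies patchiness of a nonnegative signal: a sparse dotted
    deposit has CV well above 1, a homogeneous layer well below it.
    """
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[np.asarray(mask, bool)]
    if v.size == 0:
        raise ValueError("empty ROI")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero-mean signal has no defined CV")
    return float(v.std() / mean)


def distributions_to_frame(
    distributions: list[ScoreDistribution], bins: PercentileBins
) -> pd.DataFrame:
    """Long-format table (image, stage, component, bin, edges, freq)."""
    rows = []
    for d in distributions:
        for i, f in enumerate(d.frequencies):
            rows.append({
                "image_id": d.image_id,
                "stage": d.stage,
                "component": d.component,
                "bin_index": i,
                "lower_edge": bins.edges[i],
                "upper_edge": bins.edges[i + 1] if i + 1 < len(bins.edges)
                else bins.edges[-1],
                "frequency": f,
            })
    return pd.DataFrame(rows)
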