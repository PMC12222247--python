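"""Ground-truthed synthetic grain-section acquisitions.

The study design this generator emulates: transverse cryo-sections of
developing bread-wheat grains imaged at four developmental stages (250,
450, 650 and 850 cumulative degree-days after flowering, °DAF), ten
sections per stage taken from five grains, each section acquired as
four 14-bit RGB fluorescence images (filter cubes U1, U2, Blue, Green).

A :class:`SectionPhantom` is a tissue label map (elliptical section
with a ventral crease notch, concentric outer layers, an interior of
starchy endosperm) plus per-fluorophore abundance maps.  Three
fluorophore pseudo-spectra span the contrasts the analysis is designed
to resolve:

* ``chlorophyll`` — red emission under Blue/Green excitation, strong in
  the endocarp early in development and decaying to almost nothing by
  grain desiccation;
* ``hydroxycinnamate`` — blue emission under the two UV excitations,
  rising through grain filling and receding slightly at desiccation;
* ``lignin`` — green emission under Blue excitation plus a broad tail;
  absent early, deposited as patchy dots mid-development and spread
  homogeneously over the outer layers at the last stage.

The forward model is linear mixing of the endmember spectra, a
per-channel additive background, additive Gaussian noise and clipping
to the 14-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as gio
from .channels import (
    BASELINE_CHANNELS,
    CHANNELS_11,
    FILTER_PLANES,
    FILTERS,
    MAX_COUNT,
    VISIBLE_FILTERS,
    channel_index,
)

STAGES: tuple[int, ...] = (250, 450, 650, 850)

TISSUE_CODES: dict[str, int] = {
    "background": 0,
    "outer_pericarp": 1,
    "endocarp": 2,
    "testa_line": 3,
    "aleurone": 4,
    "starchy_endosperm": 5,
    "crease_complex": 6,
    "dot_feature": 7,
}

#: Tissue codes making up the grain outer layers (everything but the
#: starchy endosperm interior).
OUTER_LAYER_CODES: tuple[int, ...] = (1, 2, 3, 4, 6, 7)

# Stage-level study conditions: mean section areas (mm^2) and their
# between-section standard deviations, per developmental stage.
STAGE_AREA_MM2 = {250: 4.64, 450: 6.56, 650: 7.11, 850: 6.11}
STAGE_AREA_SD_MM2 = {250: 0.22, 450: 0.57, 650: 0.37, 850: 0.46}

# Per-stage fluorophore levels (fluorescence counts at unit endmember
# weight).  Chlorophyll fluorescence is high and homogeneous early,
# irregular and patchy at 650 °DAF and reduced to sparse dots at
# 850 °DAF: the per-pixel level stays high where chlorophyll remains,
# while its coverage of the endocarp collapses, so the mean abundance
# over the endocarp is monotone non-increasing.  The UV-excited blue
# emission rises then falls; lignin appears as dots mid-development and
# becomes homogeneous over the outer layers at the last stage.
CHLOROPHYLL_LEVEL = {250: 9000.0, 450: 5500.0, 650: 6000.0, 850: 4000.0}
CHLOROPHYLL_COVERAGE = {250: 1.0, 450: 1.0, 650: 0.35, 850: 0.02}
CHLOROPHYLL_RESIDUAL_FRAC = 0.02   # level outside patches, as a fraction
PHENOLIC_OUTER_LEVEL = {250: 1500.0, 450: 3000.0, 650: 4500.0, 850: 2800.0}
#: The endocarp carries UV-excited blue emission from 450 °DAF onward
#: (cell-wall phenolics appearing during filling), at a fraction of the
#: outer-layer level.
PHENOLIC_ENDOCARP_FRAC = {250: 0.0, 450: 0.5, 650: 0.5, 850: 0.5}
PHENOLIC_ENDOSPERM_LEVEL = {250: 500.0, 450: 500.0, 650: 400.0, 850: 250.0}
LIGNIN_LEVEL = {250: 0.0, 450: 4500.0, 650: 5000.0, 850: 5000.0}
N_DOTS = {250: 0, 450: 40, 650: 120, 850: 0}

#: Default additive background per channel (counts), channel-dependent
#: as observed on real acquisitions.
DEFAULT_BACKGROUND = np.array(
    [120.0, 95.0, 110.0, 90.0, 85.0, 60.0, 70.0, 65.0, 55.0, 50.0, 58.0]
)

#: Number of sections contributed by each of the five grains per stage.
GRAIN_PATTERN: tuple[int, ...] = (3, 2, 2, 2, 1)

# Reference geometry: physical field of view of the stitched large
# image is fixed; the default 512-wide grid is a scaled-down version of
# the full-resolution mosaic, and all pixel-unit parameters scale with
# grid width.
REFERENCE_WIDTH_FULL = 3500
PIXEL_SIZE_FULL_UM = 1.44


@dataclass(frozen=True)
class GeometryParams:
    """Section geometry, parameterized at a given grid size.

    Thickness parameters are in pixels at ``shape`` and scale with the
    grid width relative to the 512-px default.
    """

    shape: tuple[int, int] = (384, 512)
    aspect: float = 0.72            # semi-minor / semi-major axis
    pericarp_px: float = 6.0
    endocarp_px: float = 9.0
    testa_px: float = 2.0
    aleurone_px: float = 4.0
    crease_depth_frac: float = 0.30  # fraction of the semi-minor axis
    crease_mouth_frac: float = 0.14  # half-width at mouth / semi-major
    crease_band_px: float = 10.0
    dot_radius_px: float = 2.0
    margin_px: float = 12.0

    @property
    def scale(self) -> float:
        return self.shape[1] / 512.0

    @property
    def pixel_size_um(self) -> float:
        return PIXEL_SIZE_FULL_UM * REFERENCE_WIDTH_FULL / self.shape[1]

    def px(self, value: float) -> float:
        return max(1.0, value * self.scale)


@dataclass(frozen=True)
class EndmemberSpectrum:
    """A fluorophore pseudo-spectrum over the 11 working channels."""

    name: str
    channel_weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.channel_weights, dtype=float)
        if w.shape != (len(CHANNELS_11),):
            raise ValueError("endmember must have 11 channel weights")
        if np.any(w < 0):
            raise ValueError("endmember weights must be nonnegative")
        for c in BASELINE_CHANNELS:
            if w[channel_index(c)] != 0.0:
                raise ValueError(f"baseline channel {c} must have zero weight")
        object.__setattr__(self, "channel_weights", w)


def _weights(**kv: float) -> np.ndarray:
    w = np.zeros(len(CHANNELS_11))
    for name, value in kv.items():
        w[channel_index(name)] = value
    return w


def default_endmembers() -> list[EndmemberSpectrum]:
    """The three canonical fluorophores of the default phantom."""
    return [
        EndmemberSpectrum("chlorophyll", _weights(
            GRr=1.0, BLr=0.90, U2r=0.25, U1g=0.03, U2g=0.03)),
        EndmemberSpectrum("hydroxycinnamate", _weights(
            U1b=1.0, U1g=0.35, U2b=0.90, U2g=0.30, U2r=0.03)),
        EndmemberSpectrum("lignin", _weights(
            BLg=1.0, U1b=0.30, U1g=0.35, U2b=0.25, U2g=0.30,
            BLr=0.06, GRr=0.03, U2r=0.02)),
    ]


@dataclass
class SectionPhantom:
    """Ground truth for one synthetic grain section."""

    label_map: np.ndarray            # uint8 tissue codes, (H, W)
    stage: int                       # °DAF category
    abundance_maps: dict[str, np.ndarray]
    pixel_size: float                # µm per pixel
    true_background: np.ndarray      # per-channel offset, counts
    seed: int
    geometry: GeometryParams

    def section_mask(self) -> np.ndarray:
        return self.label_map != TISSUE_CODES["background"]

    def outer_layers_mask(self) -> np.ndarray:
        return np.isin(self.label_map, OUTER_LAYER_CODES)

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.label_map == TISSUE_CODES[name]


@dataclass
class RawFilterImage:
    """One RGB acquisition through a single filter cube, 14-bit."""

    filter: str
    rgb_planes: np.ndarray           # uint16 (3, H, W), (R, G, B)
    exposure_gain: float = 1.0

    def __post_init__(self):
        if self.filter not in FILTERS:
            raise ValueError(f"unknown filter {self.filter!r}")
        p = np.asarray(self.rgb_planes)
        if p.ndim != 3 or p.shape[0] != 3:
            raise ValueError("rgb_planes must have shape (3, H, W)")
        if p.min() < 0 or p.max() > MAX_COUNT:
            raise ValueError("plane values outside the 14-bit range")


def _smooth_field(shape, rng, sigma_px: float, sd: float) -> np.ndarray:
    """Multiplicative texture with mean 1 and standard deviation ~sd."""
    if sd <= 0:
        return np.ones(shape)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    s = noise.std()
    if s > 0:
        noise /= s
    return np.clip(1.0 + sd * noise, 0.0, None)


def _patchy_mask(shape, rng, sigma_px: float, coverage: float,
                 region: np.ndarray) -> np.ndarray:
    """Irregular patches covering ~``coverage`` of ``region``'s pixels.

    Thresholds a smoothed noise field at the per-region quantile, so
    the covered fraction is held at the requested value regardless of
    seed.
    """
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    cutoff = np.quantile(field[region], 1.0 - coverage)
    return field > cutoff


def generate_phantom(
    stage: int,
    geometry: GeometryParams | None = None,
    seed: int = 0,
) -> SectionPhantom:
    """Generate one ground-truthed section phantom.

    Deterministic for a fixed seed.  Raises ``ValueError`` for an
    unknown stage or a geometry that does not fit the grid.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    geom = geometry or GeometryParams()
    rng = np.random.default_rng(seed)
    H, W = geom.shape
    ps = geom.pixel_size_um

    # Section size: per-stage mean area with between-section jitter.
    rel_sd = STAGE_AREA_SD_MM2[stage] / STAGE_AREA_MM2[stage]
    area_mm2 = STAGE_AREA_MM2[stage] * (1.0 + rng.normal(0.0, rel_sd))
    area_px = area_mm2 * 1e6 / ps**2
    a = float(np.sqrt(area_px / (np.pi * geom.aspect)))
    b = a * geom.aspect
    if 2 * a + 2 * geom.margin_px > W or 2 * b + 2 * geom.margin_px > H:
        raise ValueError("section geometry exceeds the image grid")

    cy = H / 2.0 + rng.uniform(-2.0, 2.0) * geom.scale
    cx = W / 2.0 + rng.uniform(-3.0, 3.0) * geom.scale
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    ellipse = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    # Ventral crease: a tapering notch carved upward from the bottom.
    depth = geom.crease_depth_frac * b
    mouth_hw = geom.crease_mouth_frac * a
    tip_hw = max(1.5, 0.15 * mouth_hw)
    y_bottom = cy + b
    t = np.clip((yy - (y_bottom - depth)) / depth, 0.0, 1.0)
    halfwidth = tip_hw + (mouth_hw - tip_hw) * t
    notch = (yy >= y_bottom - depth) & (np.abs(xx - cx) <= halfwidth)
    section = ellipse & ~notch

    labels = np.zeros((H, W), dtype=np.uint8)
    depth_map = ndimage.distance_transform_edt(section)
    t_p = geom.px(geom.pericarp_px)
    t_e = t_p + geom.px(geom.endocarp_px)
    t_t = t_e + geom.px(geom.testa_px)
    t_a = t_t + geom.px(geom.aleurone_px)
    labels[section] = TISSUE_CODES["starchy_endosperm"]
    labels[section & (depth_map < t_a)] = (
        TISSUE_CODES["aleurone"] if stage >= 450
        else TISSUE_CODES["starchy_endosperm"]
    )
    labels[section & (depth_map < t_t)] = TISSUE_CODES["testa_line"]
    labels[section & (depth_map < t_e)] = TISSUE_CODES["endocarp"]
    labels[section & (depth_map < t_p)] = TISSUE_CODES["outer_pericarp"]

    # Crease complex: tissue within a band around the notch.
    dist_to_notch = ndimage.distance_transform_edt(~notch)
    crease = section & (dist_to_notch <= geom.px(geom.crease_band_px))
    labels[crease] = TISSUE_CODES["crease_complex"]

    # Lignin dots in the outer layers at mid development.
    n_dots = N_DOTS[stage]
    if n_dots:
        band = section & (depth_map < t_a)
        candidates = np.flatnonzero(band)
        chosen = rng.choice(candidates, size=min(n_dots, candidates.size),
                            replace=False)
        dot_centers = np.zeros(H * W, dtype=bool)
        dot_centers[chosen] = True
        r = geom.px(geom.dot_radius_px)
        dots = (
            ndimage.distance_transform_edt(~dot_centers.reshape(H, W)) <= r
        ) & section
        labels[dots] = TISSUE_CODES["dot_feature"]

    # --- abundance maps -----------------------------------------------------
    def lvl(table):
        return table[stage] * (1.0 + rng.normal(0.0, 0.02))

    chl = np.zeros((H, W))
    chl_tissues = (labels == TISSUE_CODES["endocarp"]) | crease
    chl[chl_tissues] = lvl(CHLOROPHYLL_LEVEL)
    coverage = CHLOROPHYLL_COVERAGE[stage]
    if coverage < 1.0:
        patches = _patchy_mask((H, W), rng, 2.0 * geom.scale,
                               coverage, chl_tissues)
        chl[chl_tissues & ~patches] *= CHLOROPHYLL_RESIDUAL_FRAC
    chl *= _smooth_field((H, W), rng, 3.0 * geom.scale, 0.15)

    phen = np.zeros((H, W))
    phen_tissues = (
        (labels == TISSUE_CODES["outer_pericarp"])
        | (labels == TISSUE_CODES["testa_line"])
        | (labels == TISSUE_CODES["aleurone"])
        | crease
    )
    phen[phen_tissues] = lvl(PHENOLIC_OUTER_LEVEL)
    phen[labels == TISSUE_CODES["endocarp"]] = (
        lvl(PHENOLIC_OUTER_LEVEL) * PHENOLIC_ENDOCARP_FRAC[stage])
    phen[labels == TISSUE_CODES["starchy_endosperm"]] = lvl(
        PHENOLIC_ENDOSPERM_LEVEL)
    phen *= _smooth_field((H, W), rng, 4.0 * geom.scale, 0.15)

    lig = np.zeros((H, W))
    if stage in (450, 650):
        lig[labels == TISSUE_CODES["dot_feature"]] = lvl(LIGNIN_LEVEL)
    elif stage == 850:
        outer = np.isin(labels, OUTER_LAYER_CODES)
        lig[outer] = lvl(LIGNIN_LEVEL)
        lig *= _smooth_field((H, W), rng, 4.0 * geom.scale, 0.10)

    abundance_maps = {
        "chlorophyll": np.clip(chl, 0.0, None),
        "hydroxycinnamate": np.clip(phen, 0.0, None),
        "lignin": np.clip(lig, 0.0, None),
    }
    return SectionPhantom(
        label_map=labels,
        stage=stage,
        abundance_maps=abundance_maps,
        pixel_size=ps,
        true_background=DEFAULT_BACKGROUND.copy(),
        seed=seed,
        geometry=geom,
    )


def mixed_signal(
    phantom: SectionPhantom,
    endmembers: list[EndmemberSpectrum] | None = None,
) -> np.ndarray:
    """Noise-free, background-free linear mixing term, shape (H, W, 11)."""
    endmembers = endmembers if endmembers is not None else default_endmembers()
    H, W = phantom.label_map.shape
    signal = np.zeros((H, W, len(CHANNELS_11)))
    for em in endmembers:
        ab = phantom.abundance_maps.get(em.name)
        if ab is None:
            continue
        signal += ab[..., None] * em.channel_weights
    return signal


def render_filter_images(
    phantom: SectionPhantom,
    endmembers: list[EndmemberSpectrum] | None = None,
    noise_sd: float = 10.0,
    seed: int = 0,
    visible_gain: float = 1.0,
    reflection_level: float = 6000.0,
    seam_amplitude: float = 0.0,
) -> dict[str, RawFilterImage]:
    """Render the four RGB filter acquisitions of one phantom.

    The expected value of each working channel at a pixel is
    ``sum_f abundance_f * weight_f(channel) + background(channel)``.
    The U1 red plane carries the excitation-band reflection artefact
    instead of fluorescence.  Planes of the visible filters (BL, GR)
    are divided by ``visible_gain`` before digitization, emulating their
    lower raw intensity; assembly multiplies it back.  ``seam_amplitude``
    optionally adds a multiplicative stitching-band artefact (off by
    default).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if visible_gain <= 0:
        raise ValueError("visible_gain must be positive")
    rng = np.random.default_rng(seed)
    H, W = phantom.label_map.shape

    expected = mixed_signal(phantom, endmembers) + phantom.true_background
    if seam_amplitude:
        seam = np.ones((H, W))
        seam[:, W // 2: W // 2 + max(1, W // 100)] *= 1.0 + seam_amplitude
        expected = expected * seam[..., None]

    u1r = np.full((H, W), float(DEFAULT_BACKGROUND.mean()))
    u1r[phantom.section_mask()] += reflection_level

    def digitize(plane: np.ndarray) -> np.ndarray:
        noisy = plane + (rng.normal(0.0, noise_sd, plane.shape)
                         if noise_sd > 0 else 0.0)
        return np.clip(np.rint(noisy), 0, MAX_COUNT).astype(np.uint16)

    out: dict[str, RawFilterImage] = {}
    for filt in FILTERS:
        gain = visible_gain if filt in VISIBLE_FILTERS else 1.0
        planes = []
        for chan in FILTER_PLANES[filt]:
            if chan == "U1r":
                plane = u1r
            else:
                plane = expected[..., channel_index(chan)]
            planes.append(digitize(plane / gain))
        out[filt] = RawFilterImage(
            filter=filt,
            rgb_planes=np.stack(planes),
            exposure_gain=1.0 / gain,
        )
    return out


DEFAULT_DESIGN: dict[int, int] = {s: 10 for s in STAGES}


def _grain_ids(n: int) -> list[int]:
    """Assign sections to grains following the per-stage study pattern."""
    ids: list[int] = []
    grain = 1
    while len(ids) < n:
        count = GRAIN_PATTERN[(grain - 1) % len(GRAIN_PATTERN)]
        ids.extend([grain] * count)
        grain += 1
    return ids[:n]


def generate_series(
    design: dict[int, int] | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    geometry: GeometryParams | None = None,
    endmembers: list[EndmemberSpectrum] | None = None,
    noise_sd: float = 10.0,
    visible_gain: float = 1.0,
):
    """Generate the acquisition series of the default study design.

    Returns ``(manifest, acquisitions)`` where ``manifest`` is a
    DataFrame (section_id, stage, grain_id, seed and, when ``out_dir``
    is given, file paths) and ``acquisitions`` maps section_id to a
    ``(phantom, {filter: RawFilterImage})`` pair.  With ``out_dir`` the
    four filter TIFFs and the ground-truth sidecar (label TIFF + JSON)
    of every section are written as well.
    """
    design = design if design is not None else dict(DEFAULT_DESIGN)
    if not design or sum(design.values()) == 0:
        raise ValueError("design must request at least one section")
    for stage in design:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")

    rng = np.random.default_rng(seed)
    rows = []
    acquisitions = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "raw").mkdir(parents=True, exist_ok=True)
        (out_path / "truth").mkdir(parents=True, exist_ok=True)

    for stage in sorted(design):
        n = design[stage]
        grains = _grain_ids(n)
        for idx in range(n):
            child_seed = int(rng.integers(0, 2**31 - 1))
            section_id = f"s{stage}_g{grains[idx]}_{idx + 1:02d}"
            phantom = generate_phantom(stage, geometry, seed=child_seed)
            filters = render_filter_images(
                phantom, endmembers, noise_sd=noise_sd,
                seed=child_seed + 1, visible_gain=visible_gain,
            )
            acquisitions[section_id] = (phantom, filters)
            row = {
                "section_id": section_id,
                "stage": stage,
                "grain_id": grains[idx],
                "seed": child_seed,
                "visible_gain": visible_gain,
                "pixel_size_um": phantom.pixel_size,
            }
            if out_path is not None:
                for filt, raw in filters.items():
                    p = out_path / "raw" / f"{section_id}_{filt}.tif"
                    gio.write_raw_filter(p, raw.rgb_planes)
                    row[f"path_{filt}"] = str(p)
                label_path = out_path / "truth" / f"{section_id}_labels.tif"
                gio.write_label_map(label_path, phantom.label_map)
                gio.write_json(
                    out_path / "truth" / f"{section_id}_meta.json",
                    {
                        "section_id": section_id,
                        "stage": stage,
                        "seed": child_seed,
                        "pixel_size_um": phantom.pixel_size,
                        "true_background": phantom.true_background.tolist(),
                        "visible_gain": visible_gain,
                    },
                )
                row["path_labels"] = str(label_path)
            rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return manifest, acquisitions
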