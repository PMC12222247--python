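"""End-to-end orchestration of the multispectral analysis run.

A run goes: simulate (or ingest) the acquisition series -> assemble and
background-correct the 11-channel cubes -> segment the two ROIs and
measure section areas -> fit the series-wide streaming PCA and render
score images on the common scale -> compute percentile-binned score
distributions on the outer-tissue ROI -> average by stage and build the
similarity maps.  Every stage reads its inputs from and writes its
outputs to the run directory, so a run can be resumed stage by stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .assembly import (
    BackgroundVector,
    MultispectralImage,
    assemble_multispectral,
    composite_rgb,
    estimate_background,
    subtract_background,
    sum_intensity_image,
)
from .channels import CHANNELS_11
from .distributions import (
    average_by_stage,
    distributions_to_frame,
    global_histogram,
    meta_pca,
    observed_distribution,
    percentile_edges,
)
from .large_pca import (
    PcaModel,
    accumulate_statistics,
    project_scores,
    score_to_8bit,
)
from .segmentation import (
    RoiMask,
    scaled_size,
    section_area,
    segment_outer_tissues,
    segment_section,
)
from .synthetic import GeometryParams, generate_series

log = logging.getLogger("grainfluor")

STAGE_ORDER = (
    "simulate", "assemble", "segment", "pca", "distributions", "similarity",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "run"
    input_mode: str = "synthetic"            # "synthetic" | "directory"
    input_dir: str | None = None             # directory mode: acquisitions
    design: dict[int, int] | None = None     # stage -> section count
    shape: tuple[int, int] = (384, 512)
    noise_sd: float = 10.0
    visible_gain: float = 1.0
    seed: int = 0
    background_regions: list[tuple[int, int, int, int]] | None = None
    n_background_images: int = 4
    section_threshold: int = 2
    section_threshold_overrides: dict[str, int] = field(default_factory=dict)
    outer_overrides: dict[str, dict] = field(default_factory=dict)
    n_render_components: int = 5
    spread: float = 3.0
    n_bins: int = 10_000
    step_percent: float = 1.0
    write_score_tiffs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "design" in raw and raw["design"] is not None:
            raw["design"] = {int(k): int(v) for k, v in raw["design"].items()}
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["shape"] = list(self.shape)
        return d

    @property
    def root(self) -> Path:
        return Path(self.out_dir)


def _marker(cfg: RunConfig, stage: str) -> Path:
    return cfg.root / f".done_{stage}"


def _default_regions(shape: tuple[int, int]):
    """Three signal-free corner rectangles (the grain sits centered)."""
    H, W = shape
    h, w, m = max(8, H // 10), max(8, W // 12), 2
    return [
        (m, m + h, m, m + w),
        (m, m + h, W - m - w, W - m),
        (H - m - h, H - m, m, m + w),
    ]


def load_manifest(cfg: RunConfig) -> pd.DataFrame:
    path = cfg.root / "input" / "manifest.csv"
    if cfg.input_mode == "directory":
        path = Path(cfg.input_dir) / "manifest.csv"
    return pd.read_csv(path)


def _input_dir(cfg: RunConfig) -> Path:
    return Path(cfg.input_dir) if cfg.input_mode == "directory" \
        else cfg.root / "input"


def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    """Generate the synthetic acquisition series (synthetic mode)."""
    if cfg.input_mode == "directory":
        if cfg.input_dir is None or not Path(cfg.input_dir).exists():
            raise FileNotFoundError("directory mode requires input_dir")
        log.info("ingesting acquisitions from %s", cfg.input_dir)
        return load_manifest(cfg)
    log.info("simulating acquisition series (seed=%d)", cfg.seed)
    manifest, _ = generate_series(
        design=cfg.design,
        out_dir=cfg.root / "input",
        seed=cfg.seed,
        geometry=GeometryParams(shape=cfg.shape),
        noise_sd=cfg.noise_sd,
        visible_gain=cfg.visible_gain,
    )
    return manifest


def _read_acquisition(row: pd.Series, input_dir: Path):
    from .synthetic import RawFilterImage

    out = {}
    for filt in ("U1", "U2", "BL", "GR"):
        key = f"path_{filt}"
        path = Path(row[key]) if key in row and pd.notna(row.get(key)) \
            else input_dir / "raw" / f"{row['section_id']}_{filt}.tif"
        if not path.exists():
            raise FileNotFoundError(
                f"section {row['section_id']}: missing {filt} acquisition"
            )
        out[filt] = RawFilterImage(filter=filt,
                                   rgb_planes=gio.read_raw_filter(path))
    return out


def _cube_path(cfg: RunConfig, section_id: str) -> Path:
    return cfg.root / "cubes" / f"{section_id}_cube.tif"


def _read_cube(cfg: RunConfig, section_id: str) -> MultispectralImage:
    data, channels, meta = gio.read_multispectral(_cube_path(cfg, section_id))
    return MultispectralImage(
        data=data, channels=channels,
        pixel_size=meta.get("pixel_size_um"), provenance=section_id,
    )


def stage_assemble(cfg: RunConfig, manifest: pd.DataFrame) -> BackgroundVector:
    """Assemble cubes, estimate and subtract the channel background."""
    input_dir = _input_dir(cfg)
    (cfg.root / "cubes").mkdir(parents=True, exist_ok=True)
    (cfg.root / "composites").mkdir(exist_ok=True)

    def assemble_row(row):
        acq = _read_acquisition(row, input_dir)
        gain = float(row.get("visible_gain", cfg.visible_gain))
        return assemble_multispectral(
            acq, visible_gain=gain,
            pixel_size=float(row.get("pixel_size_um", np.nan)),
            provenance=row["section_id"],
        )

    # Background: a few signal-free rectangles read on one acquisition
    # per stage (or the first few sections).
    picks = (manifest.groupby("stage").head(1)
             if "stage" in manifest else manifest.head(1))
    picks = picks.head(cfg.n_background_images)
    regions = cfg.background_regions or _default_regions(cfg.shape)
    bg_images = [assemble_row(row) for _, row in picks.iterrows()]
    background = estimate_background(bg_images, regions)
    gio.write_json(cfg.root / "background.json", {
        "channels": list(CHANNELS_11),
        "values": background.values.tolist(),
        "n_regions_used": background.n_regions_used,
        "regions": [list(r) for r in regions],
        "images": picks["section_id"].tolist(),
    })
    log.info("background estimated from %d regions",
             background.n_regions_used)

    for _, row in manifest.iterrows():
        sid = row["section_id"]
        image = subtract_background(assemble_row(row), background)
        gio.write_multispectral(
            _cube_path(cfg, sid), image.data, image.channels,
            pixel_size=image.pixel_size, provenance=sid,
        )
        gio.write_png(cfg.root / "composites" / f"{sid}_sum8.png",
                      sum_intensity_image(image))
        gio.write_png(cfg.root / "composites" / f"{sid}_composite.png",
                      composite_rgb(image))
        log.debug("assembled %s", sid)
    return background


def _mask_path(cfg: RunConfig, section_id: str, kind: str) -> Path:
    return cfg.root / "masks" / f"{section_id}_{kind}.tif"


def _read_roi(cfg: RunConfig, section_id: str, kind: str) -> RoiMask:
    path = _mask_path(cfg, section_id, kind)
    params = gio.read_json(path.with_suffix(path.suffix + ".json"))
    return RoiMask(mask=gio.read_mask(path), kind=kind, params_used=params)


def stage_segment(cfg: RunConfig, manifest: pd.DataFrame) -> pd.DataFrame:
    """Compute both ROIs per section and the section-area table."""
    (cfg.root / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in manifest.iterrows():
        sid = row["section_id"]
        image = _read_cube(cfg, sid)
        sum8 = sum_intensity_image(image)
        thr = cfg.section_threshold_overrides.get(sid, cfg.section_threshold)
        section = segment_section(sum8, threshold=thr)
        outer = segment_outer_tissues(
            image, section, **cfg.outer_overrides.get(sid, {})
        )
        gio.write_mask(_mask_path(cfg, sid, "whole_section"),
                       section.mask, section.params_used)
        gio.write_mask(_mask_path(cfg, sid, "outer_tissues"),
                       outer.mask, outer.params_used)
        ps = float(row.get("pixel_size_um", image.pixel_size or np.nan))
        rows.append({
            "section_id": sid,
            "stage": row.get("stage"),
            "area_mm2": section_area(section, ps),
            "n_section_pixels": section.n_pixels,
            "n_outer_pixels": outer.n_pixels,
        })
        log.debug("segmented %s", sid)
    areas = pd.DataFrame(rows)
    areas.to_csv(cfg.root / "areas.csv", index=False)
    return areas


def _iter_series(cfg: RunConfig, manifest: pd.DataFrame, kind: str):
    for _, row in manifest.iterrows():
        sid = row["section_id"]
        yield _read_cube(cfg, sid), _read_roi(cfg, sid, kind)


def stage_pca(cfg: RunConfig, manifest: pd.DataFrame) -> PcaModel:
    """Fit the streaming PCA on whole-section pixels; render scores."""
    stats = accumulate_statistics(
        _iter_series(cfg, manifest, "whole_section"))
    model = finalize = None
    from .large_pca import finalize_pca  # local import keeps module lean

    model = finalize_pca(stats)
    gio.write_json(cfg.root / "pca_model.json", model.to_dict() | {
        "spread": cfg.spread,
    })
    log.info("large PCA fitted on %d pixels of %d images; top-5 "
             "explained %.2f%%", model.n_pixels, model.n_images,
             model.explained[:5].sum())

    scores_dir = cfg.root / "scores"
    scores_dir.mkdir(exist_ok=True)
    n_comp = min(cfg.n_render_components, model.n_components)
    for _, row in manifest.iterrows():
        sid = row["section_id"]
        image = _read_cube(cfg, sid)
        roi = _read_roi(cfg, sid, "whole_section")
        for k in range(n_comp):
            score = project_scores(image, roi, model, k, image_id=sid)
            gray, bounds = score_to_8bit(score, model, cfg.spread)
            gio.write_png(scores_dir / f"{sid}_c{k + 1}.png", gray)
            if cfg.write_score_tiffs:
                gio.write_multispectral(
                    scores_dir / f"{sid}_c{k + 1}.tif",
                    score.values[..., None].astype(np.float32),
                    channels=(f"score_c{k + 1}",),
                    provenance=sid,
                )
    return model


def stage_distributions(cfg: RunConfig, manifest: pd.DataFrame,
                        model: PcaModel | None = None) -> pd.DataFrame:
    """Percentile-binned score distributions on the outer-tissue ROI.

    The global percentile pass and the per-image pass both use the
    outer-tissue pixels, so the pooled distribution is uniform across
    bins by construction.
    """
    if model is None:
        model = PcaModel.from_dict(gio.read_json(cfg.root / "pca_model.json"))
    (cfg.root / "distributions").mkdir(exist_ok=True)
    n_comp = min(cfg.n_render_components, model.n_components)

    all_frames = []
    for k in range(n_comp):
        def score_stream():
            from .large_pca import iter_score_arrays
            return iter_score_arrays(
                _iter_series(cfg, manifest, "outer_tissues"), model, k)

        hist = global_histogram(score_stream, n_bins=cfg.n_bins, component=k)
        bins = percentile_edges(hist, step_percent=cfg.step_percent)
        gio.write_json(
            cfg.root / "distributions" / f"bins_c{k + 1}.json",
            {
                "component": k + 1,
                "n_bins_global": cfg.n_bins,
                "global_min": float(hist.edges[0]),
                "global_max": float(hist.edges[-1]),
                "n_total_pixels": hist.n_total,
                "percentile_step": cfg.step_percent,
                "edges": bins.edges.tolist(),
            },
        )
        dists = []
        for (image, roi), (_, row) in zip(
            _iter_series(cfg, manifest, "outer_tissues"),
            manifest.iterrows(),
        ):
            score = project_scores(image, roi, model, k,
                                   image_id=row["section_id"])
            dists.append(observed_distribution(
                score, roi, bins, stage=int(row["stage"])))
        frame = distributions_to_frame(dists, bins)
        all_frames.append(frame)
        average_by_stage(dists).to_csv(
            cfg.root / "distributions" / f"stage_means_c{k + 1}.csv")
        log.info("component %d: %d percentile bins", k + 1, bins.n_bins)

    table = pd.concat(all_frames, ignore_index=True)
    table.to_csv(cfg.root / "distributions" / "distributions.csv",
                 index=False)
    return table


def stage_similarity(cfg: RunConfig, manifest: pd.DataFrame) -> pd.DataFrame:
    """Similarity maps: PCA of the per-image score distributions."""
    from .distributions import ScoreDistribution

    table = pd.read_csv(cfg.root / "distributions" / "distributions.csv")
    (cfg.root / "similarity").mkdir(exist_ok=True)
    rows = []
    for comp, sub in table.groupby("component"):
        dists = []
        for sid, img_rows in sub.groupby("image_id", sort=False):
            img_rows = img_rows.sort_values("bin_index")
            dists.append(ScoreDistribution(
                image_id=str(sid),
                component=int(comp),
                frequencies=img_rows["frequency"].to_numpy(),
                stage=int(img_rows["stage"].iloc[0]),
            ))
        if len(dists) < 2:
            log.warning("component %s: fewer than 2 images, similarity "
                        "map skipped", comp)
            continue
        smap = meta_pca(dists, n_components=2)
        for i, sid in enumerate(smap.image_ids):
            rows.append({
                "component": comp,
                "image_id": sid,
                "stage": smap.stages[i],
                "axis1": smap.coordinates[i, 0],
                "axis2": smap.coordinates[i, 1]
                if smap.coordinates.shape[1] > 1 else 0.0,
                "explained1_pct": smap.explained_pct[0],
                "explained2_pct": smap.explained_pct[1]
                if len(smap.explained_pct) > 1 else 0.0,
            })
        _plot_similarity(cfg, smap, comp)
    result = pd.DataFrame(rows)
    result.to_csv(cfg.root / "similarity" / "similarity_map.csv", index=False)
    return result


def _plot_similarity(cfg: RunConfig, smap, comp) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    stages = np.asarray([s or 0 for s in smap.stages])
    for stage in np.unique(stages):
        sel = stages == stage
        ax.scatter(smap.coordinates[sel, 0],
                   smap.coordinates[sel, 1]
                   if smap.coordinates.shape[1] > 1
                   else np.zeros(sel.sum()),
                   label=f"{stage} °DAF", s=25)
    ax.set_xlabel(f"axis 1 ({smap.explained_pct[0]:.1f}%)")
    ax.set_ylabel(
        f"axis 2 ({smap.explained_pct[1]:.1f}%)"
        if len(smap.explained_pct) > 1 else "axis 2")
    ax.legend(fontsize=8)
    ax.set_title(f"Similarity map, score component {comp}")
    fig.tight_layout()
    fig.savefig(cfg.root / "similarity" / f"similarity_c{comp}.png", dpi=120)
    plt.close(fig)


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Run every stage in order; with ``resume`` completed stages are
    skipped (identified by their done-markers) and the final outputs
    are unchanged."""
    cfg.root.mkdir(parents=True, exist_ok=True)
    manifest = None

    def done(stage: str) -> bool:
        return resume and _marker(cfg, stage).exists()

    def finish(stage: str) -> None:
        _marker(cfg, stage).touch()

    if not done("simulate"):
        manifest = stage_simulate(cfg)
        finish("simulate")
    else:
        log.info("resume: simulate already done")
    manifest = load_manifest(cfg) if manifest is None else manifest

    if not done("assemble"):
        stage_assemble(cfg, manifest)
        finish("assemble")
    if not done("segment"):
        stage_segment(cfg, manifest)
        finish("segment")
    model = None
    if not done("pca"):
        model = stage_pca(cfg, manifest)
        finish("pca")
    if not done("distributions"):
        stage_distributions(cfg, manifest, model)
        finish("distributions")
    if not done("similarity"):
        if len(manifest) >= 2:
            stage_similarity(cfg, manifest)
        else:
            log.warning("single-section run: similarity map needs >= 2 "
                        "images, skipped")
        finish("similarity")

    areas = pd.read_csv(cfg.root / "areas.csv")
    by_stage = areas.groupby("stage")["area_mm2"].agg(["mean", "std"])
    manifest_out = {
        "config": cfg.to_dict(),
        "n_sections": int(len(manifest)),
        "seed": cfg.seed,
        "area_mm2_by_stage": {
            str(s): {"mean": float(r["mean"]),
                     "sd": float(r["std"]) if np.isfinite(r["std"]) else None}
            for s, r in by_stage.iterrows()
        },
        "element_scale_note": {
            "grid_width": cfg.shape[1],
            "section_open": scaled_size(51, cfg.shape[1]),
            "section_close": scaled_size(150, cfg.shape[1]),
        },
    }
    gio.write_json(cfg.root / "run_manifest.json", manifest_out)
    log.info("pipeline complete: %d sections", len(manifest))
    return manifest_out
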