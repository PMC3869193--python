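"""End-to-end pipeline: simulate → extract → analyze, with a run manifest.

A run is fully described by a serializable :class:`PipelineConfig` plus its
seed; re-running the same config and seed reproduces the synthetic outputs
bit-identically.  Outputs are plain files — per-droplet TIFF stacks, long-
format ``series.csv``, per-droplet ``results.csv``, per-group
``summary.csv``, the occupancy design table, curve plots, and a
``manifest.json`` listing every output with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import growth, imaging, occupancy, scene as scene_mod

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "series_to_frame"]

log = logging.getLogger("moca")


def _version() -> str:
    try:
        return _pkg_version("moca")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


class LayoutConfig(BaseModel):
    n_rows: int = 4
    n_cols: int = 6
    spot_diameter_mm: float = 3.18
    pitch_mm: float = 4.5
    pixels_per_mm: float = 100.0
    frame_margin: float = 0.2

    def build(self) -> scene_mod.DropletLayout:
        return scene_mod.DropletLayout(**self.model_dump())


class GrowthConfig(BaseModel):
    specific_growth_rate: float = 0.7
    lag_mean_h: float = 2.0
    lag_sd_h: float = 1.0
    initial_biomass_per_cell: float = 1.0
    carrying_capacity: float = 1.5e6
    sporulation: bool = False
    rebound_ramp_h: float = 6.0
    rebound_fraction: float = 0.3

    def build(self) -> scene_mod.GrowthParams:
        return scene_mod.GrowthParams(**self.model_dump())


class RenderConfig(BaseModel):
    background_intensity: float = 200.0
    oil_intensity: float = 120.0
    colony_optical_depth: float = 2.5
    colony_area_per_biomass: float = 0.03
    noise_sd: float = 2.0
    illumination_low: float = 0.9
    illumination_high: float = 1.1
    measurement_shrink: float = 0.9
    placement_radius_fraction: float = 0.8

    def build(self) -> scene_mod.RenderParams:
        return scene_mod.RenderParams(**self.model_dump())


class AnalysisConfig(BaseModel):
    threshold: float = 0.99
    baseline_frames: int = 1
    min_final_drop: float = 0.05
    rebound_min_rise: float = 0.05
    rebound_min_frames: int = 6


class PipelineConfig(BaseModel):
    """Validated, YAML-serializable description of one synthetic run."""

    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    concentrations: list[float] = [1000.0, 100.0, 10.0, 1.0]  # cells/ul
    droplets_per_concentration: int = 6
    volume_ul: float = 1.0
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    render: RenderConfig = Field(default_factory=RenderConfig)
    t_end_h: float = 72.0
    frame_interval_h: float = 0.5
    substep_h: float = 0.05
    extraction_mode: str = "grid"
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)


def series_to_frame(series_list) -> pd.DataFrame:
    """Long-format series table: droplet_id, time_h, raw_mean_intensity, pixel_count."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "droplet_id": s.droplet_id,
                    "time_h": s.times_h,
                    "raw_mean_intensity": s.raw_mean_intensity,
                    "pixel_count": s.pixel_count,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _plot_curves(results, threshold, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    groups = sorted({r.group for r in results})
    cmap = plt.get_cmap("viridis")
    colors = {g: cmap(i / max(len(groups) - 1, 1)) for i, g in enumerate(groups)}
    for r in results:
        ax.plot(r.times_h, r.normalized, color=colors[r.group], lw=0.8, alpha=0.8)
    ax.axhline(threshold, color="red", ls=":", lw=1)
    handles = [plt.Line2D([], [], color=colors[g], label=f"{g:g} cells/droplet") for g in groups]
    ax.legend(handles=handles, fontsize=8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized transmission")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_boxes(summaries, results, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [s.group for s in summaries if s.n_grew > 0]
    data = [
        [
            r.threshold_time_h
            for r in results
            if r.group == g and r.grew and r.threshold_time_h is not None
        ]
        for g in groups
    ]
    fig, ax = plt.subplots(figsize=(5, 4))
    if data:
        ax.boxplot(data, tick_labels=[f"{g:g}" for g in groups], whis=1.5)
    ax.set_xlabel("nominal cells per droplet")
    ax.set_ylabel("threshold growth time (h)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Run simulate → extract → analyze and write all outputs under ``outdir``.

    Returns a dict with the in-memory results and the manifest.  ``seed``
    overrides ``config.seed`` when given.
    """
    seed = config.seed if seed is None else int(seed)
    os.makedirs(outdir, exist_ok=True)
    files: list[str] = []

    # -- simulate ----------------------------------------------------------
    log.info("simulate: planning %d droplets", config.layout.n_rows * config.layout.n_cols)
    layout = config.layout.build()
    times = scene_mod.default_times(config.t_end_h, config.frame_interval_h)
    syn = scene_mod.plan_experiment(
        layout,
        config.concentrations,
        config.droplets_per_concentration,
        config.volume_ul,
        seed=seed,
        growth=config.growth.build(),
        render=config.render.build(),
        times_h=times,
        substep_h=config.substep_h,
    )
    stack, truth = scene_mod.render_stack(syn, threshold=config.analysis.threshold)
    scene_dir = os.path.join(outdir, "scene")
    files += scene_mod.write_scene(syn, stack, truth, scene_dir)

    # -- extract -----------------------------------------------------------
    log.info("extract: mode=%s", config.extraction_mode)
    rois = imaging.locate_droplets(stack, layout, mode=config.extraction_mode)
    series = imaging.extract_transmission(stack, rois, syn.times_h)
    series_path = os.path.join(outdir, "series.csv")
    series_to_frame(series).to_csv(series_path, index=False)
    files.append(series_path)

    # -- analyze -----------------------------------------------------------
    log.info("analyze: threshold=%g", config.analysis.threshold)
    groups = {d.droplet_id: d.group for d in syn.droplets}
    a = config.analysis
    results = growth.analyze_experiment(
        series,
        groups,
        threshold=a.threshold,
        baseline_frames=a.baseline_frames,
        min_final_drop=a.min_final_drop,
        rebound_min_rise=a.rebound_min_rise,
        rebound_min_frames=a.rebound_min_frames,
    )
    results_path = os.path.join(outdir, "results.csv")
    growth.results_to_frame(results).to_csv(results_path, index=False)
    files.append(results_path)

    summaries = growth.summarize_groups(results)
    summary_path = os.path.join(outdir, "summary.csv")
    growth.summaries_to_frame(summaries).to_csv(summary_path, index=False)
    files.append(summary_path)

    # -- occupancy design table -------------------------------------------
    occ_rows = []
    for conc in config.concentrations:
        lam = occupancy.lambda_from_loading(conc, config.volume_ul)
        ks, ps = occupancy.occupancy_table(lam, max_k=8)
        for k, p in zip(ks, ps):
            occ_rows.append(
                {
                    "concentration_per_ul": conc,
                    "mean_occupancy": lam,
                    "k": int(k),
                    "probability": float(p),
                    "percent": 100.0 * float(p),
                }
            )
    occ_path = os.path.join(outdir, "occupancy.csv")
    pd.DataFrame(occ_rows).to_csv(occ_path, index=False)
    files.append(occ_path)

    # -- plots -------------------------------------------------------------
    plots_dir = os.path.join(outdir, "plots")
    os.makedirs(plots_dir, exist_ok=True)
    curves_png = os.path.join(plots_dir, "growth_curves.png")
    boxes_png = os.path.join(plots_dir, "threshold_boxplot.png")
    _plot_curves(results, a.threshold, curves_png)
    _plot_boxes(summaries, results, boxes_png)
    files += [curves_png, boxes_png]

    # -- manifest ----------------------------------------------------------
    manifest = {
        "package": "moca",
        "version": _version(),
        "seed": seed,
        "rng": "numpy PCG64 (default_rng)",
        "config": config.model_dump(),
        "files": {os.path.relpath(p, outdir): _sha256(p) for p in sorted(files)},
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "scene": syn,
        "stack": stack,
        "truth": truth,
        "series": series,
        "results": results,
        "summaries": summaries,
        "manifest": manifest,
        "outdir": str(outdir),
    }
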