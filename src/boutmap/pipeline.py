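"""End-to-end pipeline: simulate -> bouts -> preprocess -> windows ->
classify -> cluster -> maps.

One run unit is one trial in one imaging plane.  The configuration is
validated up front; defaults are the experimental parameters (5.81 Hz
imaging, 315 s trials of 10 s motion / 5 s static, classification
threshold 0.6, clustering threshold 0.75 with minimum cluster size 50).
Every stage writes its artifact into the output directory and the run
ends with a manifest (parameters, seed, artifact hashes) sufficient to
reproduce the outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .classify import classify_rois
from .cluster import cluster_traces
from .events import EventWindowSpec, select_stimulus_events, select_swim_events
from .exceptions import BoutmapError
from .kinematics import BoutDetector, bouts_to_frame, read_angle_csv
from .maps import compute_cluster_map, write_map
from .preprocess import (
    BleedthroughCorrector,
    Movie,
    dff,
    extract_roi_traces,
    spatial_mean_filter,
)
from .stimulus import make_schedule
from .synthetic import (
    BoutParams,
    CalciumKernel,
    NoiseParams,
    generate_movie,
    generate_tail_trace,
    make_scene,
    write_simulation,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class ScheduleConfig(BaseModel):
    trial_duration_s: float = Field(315.0, gt=0)
    motion_s: float = Field(10.0, gt=0)
    static_s: float = Field(5.0, gt=0)


class SimulateConfig(BaseModel):
    enabled: bool = True
    frame_shape: tuple[int, int] = (128, 64)
    n_per_archetype: int = Field(8, ge=1)
    bleed_factor: float = Field(0.1, ge=0)
    frame_rate_hz: float = Field(5.81, gt=0)
    behavior_rate_hz: float = Field(250.0, gt=0)
    photon_scale: float = Field(1.0, ge=0)
    read_noise_sd: float = Field(2.0, ge=0)
    blob_sigma_px: float = Field(1.5, gt=0)


class BoutConfig(BaseModel):
    min_amplitude_deg: float = Field(5.0, gt=0)
    min_interpeak_s: float = Field(0.01, gt=0)
    max_intrabout_gap_s: float = Field(0.1, gt=0)
    pad_s: float = Field(0.02, ge=0)
    struggle_amplitude_deg: float = Field(100.0, gt=0)
    nan_fraction: float = Field(0.2, ge=0, le=1)


class WindowConfig(BaseModel):
    swim_pre_s: float = Field(2.0, ge=0)
    swim_post_s: float = Field(5.0, ge=0)
    swim_min_gap_s: float = Field(0.5, ge=0)
    stim_pre_s: float = Field(5.0, ge=0)
    stim_post_s: float = Field(10.0, ge=0)

    def swim_spec(self) -> EventWindowSpec:
        return EventWindowSpec("swim", self.swim_pre_s, self.swim_post_s,
                               self.swim_min_gap_s)

    def stim_spec(self) -> EventWindowSpec:
        return EventWindowSpec("stimulus", self.stim_pre_s, self.stim_post_s)


class PreprocessConfig(BaseModel):
    filter_size_px: int = Field(2, ge=1)
    baseline_method: Literal["sliding_percentile", "global_percentile"] = (
        "sliding_percentile"
    )
    baseline_window_s: float = Field(30.0, gt=0)
    baseline_percentile: float = Field(10.0, gt=0, lt=100)
    correct_bleedthrough: bool = True


class ClassifyConfig(BaseModel):
    threshold: float = Field(0.6, gt=0, le=1)
    method: Literal["pearson", "spearman"] = "pearson"


class ClusterConfig(BaseModel):
    threshold: float = Field(0.75, gt=0, le=1)
    min_size: int = Field(50, ge=1)


class PipelineConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "boutmap_run"
    green_tiff: str | None = None
    red_tiff: str | None = None
    angle_csv: str | None = None
    footprints_npy: str | None = None
    schedule: ScheduleConfig = ScheduleConfig()
    simulate: SimulateConfig = SimulateConfig()
    bouts: BoutConfig = BoutConfig()
    windows: WindowConfig = WindowConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    classify: ClassifyConfig = ClassifyConfig()
    cluster: ClusterConfig = ClusterConfig()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest.

    Any stage failure raises with the stage name attached; artifacts
    written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "artifacts": {},
    }
    stage = "setup"
    try:
        rng = np.random.default_rng(config.seed)
        sched_cfg = config.schedule
        schedule = make_schedule(
            sched_cfg.trial_duration_s, sched_cfg.motion_s, sched_cfg.static_s
        )

        # --- simulate or load inputs -----------------------------------
        stage = "simulate"
        footprints = None
        if config.simulate.enabled:
            sim = config.simulate
            scene = make_scene(
                n_per_archetype=sim.n_per_archetype,
                frame_shape=sim.frame_shape,
                blob_sigma_px=sim.blob_sigma_px,
                bleed_factor=sim.bleed_factor,
                seed=config.seed,
            )
            trace, planted = generate_tail_trace(
                schedule, sim.behavior_rate_hz, BoutParams(), seed=rng
            )
            green, red, _, _ = generate_movie(
                scene,
                schedule,
                planted,
                CalciumKernel(),
                sim.frame_rate_hz,
                NoiseParams(sim.photon_scale, sim.read_noise_sd),
                seed=rng,
            )
            write_simulation(outdir / "simulation", scene, schedule, trace,
                             planted, green, red)
            footprints = scene.footprints
            manifest["stages"]["simulate"] = {
                "n_rois": scene.n_rois,
                "n_planted_bouts": len(planted),
                "archetype_counts": {
                    a: int(sum(x == a for x in scene.archetypes))
                    for a in sorted(set(scene.archetypes))
                },
            }
        else:
            import tifffile

            if config.green_tiff is None or config.angle_csv is None:
                raise BoutmapError(
                    "without simulation, green_tiff and angle_csv are required"
                )
            green = Movie(
                tifffile.imread(config.green_tiff),
                frame_rate_hz=config.simulate.frame_rate_hz,
                channel="green",
            )
            red = None
            if config.red_tiff is not None:
                red = Movie(
                    tifffile.imread(config.red_tiff),
                    frame_rate_hz=green.frame_rate_hz,
                    channel="red",
                )
            trace = read_angle_csv(config.angle_csv)
            if config.footprints_npy is None:
                raise BoutmapError("footprints_npy is required to extract ROI traces")
            footprints = np.load(config.footprints_npy)
            manifest["stages"]["simulate"] = {"skipped": True}

        # --- bout extraction -------------------------------------------
        stage = "bouts"
        detector = BoutDetector(**config.bouts.model_dump())
        bouts = detector.detect(trace)
        bouts_df = bouts_to_frame(bouts)
        bouts_df.to_csv(outdir / "bouts.csv", index=False)
        retained = [b for b in bouts if not b.is_excluded]
        manifest["stages"]["bouts"] = {
            "n_detected": len(bouts),
            "n_retained": len(retained),
        }

        # --- preprocessing ---------------------------------------------
        stage = "preprocess"
        if config.preprocess.correct_bleedthrough and red is not None:
            corrector = BleedthroughCorrector().fit(green, red)
            green_corr = corrector.transform(green, red)
            manifest["stages"]["preprocess"] = {
                "bleed_factor_estimate": corrector.factor_
            }
        else:
            green_corr = green
            manifest["stages"]["preprocess"] = {"bleed_factor_estimate": None}
        filtered = spatial_mean_filter(green_corr, config.preprocess.filter_size_px)
        raw_traces = extract_roi_traces(green_corr, footprints)
        dff_mat = dff(
            raw_traces,
            green.frame_rate_hz,
            method=config.preprocess.baseline_method,
            window_s=config.preprocess.baseline_window_s,
            percentile=config.preprocess.baseline_percentile,
        )
        times = green.times
        pd.DataFrame(
            {"frame": np.arange(times.size), "t_s": times}
            | {f"roi_{i}": dff_mat[i] for i in range(dff_mat.shape[0])}
        ).to_csv(outdir / "roi_dff.csv", index=False)

        # --- event selection -------------------------------------------
        stage = "events"
        swim_spec = config.windows.swim_spec()
        stim_spec = config.windows.stim_spec()
        swim_events = select_swim_events(retained, swim_spec, schedule.trial_duration)
        stim_events = select_stimulus_events(schedule, stim_spec)
        pd.DataFrame({"onset_s": swim_events}).to_csv(
            outdir / "swim_events.csv", index=False
        )
        pd.DataFrame({"onset_s": stim_events}).to_csv(
            outdir / "stimulus_events.csv", index=False
        )
        manifest["stages"]["events"] = {
            "n_swim_events": int(swim_events.size),
            "n_stimulus_events": int(stim_events.size),
        }

        # --- classification --------------------------------------------
        stage = "classify"
        table, swim_sets, stim_sets = classify_rois(
            dff_mat,
            green.frame_rate_hz,
            swim_events,
            stim_events,
            threshold=config.classify.threshold,
            method=config.classify.method,
            swim_spec=swim_spec,
            stim_spec=stim_spec,
        )
        table.to_csv(outdir / "classification.csv", index=False)
        counts = table["category"].value_counts().to_dict()
        manifest["stages"]["classify"] = {"category_counts": counts}

        # --- clustering (each category independently) ------------------
        stage = "cluster"
        all_clusters = []
        for kind, category, sets in (
            ("swim", "swim_driven", swim_sets),
            ("stimulus", "stimulus_driven", stim_sets),
        ):
            ids = table.loc[table["category"] == category, "roi_id"].to_numpy()
            ids = np.asarray([i for i in ids if i in sets])
            if ids.size == 0:
                manifest["stages"].setdefault("cluster", {})[kind] = {"n_clusters": 0}
                continue
            waveforms = np.asarray([sets[i].average for i in ids])
            clusters, labels = cluster_traces(
                waveforms,
                threshold=config.cluster.threshold,
                min_size=config.cluster.min_size,
                event_kind=kind,
                roi_ids=ids,
            )
            pd.DataFrame({"roi_id": ids, "cluster": labels}).to_csv(
                outdir / f"{kind}_cluster_membership.csv", index=False
            )
            if clusters:
                off = sets[ids[0]].offsets_s
                cen_df = pd.DataFrame(
                    [c.centroid for c in clusters],
                    columns=[f"t{o:+.3f}" for o in off],
                )
                cen_df.insert(0, "cluster", [c.cluster_id for c in clusters])
                cen_df.to_csv(outdir / f"{kind}_cluster_centroids.csv", index=False)
            manifest["stages"].setdefault("cluster", {})[kind] = {
                "n_clusters": len(clusters),
                "sizes": [c.n_members for c in clusters],
            }
            all_clusters.extend(clusters)

        # --- pixel maps -------------------------------------------------
        stage = "maps"
        map_summaries = {}
        for c in all_clusters:
            events = swim_events if c.event_kind == "swim" else stim_events
            spec = swim_spec if c.event_kind == "swim" else stim_spec
            cmap = compute_cluster_map(
                filtered, c.centroid, events, spec,
                cluster_id=f"{c.event_kind}_{c.cluster_id}",
            )
            write_map(cmap, outdir / f"map_{c.event_kind}_{c.cluster_id}.tif")
            vals = cmap.values[cmap.defined_mask]
            map_summaries[f"{c.event_kind}_{c.cluster_id}"] = {
                "n_events": cmap.n_events,
                "mean_correlation": float(vals.mean()) if vals.size else None,
            }
        manifest["stages"]["maps"] = map_summaries
    except Exception as exc:
        raise BoutmapError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(outdir))] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
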