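"""End-to-end orchestration: simulate → calibrate → fuse → gait → agree.

The functions here bind the modules into the reproducible runs the CLI
exposes.  A simulated dataset directory contains marker observations,
per-sensor skeleton streams per recording, reference-system trajectories,
optional point clouds, ground-truth sidecars and a manifest; a run
directory contains the calibration, fused series, gait-parameter tables,
agreement tables and a machine-readable run log.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import io as gio
from .agreement import agreement_table, render_table
from .calibration import IcpParams, calibrate, icp_refine
from .config import PipelineConfig, config_hash, save_config
from .fusion import (FusedSeries, fuse, joint_index, resample_streams, smooth,
                     transform_stream)
from .gait import analyze_recording, parameters_frame
from .simulate import (CorruptionModel, GaitCommand, corrupt_streams,
                       default_marker_poses, perfect_sensor, simulate_gait,
                       simulate_marker_observations, simulate_point_clouds,
                       simulate_rig)

__all__ = [
    "build_rig", "subject_commands", "simulate_dataset",
    "fuse_recording", "gait_from_series", "run_pipeline",
]


def build_rig(cfg: PipelineConfig):
    return simulate_rig(n_rows=cfg.n_rows, row_spacing=cfg.row_spacing,
                        corridor_width=cfg.corridor_width,
                        inward_angle=cfg.inward_angle,
                        sensor_height=cfg.sensor_height,
                        frame_rate=cfg.frame_rate)


def subject_commands(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    """One gait command per subject, drawn around the cohort means."""
    commands = {}
    for s in range(cfg.n_subjects):
        commands[f"S{s + 1:02d}"] = GaitCommand(
            step_length=max(0.3, rng.normal(cfg.step_length,
                                            cfg.subject_sd_step_length)),
            step_width=max(0.04, rng.normal(cfg.step_width,
                                            cfg.subject_sd_step_width)),
            cadence=max(40.0, rng.normal(cfg.cadence, cfg.subject_sd_cadence)),
            duty_factor=cfg.duty_factor, n_strides=cfg.n_strides,
            start_foot=cfg.start_foot)
    return commands


def _corruption(cfg: PipelineConfig) -> CorruptionModel:
    return CorruptionModel(
        joint_noise_sigma=cfg.joint_noise_sigma,
        lateral_surface_bias=cfg.lateral_surface_bias,
        occlusion_dropout=cfg.occlusion_dropout,
        occlusion_threshold=cfg.occlusion_threshold,
        timestamp_jitter=cfg.timestamp_jitter,
        frame_rate_wobble=cfg.frame_rate_wobble)


def simulate_dataset(cfg: PipelineConfig, out_dir) -> dict:
    """Write a complete synthetic dataset; returns the manifest."""
    cfg.validate()
    out = gio.ensure_dir(out_dir)
    rng = np.random.default_rng(cfg.seed)
    rig = build_rig(cfg)
    markers = default_marker_poses(cfg.n_markers, cfg.marker_spacing)
    observations, _ = simulate_marker_observations(
        rig, markers, cfg.marker_side, cfg.marker_noise_sigma,
        seed=int(rng.integers(2**31)))
    gio.write_marker_observations(out / "markers.tsv", observations)

    clouds = simulate_point_clouds(rig, density=cfg.cloud_density,
                                   seed=int(rng.integers(2**31)))
    for sid, cloud in sorted(clouds.items()):
        gio.write_point_cloud(out / f"cloud_s{sid}.xyz", cloud)

    commands = subject_commands(cfg, rng)
    corruption = _corruption(cfg)
    ref_sensor = perfect_sensor(sensor_id=99)
    ref_sensor.frame_rate = cfg.reference_rate
    recordings = []
    truth_doc = {}
    for subject, cmd in commands.items():
        for trial in range(cfg.n_trials):
            rec_id = f"{subject}/T{trial + 1:02d}"
            rec_dir = gio.ensure_dir(out / subject / f"T{trial + 1:02d}")
            truth = simulate_gait(cmd)
            streams = corrupt_streams(truth, rig, corruption,
                                      seed=int(rng.integers(2**31)))
            for st in streams:
                gio.write_stream(rec_dir / f"stream_s{st.sensor_id}.tsv", st)
            ref = corrupt_streams(
                truth, [ref_sensor],
                CorruptionModel(joint_noise_sigma=cfg.reference_noise_sigma,
                                lateral_surface_bias=0.0,
                                occlusion_dropout=False,
                                timestamp_jitter=0.0, frame_rate_wobble=0.0),
                seed=int(rng.integers(2**31)))[0]
            gio.write_trajectories(
                rec_dir / "reference.tsv", ref.timestamps,
                {"AnkleLeft": ref.positions[:, joint_index("AnkleLeft"), :],
                 "AnkleRight": ref.positions[:, joint_index("AnkleRight"), :]})
            truth_doc[rec_id] = {
                "step_length_cm": cmd.step_length * 100.0,
                "step_width_cm": cmd.step_width * 100.0,
                "step_time_s": cmd.step_time,
                "stride_length_cm": 2 * cmd.step_length * 100.0,
                "walking_speed_cm_s": cmd.step_length * 100.0 / cmd.step_time,
                "n_events": 2 * cmd.n_strides,
            }
            recordings.append(rec_id)
    manifest = {"config_hash": config_hash(cfg), "seed": cfg.seed,
                "recordings": recordings,
                "sensors": [s.sensor_id for s in rig]}
    save_config(out / "config.yaml", cfg)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _subset_ids(streams, subset: str) -> list:
    if subset == "both":
        return [s.sensor_id for s in streams]
    side = "left" if subset == "left_only" else "right"
    ids = [s.sensor_id for s in streams if s.side_tag == side]
    if not ids:
        raise ValueError(f"no sensors match subset {subset!r}")
    return ids


def fuse_recording(streams, calibration, cfg: PipelineConfig,
                   subset: str | None = None) -> FusedSeries:
    """Transform, resample, average and smooth one recording's streams."""
    subset = subset or cfg.subset
    ids = _subset_ids(streams, subset)
    chosen = [s for s in streams if s.sensor_id in ids]
    global_streams = [transform_stream(s, calibration.transforms[s.sensor_id])
                      for s in chosen]
    gridded = resample_streams(global_streams, rate=cfg.resample_rate,
                               max_gap=cfg.max_gap)
    fused = fuse(gridded)
    return smooth(fused, order=cfg.filter_order, cutoff=cfg.filter_cutoff)


def gait_from_series(series: FusedSeries, cfg: PipelineConfig):
    """Gait extraction from a fused series' ankle trajectories."""
    left, _ = series.joint("AnkleLeft")
    right, _ = series.joint("AnkleRight")
    return analyze_recording(series.grid, left, right,
                             hysteresis=cfg.hysteresis,
                             start_foot=cfg.start_foot)


def gait_from_reference(times, named: dict, cfg: PipelineConfig):
    """Same procedure on reference-system marker trajectories.

    The (typically 120 Hz) trajectories are linearly resampled onto the
    pipeline's uniform grid and smoothed with the same zero-phase filter
    before event detection.
    """
    grid_n = int(np.floor((times[-1] - times[0]) * cfg.resample_rate)) + 1
    grid = times[0] + np.arange(grid_n) / cfg.resample_rate
    ankles = {}
    for key in ("AnkleLeft", "AnkleRight"):
        arr = np.asarray(named[key], float)
        res = np.column_stack([np.interp(grid, times, arr[:, i])
                               for i in range(3)])
        ankles[key] = res
    # pack into a FusedSeries so the identical smoothing path applies
    from .fusion import N_JOINTS, joint_index
    pos = np.full((grid_n, N_JOINTS, 3), np.nan)
    valid = np.zeros((grid_n, N_JOINTS), dtype=bool)
    for key in ankles:
        j = joint_index(key)
        pos[:, j, :] = ankles[key]
        valid[:, j] = True
    series = smooth(FusedSeries(grid, pos, valid),
                    order=cfg.filter_order, cutoff=cfg.filter_cutoff)
    return gait_from_series(series, cfg)


def run_pipeline(dataset_dir, cfg: PipelineConfig, out_dir,
                 subsets=("both",)) -> dict:
    """Calibrate, fuse (per subset), extract gait and compare to reference.

    Writes per-subset gait-parameter CSVs, agreement tables (CSV + aligned
    text) and a run log counting every exclusion and warning.
    """
    import warnings as _warnings
    from pathlib import Path

    cfg.validate()
    ds = Path(dataset_dir)
    out = gio.ensure_dir(out_dir)
    log: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed,
                 "warnings": [], "counts": {}}

    observations = gio.read_marker_observations(ds / "markers.tsv")
    from .calibration import square_marker_template
    templates = {mid: square_marker_template(mid, cfg.marker_side)
                 for mid in sorted({o.marker_id for o in observations})}
    calib = calibrate(observations, templates, cfg.origin_marker_id)
    if cfg.use_icp:
        clouds = {}
        for f in sorted(ds.glob("cloud_s*.xyz")):
            sid = int(f.stem.split("_s")[1])
            clouds[sid] = gio.read_point_cloud(f)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            calib = icp_refine(clouds, calib, IcpParams(),
                               rng=np.random.default_rng(cfg.seed))
        log["warnings"] += [str(w.message) for w in caught]
    gio.write_calibration(out / "calibration.yaml", calib)

    with open(ds / "manifest.json") as fh:
        manifest = json.load(fh)

    ref_frames = []
    subset_frames: dict = {s: [] for s in subsets}
    n_dropped_events = 0
    for rec_id in manifest["recordings"]:
        rec_dir = ds / rec_id
        streams = [gio.read_stream(f)
                   for f in sorted(rec_dir.glob("stream_s*.tsv"),
                                   key=lambda p: int(p.stem.split("_s")[1]))]
        for subset in subsets:
            fused = fuse_recording(streams, calib, cfg, subset=subset)
            gio.write_fused(out / f"fused_{rec_id.replace('/', '_')}_{subset}.tsv",
                            fused)
            steps, strides, summary, placements = gait_from_series(fused, cfg)
            n_dropped_events += sum(p.flagged for p in placements)
            subset_frames[subset].append(parameters_frame(
                rec_id, "rig", subset, steps, strides, summary))
        t_ref, named = gio.read_trajectories(rec_dir / "reference.tsv")
        steps, strides, summary, _ = gait_from_reference(t_ref, named, cfg)
        ref_frames.append(parameters_frame(rec_id, "reference", "n/a",
                                           steps, strides, summary))

    params_ref = pd.concat(ref_frames, ignore_index=True)
    params_ref.to_csv(out / "gait_reference.csv", index=False)
    tables = {}
    for subset in subsets:
        params = pd.concat(subset_frames[subset], ignore_index=True)
        params.to_csv(out / f"gait_rig_{subset}.csv", index=False)
        table = agreement_table(params, params_ref,
                                max_time_offset=cfg.max_gap)
        table.to_csv(out / f"agreement_{subset}.csv", index=False)
        with open(out / f"agreement_{subset}.txt", "w") as fh:
            fh.write(render_table(table) + "\n")
        tables[subset] = table
    log["counts"] = {
        "recordings": len(manifest["recordings"]),
        "flagged_placements": n_dropped_events,
        "reference_steps": int((params_ref["parameter"] == "step_length").sum()),
    }
    log["excluded_per_recording"] = "first left step and first right stride"
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return {"calibration": calib, "tables": tables, "log": log,
            "params_reference": params_ref,
            "params_rig": {s: pd.concat(subset_frames[s], ignore_index=True)
                           for s in subsets}}
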