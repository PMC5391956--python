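"""Plain-text readers and writers for every pipeline artifact.

All formats are line-oriented text so datasets remain inspectable and
diffable: tab-separated tables for streams and trajectories, XYZ text for
point clouds, YAML for calibration results and sidecar metadata, CSV for
gait-parameter and agreement tables.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult, MarkerObservation
from .fusion import JOINT_NAMES, N_JOINTS, FusedSeries, SensorStream
from .transforms import RigidTransform

__all__ = [
    "write_marker_observations", "read_marker_observations",
    "write_calibration", "read_calibration",
    "write_point_cloud", "read_point_cloud",
    "write_stream", "read_stream",
    "write_fused", "read_fused",
    "write_trajectories", "read_trajectories",
]


# --- marker observations ---------------------------------------------------

def write_marker_observations(path, observations) -> None:
    """One row per corner: sensor_id, marker_id, frame, corner, x, y, z (m).

    ``frame`` numbers repeated observations of the same (sensor, marker)
    pair, preserving the corner correspondence of each capture frame.
    """
    frame_counter: dict = {}
    with open(path, "w") as fh:
        fh.write("sensor_id\tmarker_id\tframe\tcorner\tx\ty\tz\n")
        for obs in observations:
            key = (obs.sensor_id, obs.marker_id)
            frame = frame_counter.get(key, 0)
            frame_counter[key] = frame + 1
            for i, (x, y, z) in enumerate(obs.corner_points):
                fh.write(f"{obs.sensor_id}\t{obs.marker_id}\t{frame}\t{i}"
                         f"\t{x:.9f}\t{y:.9f}\t{z:.9f}\n")


def read_marker_observations(path) -> list[MarkerObservation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sid, mid, _), grp in df.groupby(["sensor_id", "marker_id", "frame"],
                                         sort=True):
        grp = grp.sort_values("corner")
        out.append(MarkerObservation(int(sid), int(mid),
                                     grp[["x", "y", "z"]].to_numpy()))
    return out


# --- calibration -----------------------------------------------------------

def write_calibration(path, result: CalibrationResult) -> None:
    doc = {
        "origin_marker_id": int(result.origin_marker_id),
        "frame_convention": result.frame_convention,
        "refined": bool(result.refined),
        "sensors": {},
    }
    for sid in result.sensor_ids():
        tf = result.transforms[sid]
        doc["sensors"][int(sid)] = {
            "quaternion_xyzw": [float(v) for v in tf.as_quaternion()],
            "translation_m": [float(v) for v in tf.translation],
            "path": [f"{kind}:{ident}" for kind, ident in result.paths[sid]],
            "rms_residual_m": float(result.residuals[sid]),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_calibration(path) -> CalibrationResult:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    transforms, paths, residuals = {}, {}, {}
    for sid, entry in doc["sensors"].items():
        sid = int(sid)
        transforms[sid] = RigidTransform.from_quaternion(
            entry["quaternion_xyzw"], entry["translation_m"])
        paths[sid] = [tuple([p.split(":")[0],
                             int(p.split(":")[1])]) for p in entry["path"]]
        residuals[sid] = float(entry["rms_residual_m"])
    return CalibrationResult(transforms, paths, residuals,
                             int(doc["origin_marker_id"]),
                             refined=bool(doc["refined"]),
                             frame_convention=doc["frame_convention"])


# --- point clouds ----------------------------------------------------------

def write_point_cloud(path, points: np.ndarray) -> None:
    np.savetxt(path, np.asarray(points, float), fmt="%.6f")


def read_point_cloud(path) -> np.ndarray:
    pts = np.loadtxt(path)
    return pts.reshape(-1, 3)


# --- skeleton streams ------------------------------------------------------

def write_stream(path, stream: SensorStream, sidecar: bool = True) -> None:
    """Tab-separated: timestamp_s, body_id, then 25 × (x, y, z, state);
    sensor identity and side go to a ``<path>.meta.yaml`` sidecar."""
    cols = ["timestamp_s", "body_id"]
    for name in JOINT_NAMES:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z", f"{name}_state"]
    n = len(stream.timestamps)
    data = np.empty((n, 2 + 4 * N_JOINTS))
    data[:, 0] = stream.timestamps
    data[:, 1] = stream.body_id
    data[:, 2::4] = stream.positions[..., 0]
    data[:, 3::4] = stream.positions[..., 1]
    data[:, 4::4] = stream.positions[..., 2]
    data[:, 5::4] = stream.states
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.9g")
    if sidecar:
        with open(f"{path}.meta.yaml", "w") as fh:
            yaml.safe_dump({"sensor_id": int(stream.sensor_id),
                            "side_tag": stream.side_tag}, fh)


def read_stream(path) -> SensorStream:
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    raw = df.to_numpy(dtype=float)
    positions = np.empty((n, N_JOINTS, 3))
    positions[..., 0] = raw[:, 2::4]
    positions[..., 1] = raw[:, 3::4]
    positions[..., 2] = raw[:, 4::4]
    states = raw[:, 5::4].astype(int)
    meta_path = f"{path}.meta.yaml"
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
    else:
        meta = {"sensor_id": 0, "side_tag": "left"}
    return SensorStream(int(meta["sensor_id"]), meta["side_tag"],
                        raw[:, 0], positions, states,
                        body_id=int(raw[0, 1]) if n else 0)


# --- fused series ----------------------------------------------------------

def write_fused(path, series: FusedSeries) -> None:
    cols = ["timestamp_s"]
    for name in JOINT_NAMES:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z", f"{name}_valid",
                 f"{name}_count"]
    n = len(series.grid)
    data = np.empty((n, 1 + 5 * N_JOINTS))
    data[:, 0] = series.grid
    data[:, 1::5] = np.where(series.valid, series.positions[..., 0], np.nan)
    data[:, 2::5] = np.where(series.valid, series.positions[..., 1], np.nan)
    data[:, 3::5] = np.where(series.valid, series.positions[..., 2], np.nan)
    data[:, 4::5] = series.valid
    data[:, 5::5] = series.count
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.9g")


def read_fused(path) -> FusedSeries:
    raw = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    n = raw.shape[0]
    positions = np.empty((n, N_JOINTS, 3))
    positions[..., 0] = raw[:, 1::5]
    positions[..., 1] = raw[:, 2::5]
    positions[..., 2] = raw[:, 3::5]
    valid = raw[:, 4::5] > 0.5
    count = raw[:, 5::5].astype(int)
    return FusedSeries(raw[:, 0], positions, valid, count)


# --- generic labeled trajectories (reference-system input) -----------------

def write_trajectories(path, times: np.ndarray, named: dict) -> None:
    """Tab-separated: timestamp_s plus ``<name>_x/_y/_z`` per trajectory."""
    cols, arrays = ["timestamp_s"], [np.asarray(times, float)]
    for name, arr in named.items():
        arr = np.asarray(arr, float)
        for i, ax in enumerate("xyz"):
            cols.append(f"{name}_{ax}")
            arrays.append(arr[:, i])
    pd.DataFrame(dict(zip(cols, arrays))).to_csv(path, sep="\t", index=False,
                                                 float_format="%.9g")


def read_trajectories(path) -> tuple[np.ndarray, dict]:
    df = pd.read_csv(path, sep="\t")
    times = df["timestamp_s"].to_numpy(dtype=float)
    named = {}
    for col in df.columns:
        if col.endswith("_x"):
            base = col[:-2]
            named[base] = df[[f"{base}_x", f"{base}_y", f"{base}_z"]].to_numpy(
                dtype=float)
    return times, named


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
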