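"""Fusing per-sensor skeleton streams into one global-frame skeleton.

Each depth sensor delivers 25-joint skeleton frames at a slightly varying
rate near 30 Hz, in its own coordinate frame, with a per-joint tracking
state.  Fusion proceeds in four steps that mirror the acquisition
pipeline: (1) map every stream into the global frame with the calibrated
sensor pose, (2) resample each stream onto a uniform 30 Hz grid by linear
interpolation, treating non-tracked joints as missing, (3) average the
sensors with equal weights per joint and grid sample, and (4) low-pass
filter the fused trajectories with a zero-phase Butterworth filter.

Streams are stored as arrays: timestamps ``(n,)``, joint positions
``(n, 25, 3)`` and integer tracking states ``(n, 25)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .transforms import RigidTransform

__all__ = [
    "JOINT_NAMES", "TRACKED", "INFERRED", "UNTRACKED",
    "SensorStream", "FusedSeries",
    "transform_stream", "resample_uniform", "fuse", "smooth",
]

#: Kinect v2 joint order (fixed across all files and arrays).
JOINT_NAMES = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)
N_JOINTS = len(JOINT_NAMES)

TRACKED, INFERRED, UNTRACKED = 2, 1, 0
STATE_NAMES = {TRACKED: "tracked", INFERRED: "inferred", UNTRACKED: "untracked"}


def joint_index(name: str) -> int:
    return JOINT_NAMES.index(name)


@dataclass
class SensorStream:
    """Timestamped 25-joint samples from one sensor.

    ``side_tag`` records the sensor's placement relative to the walking
    direction ({"left", "right"}); it drives the subset selection for
    one-sided versus two-sided reconstruction.
    """

    sensor_id: int
    side_tag: str
    timestamps: np.ndarray           # (n,) seconds, strictly increasing
    positions: np.ndarray            # (n, 25, 3) meters
    states: np.ndarray               # (n, 25) in {TRACKED, INFERRED, UNTRACKED}
    body_id: int = 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.positions = np.asarray(self.positions, float)
        self.states = np.asarray(self.states, int)
        n = self.timestamps.shape[0]
        if self.positions.shape != (n, N_JOINTS, 3):
            raise ValueError(f"positions must be (n, {N_JOINTS}, 3)")
        if self.states.shape != (n, N_JOINTS):
            raise ValueError(f"states must be (n, {N_JOINTS})")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.side_tag not in ("left", "right"):
            raise ValueError("side_tag must be 'left' or 'right'")


@dataclass
class FusedSeries:
    """Uniform-rate global-frame joint trajectories with validity masks."""

    grid: np.ndarray                 # (T,) uniform timestamps
    positions: np.ndarray            # (T, 25, 3); NaN where invalid
    valid: np.ndarray                # (T, 25) bool
    count: np.ndarray = field(default=None)  # (T, 25) contributing sensors

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.positions = np.asarray(self.positions, float)
        self.valid = np.asarray(self.valid, bool)
        if self.count is None:
            self.count = self.valid.astype(int)
        if len(self.grid) > 1:
            dt = np.diff(self.grid)
            if not np.allclose(dt, dt[0], atol=1e-9):
                raise ValueError("grid spacing must be uniform")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.diff(self.grid[:2])[0])

    def joint(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions (T, 3), valid (T,)) for a named joint."""
        j = joint_index(name)
        return self.positions[:, j, :], self.valid[:, j]


def transform_stream(stream: SensorStream, pose: RigidTransform) -> SensorStream:
    """Map every joint position by ``pose``; states and timestamps unchanged."""
    return replace(stream, positions=pose.apply(stream.positions))


def resample_uniform(stream: SensorStream, rate: float = 30.0,
                     max_gap: float = 0.2,
                     grid: np.ndarray | None = None) -> FusedSeries:
    """Linear-interpolation resampling of one stream onto a uniform grid.

    A grid sample of a joint is valid only when both flanking raw frames
    have state ``tracked`` and are no more than ``max_gap`` seconds apart;
    inferred joints count as missing, since inferred positions are not
    trusted for gait analysis.
    """
    t = stream.timestamps
    if len(t) < 2:
        raise ValueError("resampling needs at least 2 frames")
    if grid is None:
        n = int(np.floor((t[-1] - t[0]) * rate)) + 1
        grid = t[0] + np.arange(n) / rate
    else:
        grid = np.asarray(grid, float)

    # Flanking raw-frame indices for every grid point.
    right = np.searchsorted(t, grid, side="left")
    right = np.clip(right, 1, len(t) - 1)
    left = right - 1
    in_range = (grid >= t[0] - 1e-12) & (grid <= t[-1] + 1e-12)
    dt = t[right] - t[left]
    w = np.clip((grid - t[left]) / dt, 0.0, 1.0)

    pos = ((1.0 - w)[:, None, None] * stream.positions[left]
           + w[:, None, None] * stream.positions[right])
    both_tracked = ((stream.states[left] == TRACKED)
                    & (stream.states[right] == TRACKED))
    valid = both_tracked & (dt[:, None] <= max_gap) & in_range[:, None]
    pos[~valid] = np.nan
    return FusedSeries(grid, pos, valid)


def fuse(gridded: list[FusedSeries], subset: list | None = None,
         sensor_ids: list | None = None) -> FusedSeries:
    """Equal-weight average of gridded streams on their common grid range.

    Parameters
    ----------
    gridded:
        Per-sensor resampled series; all grids must share rate and phase.
    subset, sensor_ids:
        With ``sensor_ids`` giving the id of each series, ``subset``
        restricts fusion to those ids (one-sided vs two-sided
        reconstruction); by default all series are used.
    """
    if subset is not None:
        if sensor_ids is None:
            raise ValueError("subset selection requires sensor_ids")
        keep = [g for g, sid in zip(gridded, sensor_ids) if sid in subset]
    else:
        keep = list(gridded)
    if not keep:
        raise ValueError("no streams selected for fusion")

    step = float(np.diff(keep[0].grid[:2])[0]) if len(keep[0].grid) > 1 else 1.0 / 30.0
    start = max(g.grid[0] for g in keep)
    stop = min(g.grid[-1] for g in keep)
    if stop < start - 1e-12:
        raise ValueError("streams have no common time range")
    # Align every series onto the intersected grid (grids share rate/phase).
    n = int(round((stop - start) / step)) + 1
    grid = start + np.arange(n) * step

    total = np.zeros((n, N_JOINTS, 3))
    count = np.zeros((n, N_JOINTS), dtype=int)
    for g in keep:
        offset = int(round((start - g.grid[0]) / step))
        if not np.allclose(g.grid[offset:offset + n], grid, atol=1e-9):
            raise ValueError("streams are not on a common grid")
        v = g.valid[offset:offset + n]
        p = np.where(v[..., None], g.positions[offset:offset + n], 0.0)
        total += p
        count += v
    valid = count > 0
    with np.errstate(invalid="ignore"):
        mean = total / count[..., None]
    mean[~valid] = np.nan
    return FusedSeries(grid, mean, valid, count)


def resample_streams(streams: list[SensorStream], rate: float = 30.0,
                     max_gap: float = 0.2) -> list[FusedSeries]:
    """Resample several streams onto one shared grid.

    The grid is anchored at the latest stream start (the intersection of
    the time ranges) and spans to the earliest stream end, so the phases of
    all resampled series agree exactly.
    """
    if not streams:
        raise ValueError("no streams given")
    start = max(s.timestamps[0] for s in streams)
    stop = min(s.timestamps[-1] for s in streams)
    if stop <= start:
        raise ValueError("streams have no common time range")
    n = int(np.floor((stop - start) * rate)) + 1
    grid = start + np.arange(n) / rate
    return [resample_uniform(s, rate=rate, max_gap=max_gap, grid=grid)
            for s in streams]


def butterworth_gain(freq_hz: float, cutoff_hz: float, order: int) -> float:
    """Analytic amplitude response of the zero-phase Butterworth filter.

    Forward-backward filtering applies the magnitude response twice, hence
    ``|H|² = (1 + (f/fc)^(2·order))⁻¹``.
    """
    return 1.0 / (1.0 + (freq_hz / cutoff_hz) ** (2 * order))


def smooth(series: FusedSeries, order: int = 4, cutoff: float = 6.0) -> FusedSeries:
    """Zero-phase Butterworth low-pass, per coordinate and valid segment.

    Contiguous valid segments shorter than three times the filter's
    effective length (``3·(order+1)`` samples) pass through unchanged; the
    validity mask is never altered by smoothing.
    """
    rate = series.rate
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({rate / 2} Hz)")
    b, a = signal.butter(order, cutoff, fs=rate)
    min_len = 3 * (order + 1)
    out = series.positions.copy()
    for j in range(N_JOINTS):
        v = series.valid[:, j]
        if not v.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], v.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s <= min_len:
                continue
            seg = series.positions[s:e, j, :]
            out[s:e, j, :] = signal.filtfilt(
                b, a, seg, axis=0, padlen=min(3 * (order + 1), e - s - 1))
    return FusedSeries(series.grid, out, series.valid.copy(), series.count.copy())
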