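"""Spatiotemporal gait parameters from ankle trajectories.

The five parameters — step length, step width, step time, stride length
and walking speed — are derived from the two ankle trajectories alone,
identically for the fused markerless skeleton and for a reference optical
system.  The chain is: estimate the walking frame (forward/lateral axes),
detect the events where one foot passes the other (crossings of the
forward ankle positions), read one foot placement per event from the
stance ankle, and difference consecutive placements.

Foot assignment follows the convention that a parameter belongs to the
foot last placed on the floor, and — because subjects start walking with
the left foot, making the first left step an acceleration artifact — the
first left step and the first right stride are excluded from all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WalkFrameAxes", "FootEvent", "FootPlacement",
    "StepRecord", "StrideRecord", "RecordingSummary",
    "estimate_axes", "detect_crossings", "extract_placements",
    "compute_parameters", "analyze_recording",
]

M_TO_CM = 100.0


@dataclass(frozen=True)
class WalkFrameAxes:
    """Horizontal walking frame: forward along the walk, lateral to its left."""

    forward: np.ndarray
    lateral: np.ndarray
    origin: np.ndarray

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(forward, lateral) coordinates of points of shape (..., 3)."""
        rel = np.asarray(points, float) - self.origin
        return rel @ self.forward, rel @ self.lateral

    def to_global(self, fwd, lat) -> np.ndarray:
        """Horizontal global position(s) from walk-frame coordinates."""
        return (self.origin + np.multiply.outer(np.asarray(fwd, float), self.forward)
                + np.multiply.outer(np.asarray(lat, float), self.lateral))


@dataclass(frozen=True)
class FootEvent:
    """One foot passing the other in walking direction."""

    time: float
    passing_foot: str   # "L" or "R" — the swinging foot
    stance_foot: str    # the other foot
    slope: float = 0.0  # |d/dt (left_fwd - right_fwd)| at the event


@dataclass(frozen=True)
class FootPlacement:
    foot: str
    time: float
    forward_pos: float  # m
    lateral_pos: float  # m
    flagged: bool = False


@dataclass(frozen=True)
class StepRecord:
    foot: str
    time: float
    step_length: float  # cm
    step_width: float   # cm
    step_time: float    # s


@dataclass(frozen=True)
class StrideRecord:
    foot: str
    time: float
    stride_length: float  # cm


@dataclass
class RecordingSummary:
    walking_speed: float                  # cm/s
    n_steps: dict = field(default_factory=dict)
    n_strides: dict = field(default_factory=dict)
    mean_step_length: dict = field(default_factory=dict)   # per foot, cm
    mean_step_width: dict = field(default_factory=dict)    # per foot, cm
    mean_step_time: dict = field(default_factory=dict)     # per foot, s
    mean_stride_length: dict = field(default_factory=dict)  # per foot, cm
    excluded: dict = field(default_factory=dict)


def estimate_axes(left_ankle: np.ndarray, right_ankle: np.ndarray,
                  vertical=(0.0, 0.0, 1.0),
                  min_displacement: float = 1.0) -> WalkFrameAxes:
    """Walking frame from the net horizontal mid-ankle displacement.

    ``forward`` is the unit horizontal direction of the total displacement
    of the mid-ankle trajectory; ``lateral = vertical × forward`` (points
    to the walker's left for a Z-up frame).  NaN samples are ignored.
    """
    v = np.asarray(vertical, float)
    v = v / np.linalg.norm(v)
    mid = (np.asarray(left_ankle, float) + np.asarray(right_ankle, float)) / 2.0
    ok = np.all(np.isfinite(mid), axis=1)
    if ok.sum() < 2:
        raise ValueError("not enough valid samples to estimate axes")
    mid = mid[ok]
    disp = mid[-1] - mid[0]
    disp_h = disp - (disp @ v) * v
    norm = np.linalg.norm(disp_h)
    if norm < min_displacement:
        raise ValueError(
            f"net horizontal displacement {norm:.3f} m is below the "
            f"{min_displacement} m minimum; cannot define a walking direction")
    forward = disp_h / norm
    lateral = np.cross(v, forward)
    lateral /= np.linalg.norm(lateral)
    return WalkFrameAxes(forward, lateral, mid[0])


def _central_velocity(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    vel = np.full_like(x, np.nan)
    if len(x) >= 3:
        vel[1:-1] = (x[2:] - x[:-2]) / (t[2:] - t[:-2])
    if len(x) >= 2:
        vel[0] = (x[1] - x[0]) / (t[1] - t[0])
        vel[-1] = (x[-1] - x[-2]) / (t[-1] - t[-2])
    return vel


def detect_crossings(times: np.ndarray, left_fwd: np.ndarray,
                     right_fwd: np.ndarray,
                     hysteresis: float = 0.02,
                     zero_tol: float = 1e-12) -> list[FootEvent]:
    """Events where one ankle passes the other in walking direction.

    The difference ``d = left_fwd − right_fwd`` is scanned for zero
    crossings; the event time is the linear sub-sample interpolation of the
    zero.  After an event, a new one is accepted only once ``|d|`` has
    exceeded ``hysteresis`` (meters), which suppresses chatter from noise
    around a true crossing.  A terminal return of ``d`` exactly to zero
    counts as an event; leading zeros (no established sign yet) do not.

    The passing foot is the one with the larger forward speed magnitude at
    the event (central differences); the other foot is in stance.
    """
    t = np.asarray(times, float)
    d = np.asarray(left_fwd, float) - np.asarray(right_fwd, float)
    ok = np.isfinite(d)
    t, d = t[ok], d[ok]
    lv = _central_velocity(np.asarray(left_fwd, float)[ok], t)
    rv = _central_velocity(np.asarray(right_fwd, float)[ok], t)
    if len(t) < 2:
        raise ValueError("no valid overlap between the ankle trajectories")
    if hysteresis < 0:
        raise ValueError("hysteresis must be non-negative")

    # Schmitt trigger: hold the sign last confirmed beyond the hysteresis
    # band; when d crosses zero, keep the first crossing pending and confirm
    # it as an event only once |d| exceeds the band on the opposite side.
    # Chatter inside the band therefore collapses into one event, and an
    # event can never swallow the next genuine crossing.
    events: list[FootEvent] = []
    state = 0                 # confirmed sign of d, 0 before the first band exit
    pending: tuple | None = None   # (tc, i_left, i_right) of the first crossing

    def cross_time(i):
        t0, t1, d0, d1 = t[i - 1], t[i], d[i - 1], d[i]
        if d1 == d0:
            return t0
        return t0 + (0.0 - d0) * (t1 - t0) / (d1 - d0)

    def emit(tc, i):
        frac = 0.0 if t[i] == t[i - 1] else (tc - t[i - 1]) / (t[i] - t[i - 1])
        lv_c = lv[i - 1] + frac * (lv[i] - lv[i - 1])
        rv_c = rv[i - 1] + frac * (rv[i] - rv[i - 1])
        events.append(_make_event(tc, lv_c, rv_c, d[i - 1], d[i],
                                  t[i - 1], t[i], t, lv, rv))

    for i in range(len(t)):
        di = d[i]
        zi = abs(di) <= zero_tol
        si = 0 if zi else (1 if di > 0 else -1)
        if state == 0:
            if si != 0 and abs(di) > hysteresis:
                state = si
            continue
        if zi and pending is None:
            # d returned exactly to zero after holding a sign: a touch event
            emit(t[i], max(i, 1))
            state = 0
            continue
        if si != 0 and si != state:
            if pending is None:
                pending = (cross_time(i), i)
            if abs(di) > hysteresis:
                emit(*pending)
                state = si
                pending = None
        elif si == state and abs(di) > hysteresis:
            pending = None        # chatter returned into the held sign
    return events


def _make_event(tc, lv_c, rv_c, d0, d1, t0, t1, t, lv, rv) -> FootEvent:
    slope = abs((d1 - d0) / (t1 - t0)) if t1 > t0 else 0.0
    if np.isfinite(lv_c) and np.isfinite(rv_c) and not np.isclose(
            abs(lv_c), abs(rv_c), rtol=1e-9, atol=1e-12):
        passing = "L" if abs(lv_c) > abs(rv_c) else "R"
    else:
        # Degenerate tie: the stance foot is the quieter one — smaller
        # forward-velocity variance over ±100 ms around the event.
        win = (t >= tc - 0.1) & (t <= tc + 0.1)
        var_l = np.nanvar(lv[win]) if win.any() else 0.0
        var_r = np.nanvar(rv[win]) if win.any() else 0.0
        passing = "L" if var_l >= var_r else "R"
    stance = "R" if passing == "L" else "L"
    return FootEvent(float(tc), passing, stance, float(slope))


def _interp_at(t: np.ndarray, y: np.ndarray, when: float) -> float:
    ok = np.isfinite(y)
    if not ok.any():
        return float("nan")
    return float(np.interp(when, t[ok], y[ok]))


def extract_placements(events: list[FootEvent], times: np.ndarray,
                       left_ankle_fl: tuple[np.ndarray, np.ndarray],
                       right_ankle_fl: tuple[np.ndarray, np.ndarray],
                       ) -> list[FootPlacement]:
    """One foot placement per crossing event.

    The placement is the stance ankle's (forward, lateral) position at the
    event time — during stance the forward position is a plateau, so this
    reads the footfall position.  Missing samples at the event time are
    bridged by interpolation over the valid neighbours.  If two
    consecutive events share a stance foot (a data-quality defect), the
    weaker event — the one whose crossing slope |d'| is smaller — is
    dropped and the kept placement flagged.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events to extract placements")
    t = np.asarray(times, float)
    lf, ll = (np.asarray(a, float) for a in left_ankle_fl)
    rf, rl = (np.asarray(a, float) for a in right_ankle_fl)

    kept: list[FootEvent] = []
    for ev in events:
        if kept and ev.stance_foot == kept[-1].stance_foot:
            if ev.slope > kept[-1].slope:   # keep the stronger crossing
                kept[-1] = ev
            continue
        kept.append(ev)
    if len({e.stance_foot for e in kept}) < 2:
        raise ValueError("all events share one stance foot; no alternation")

    placements = []
    dropped = len(events) - len(kept)
    for ev in kept:
        if ev.stance_foot == "L":
            fwd, lat = _interp_at(t, lf, ev.time), _interp_at(t, ll, ev.time)
        else:
            fwd, lat = _interp_at(t, rf, ev.time), _interp_at(t, rl, ev.time)
        placements.append(FootPlacement(ev.stance_foot, ev.time, fwd, lat,
                                        flagged=dropped > 0))
    return placements


def compute_parameters(placements: list[FootPlacement],
                       start_foot: str = "L",
                       ) -> tuple[list[StepRecord], list[StrideRecord],
                                  RecordingSummary]:
    """Steps, strides and the recording summary from foot placements.

    For consecutive placements ``p_{k-1}, p_k`` the step belongs to the
    foot of ``p_k``: step length is the forward advance, step width the
    unsigned lateral separation, step time the elapsed time.  Stride
    length is the forward distance between consecutive same-foot
    placements.  With ``start_foot="L"`` the first left step and the first
    right stride are removed from every output, and the walking speed is
    the sum of the included step lengths over the sum of the included step
    times.  Lengths are reported in cm, times in s, speed in cm/s.
    """
    if len(placements) < 3:
        raise ValueError("need at least 3 placements")
    feet = [p.foot for p in placements]
    for a, b in zip(feet[:-1], feet[1:]):
        if a == b:
            raise ValueError("placements must alternate feet")
    if start_foot not in ("L", "R"):
        raise ValueError("start_foot must be 'L' or 'R'")

    steps = [StepRecord(b.foot, b.time,
                        (b.forward_pos - a.forward_pos) * M_TO_CM,
                        abs(b.lateral_pos - a.lateral_pos) * M_TO_CM,
                        b.time - a.time)
             for a, b in zip(placements[:-1], placements[1:])]
    strides = []
    for foot in ("L", "R"):
        own = [p for p in placements if p.foot == foot]
        strides += [StrideRecord(foot, b.time,
                                 (b.forward_pos - a.forward_pos) * M_TO_CM)
                    for a, b in zip(own[:-1], own[1:])]
    strides.sort(key=lambda s: s.time)

    excluded = {"first_step": None, "first_stride": None}
    first_step_foot = start_foot
    first_stride_foot = "R" if start_foot == "L" else "L"
    for i, s in enumerate(steps):
        if s.foot == first_step_foot:
            excluded["first_step"] = steps.pop(i)
            break
    for i, s in enumerate(strides):
        if s.foot == first_stride_foot:
            excluded["first_stride"] = strides.pop(i)
            break
    if not steps:
        raise ValueError("no steps remain after the exclusion rule")

    total_len = sum(s.step_length for s in steps)
    total_time = sum(s.step_time for s in steps)
    summary = RecordingSummary(walking_speed=total_len / total_time,
                               excluded=excluded)
    for foot in ("L", "R"):
        fs = [s for s in steps if s.foot == foot]
        fr = [s for s in strides if s.foot == foot]
        summary.n_steps[foot] = len(fs)
        summary.n_strides[foot] = len(fr)
        if fs:
            summary.mean_step_length[foot] = float(np.mean([s.step_length for s in fs]))
            summary.mean_step_width[foot] = float(np.mean([s.step_width for s in fs]))
            summary.mean_step_time[foot] = float(np.mean([s.step_time for s in fs]))
        if fr:
            summary.mean_stride_length[foot] = float(np.mean([s.stride_length for s in fr]))
    return steps, strides, summary


def analyze_recording(times: np.ndarray, left_ankle: np.ndarray,
                      right_ankle: np.ndarray,
                      vertical=(0.0, 0.0, 1.0),
                      hysteresis: float = 0.02,
                      start_foot: str = "L",
                      ) -> tuple[list[StepRecord], list[StrideRecord],
                                 RecordingSummary, list[FootPlacement]]:
    """End-to-end gait extraction from two 3-D ankle trajectories (meters).

    Invalid samples are NaN.  Works identically for the fused markerless
    skeleton and for resampled reference-system marker trajectories.
    """
    axes = estimate_axes(left_ankle, right_ankle, vertical)
    lf, ll = axes.project(left_ankle)
    rf, rl = axes.project(right_ankle)
    events = detect_crossings(times, lf, rf, hysteresis=hysteresis)
    placements = extract_placements(events, times, (lf, ll), (rf, rl))
    steps, strides, summary = compute_parameters(placements, start_foot)
    return steps, strides, summary, placements


def parameters_frame(recording_id, system: str, sides_used: str,
                     steps: list[StepRecord], strides: list[StrideRecord],
                     summary: RecordingSummary) -> pd.DataFrame:
    """Long-format gait-parameter table: one row per step/stride value."""
    rows = []
    for s in steps:
        for name, value in (("step_length", s.step_length),
                            ("step_width", s.step_width),
                            ("step_time", s.step_time)):
            rows.append((recording_id, system, sides_used, s.foot,
                         name, value, s.time))
    for s in strides:
        rows.append((recording_id, system, sides_used, s.foot,
                     "stride_length", s.stride_length, s.time))
    rows.append((recording_id, system, sides_used, "both",
                 "walking_speed", summary.walking_speed, np.nan))
    return pd.DataFrame(rows, columns=["recording_id", "system", "sides_used",
                                       "foot", "parameter", "value", "time"])
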