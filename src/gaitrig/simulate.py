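"""Synthetic multi-sensor gait data with known ground truth.

Everything the pipeline consumes can be generated here: a corridor rig of
paired depth sensors (default: rows 2.5 m apart along the walk, 2 m wide,
rotated inward by 35°, 70°×60° field of view, 0.5–4.5 m depth range),
floor markers for the extrinsic calibration, point clouds for ICP, and
multi-sensor skeleton streams of a parameterized walker.

The walker is a 25-joint stick figure driven by the ankles: each ankle's
forward position is exactly constant during stance and advances one
stride per swing along a raised-cosine profile (C¹ at the stance
boundaries), so commanded step length, width and cadence translate into
exact ground-truth foot placements and parameters.  The corruption model
emulates the known failure modes of markerless tracking: isotropic joint
noise, a lateral "surface pull" of every joint estimate toward the
observing sensor (self-occlusion bias), dropout of far-leg joints when
the line of sight grazes the near leg, timestamp jitter (≤ 2 ms, the
clock-synchrony budget of a PTP-synchronized rig) and frame-rate wobble
around 30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import MarkerObservation, square_marker_template
from .fusion import (JOINT_NAMES, N_JOINTS, TRACKED, UNTRACKED, SensorStream,
                     joint_index)
from .gait import FootPlacement, compute_parameters
from .transforms import RigidTransform

__all__ = [
    "SensorModel", "GaitCommand", "CorruptionModel", "TrueGait",
    "simulate_rig", "default_marker_poses", "simulate_marker_observations",
    "simulate_gait", "corrupt_streams", "simulate_point_clouds",
    "perfect_sensor",
]

UP = np.array([0.0, 0.0, 1.0])

_LEFT_LEG = tuple(joint_index(j) for j in
                  ("HipLeft", "KneeLeft", "AnkleLeft", "FootLeft"))
_RIGHT_LEG = tuple(joint_index(j) for j in
                   ("HipRight", "KneeRight", "AnkleRight", "FootRight"))


@dataclass
class SensorModel:
    """A depth sensor with pose and frustum.

    ``world_to_local`` maps global coordinates into the sensor's camera
    frame (x right, y up, z along the optical axis); its inverse is the
    sensor's pose in the global frame.
    """

    sensor_id: int
    side_tag: str
    world_to_local: RigidTransform
    horizontal_fov: float = 70.0     # degrees
    vertical_fov: float = 60.0       # degrees
    depth_min: float = 0.5           # m
    depth_max: float = 4.5           # m
    frame_rate: float = 30.0         # Hz, nominal
    unrestricted: bool = False       # ignore frustum and range entirely

    def __post_init__(self) -> None:
        if self.horizontal_fov <= 0 or self.vertical_fov <= 0:
            raise ValueError("fields of view must be positive")
        if not self.depth_min < self.depth_max:
            raise ValueError("depth range must satisfy min < max")

    @property
    def global_pose(self) -> RigidTransform:
        """Sensor-local → global (what calibration estimates)."""
        return self.world_to_local.inverse()

    @property
    def position(self) -> np.ndarray:
        return self.global_pose.translation

    def visible(self, points_global: np.ndarray) -> np.ndarray:
        """Frustum-and-range test for points of shape (..., 3)."""
        p = self.world_to_local.apply(points_global)
        if self.unrestricted:
            return np.ones(p.shape[:-1], dtype=bool)
        z = p[..., 2]
        tan_h = np.tan(np.radians(self.horizontal_fov / 2.0))
        tan_v = np.tan(np.radians(self.vertical_fov / 2.0))
        with np.errstate(invalid="ignore"):
            return ((z >= self.depth_min) & (z <= self.depth_max)
                    & (np.abs(p[..., 0]) <= z * tan_h)
                    & (np.abs(p[..., 1]) <= z * tan_v))


def _look_rotation(direction: np.ndarray) -> np.ndarray:
    """Local→global rotation for a camera looking along ``direction``
    (horizontal) with y up."""
    z = direction / np.linalg.norm(direction)
    x = np.cross(UP, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def perfect_sensor(sensor_id: int = 0, side_tag: str = "left") -> SensorModel:
    """An idealized sensor: identity pose, effectively unlimited frustum.

    Useful as a stand-in for a reference system or for end-to-end tests
    that must observe the whole walk from one stream.
    """
    return SensorModel(sensor_id, side_tag, RigidTransform.identity(),
                       horizontal_fov=359.0, vertical_fov=179.0,
                       depth_min=1e-6, depth_max=1e6, unrestricted=True)


def simulate_rig(n_rows: int = 3, row_spacing: float = 2.5,
                 corridor_width: float = 2.0, inward_angle: float = 35.0,
                 sensor_height: float = 1.0, first_row_x: float = -1.8,
                 frame_rate: float = 30.0) -> list[SensorModel]:
    """Paired left/right sensors per row along the walking corridor.

    Rows sit ``row_spacing`` apart along X (walking direction), sensors
    ``corridor_width`` apart across the corridor, each rotated inward by
    ``inward_angle`` degrees from the walking direction so consecutive
    tracking volumes overlap by about two meters.  Left sensors carry odd
    ids (1, 3, 5, …), right sensors even ids.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    half = corridor_width / 2.0
    ang = np.radians(inward_angle)
    sensors = []
    for row in range(n_rows):
        x = first_row_x + row * row_spacing
        for side, y, yaw_sign, sid in (("left", half, -1.0, 2 * row + 1),
                                       ("right", -half, 1.0, 2 * row + 2)):
            direction = np.array([np.cos(ang), yaw_sign * np.sin(ang), 0.0])
            rot = _look_rotation(direction)
            pose = RigidTransform(rot, np.array([x, y, sensor_height]))
            sensors.append(SensorModel(sid, side, pose.inverse(),
                                       frame_rate=frame_rate))
    return sensors


def centerline_coverage(sensor: SensorModel, height: float = 1.0,
                        x_range=(-5.0, 15.0), step: float = 0.005,
                        ) -> tuple[float, float] | None:
    """Visible interval of the corridor centerline (y = 0) at a height."""
    x = np.arange(x_range[0], x_range[1], step)
    pts = np.column_stack([x, np.zeros_like(x), np.full_like(x, height)])
    vis = sensor.visible(pts)
    if not vis.any():
        return None
    return float(x[vis].min()), float(x[vis].max())


def tracking_volume_length(rig: list[SensorModel], height: float = 1.0) -> float:
    """Length of the union of the sensors' centerline coverage intervals."""
    step = 0.005
    x = np.arange(-5.0, 20.0, step)
    pts = np.column_stack([x, np.zeros_like(x), np.full_like(x, height)])
    vis = np.zeros(len(x), dtype=bool)
    for s in rig:
        vis |= s.visible(pts)
    return float(vis.sum() * step)


def default_marker_poses(n_markers: int = 3, spacing: float = 2.5) -> dict:
    """Floor markers along the corridor; marker 1 defines the global frame
    (flat on the floor, first in-plane edge along the walk, normal up)."""
    return {k + 1: RigidTransform(np.eye(3), np.array([k * spacing, 0.0, 0.0]))
            for k in range(n_markers)}


def simulate_marker_observations(rig, marker_poses: dict,
                                 template_side: float = 0.30,
                                 noise_sigma: float = 0.0,
                                 seed: int = 0,
                                 n_frames: int = 30) -> tuple[list, dict]:
    """Per-sensor corner observations of every fully visible marker.

    Returns (observations, templates) where templates maps marker id to
    its :class:`MarkerTemplate`.  A marker is observed only when all of
    its corners pass the sensor's frustum-and-range test; corner noise is
    isotropic Gaussian in the sensor frame, independent per frame.

    ``n_frames`` emulates a calibration capture: a static marker is imaged
    repeatedly (default one second at 30 Hz) and every frame yields one
    noisy corner observation, which the pairwise fit then pools.  With
    ``noise_sigma = 0`` a single frame is emitted, as the rest would be
    identical.
    """
    rng = np.random.default_rng(seed)
    templates = {mid: square_marker_template(mid, template_side)
                 for mid in marker_poses}
    frames = n_frames if noise_sigma > 0 else 1
    observations = []
    for sensor in rig:
        for mid, pose in sorted(marker_poses.items()):
            corners_global = pose.apply(templates[mid].corner_points)
            if not sensor.visible(corners_global).all():
                continue
            local = sensor.world_to_local.apply(corners_global)
            for _ in range(frames):
                noisy = local
                if noise_sigma > 0:
                    noisy = local + rng.normal(0.0, noise_sigma, local.shape)
                observations.append(
                    MarkerObservation(sensor.sensor_id, mid, noisy))
    return observations, templates


# ---------------------------------------------------------------------------
# Gait kinematics


@dataclass
class GaitCommand:
    """Commanded walk: all ground-truth parameters follow from these."""

    step_length: float = 0.73        # m
    step_width: float = 0.12         # m
    cadence: float = 100.0           # steps / minute
    duty_factor: float = 0.6         # stance fraction of the gait cycle
    n_strides: int = 5               # swings per foot
    start_foot: str = "L"
    walk_origin: tuple = (-0.5, 0.0)  # (x, y) of the trailing foot at start
    heading: float = 0.0             # degrees about vertical
    lead_in: float = 0.4             # s of quiet stance before the first swing
    ankle_height: float = 0.08       # m during stance
    swing_lift: float = 0.05         # m peak extra ankle lift in swing

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must be in (0, 1)")
        if self.duty_factor <= 0.5:
            raise ValueError(
                "duty_factor must exceed 0.5 so that a double-support phase "
                "exists (both swings cannot overlap)")
        if min(self.step_length, self.step_width, self.cadence,
               self.n_strides) <= 0:
            raise ValueError("step_length, step_width, cadence and n_strides "
                             "must be positive")
        if self.start_foot not in ("L", "R"):
            raise ValueError("start_foot must be 'L' or 'R'")

    @property
    def step_time(self) -> float:
        return 60.0 / self.cadence

    @property
    def cycle_time(self) -> float:
        return 2.0 * self.step_time

    @property
    def swing_duration(self) -> float:
        return (1.0 - self.duty_factor) * self.cycle_time


def _foot_forward(t: np.ndarray, x0: float, first_swing: float,
                  cmd: GaitCommand) -> tuple[np.ndarray, np.ndarray]:
    """(forward position, swing phase u∈[0,1] or NaN) for one foot.

    Stance is exactly constant; each swing advances one stride
    (2·step_length) along a raised cosine.
    """
    stride = 2.0 * cmd.step_length
    cyc = cmd.cycle_time
    rel = np.asarray(t, float) - first_swing
    k = np.floor(rel / cyc)
    k = np.clip(k, -1, cmd.n_strides - 1)
    u = (rel - k * cyc) / cmd.swing_duration
    in_swing = (k >= 0) & (u >= 0.0) & (u < 1.0)
    completed = np.where(in_swing, k, np.where(u >= 1.0, k + 1, np.maximum(k, 0)))
    completed = np.clip(completed, 0, cmd.n_strides)
    x = x0 + stride * completed
    x = np.where(in_swing,
                 x0 + stride * k + stride * (1.0 - np.cos(np.pi * u)) / 2.0,
                 x)
    phase = np.where(in_swing, u, np.nan)
    return x, phase


@dataclass
class TrueGait:
    """Ground-truth walker: exact joint trajectories plus true parameters."""

    cmd: GaitCommand
    duration: float
    placements: list            # ground-truth FootPlacement list
    event_times: np.ndarray

    def _frame_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = np.radians(self.cmd.heading)
        fwd = np.array([np.cos(h), np.sin(h), 0.0])
        lat = np.array([-np.sin(h), np.cos(h), 0.0])
        origin = np.array([self.cmd.walk_origin[0], self.cmd.walk_origin[1], 0.0])
        return fwd, lat, origin

    def _ankles_flu(self, t: np.ndarray):
        """Forward/lateral/up ankle coordinates in the walk frame."""
        cmd = self.cmd
        swap = cmd.start_foot == "R"
        # the starting foot trails at forward 0; the other leads by one step
        lead, trail = (("R", "L") if not swap else ("L", "R"))
        t0 = cmd.lead_in
        trail_fwd, trail_u = _foot_forward(t, 0.0, t0, cmd)
        lead_fwd, lead_u = _foot_forward(t, cmd.step_length,
                                         t0 + cmd.step_time, cmd)
        out = {}
        for name, fwd, u in ((trail, trail_fwd, trail_u),
                             (lead, lead_fwd, lead_u)):
            lat = np.full_like(fwd, cmd.step_width / 2.0
                               if name == "L" else -cmd.step_width / 2.0)
            lift = np.where(np.isnan(u), 0.0,
                            cmd.swing_lift * np.sin(np.pi * np.nan_to_num(u)) ** 2)
            up = cmd.ankle_height + lift
            out[name] = (fwd, lat, up, u)
        return out

    def positions(self, times: np.ndarray) -> np.ndarray:
        """All 25 joint positions, shape (len(times), 25, 3), meters."""
        t = np.atleast_1d(np.asarray(times, float))
        cmd = self.cmd
        ank = self._ankles_flu(t)
        fwd_ax, lat_ax, origin = self._frame_axes()

        def to_global(f, l, u):
            return (origin[None, :] + np.outer(f, fwd_ax)
                    + np.outer(l, lat_ax) + np.outer(u, UP))

        joints = np.zeros((len(t), N_JOINTS, 3))

        lf, ll, lu, lph = ank["L"]
        rf, rl, ru, rph = ank["R"]
        body_f = (lf + rf) / 2.0
        arm_phase = np.pi * (lf - rf) / (2.0 * cmd.step_length)  # leg asymmetry

        def put(name, f, l, u):
            joints[:, joint_index(name), :] = to_global(f, l, u)

        w = cmd.step_width
        put("AnkleLeft", lf, ll, lu)
        put("AnkleRight", rf, rl, ru)
        put("FootLeft", lf + 0.15, ll, np.maximum(lu - 0.05, 0.02))
        put("FootRight", rf + 0.15, rl, np.maximum(ru - 0.05, 0.02))
        put("HipLeft", body_f, np.full_like(body_f, w / 2 + 0.04), 0.90 * np.ones_like(body_f))
        put("HipRight", body_f, np.full_like(body_f, -w / 2 - 0.04), 0.90 * np.ones_like(body_f))
        # knees: between hip and ankle, bulging forward in swing
        for side, (f, l, u, ph) in (("Left", ank["L"]), ("Right", ank["R"])):
            bulge = np.where(np.isnan(ph), 0.0,
                             0.08 * np.sin(np.pi * np.nan_to_num(ph)))
            put(f"Knee{side}", (body_f + f) / 2.0 + bulge, l, (0.9 + u) / 2.0)
        trunk_lat = np.zeros_like(body_f)
        for name, h in (("SpineBase", 0.95), ("SpineMid", 1.15),
                        ("SpineShoulder", 1.35), ("Neck", 1.45), ("Head", 1.62)):
            put(name, body_f, trunk_lat, h * np.ones_like(body_f))
        for side, sign in (("Left", 1.0), ("Right", -1.0)):
            sh_l = np.full_like(body_f, sign * 0.18)
            swing = 0.10 * np.sin(arm_phase) * (-sign)   # arms counter the legs
            put(f"Shoulder{side}", body_f, sh_l, 1.40 * np.ones_like(body_f))
            put(f"Elbow{side}", body_f + 0.6 * swing, sh_l + sign * 0.02,
                1.15 * np.ones_like(body_f))
            put(f"Wrist{side}", body_f + swing, sh_l + sign * 0.03,
                0.95 * np.ones_like(body_f))
            put(f"Hand{side}", body_f + 1.1 * swing, sh_l + sign * 0.03,
                0.90 * np.ones_like(body_f))
            put(f"HandTip{side}", body_f + 1.2 * swing, sh_l + sign * 0.03,
                0.86 * np.ones_like(body_f))
            put(f"Thumb{side}", body_f + 1.1 * swing, sh_l + sign * 0.01,
                0.89 * np.ones_like(body_f))
        return joints

    def ankle_trajectories(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.positions(times)
        return (p[:, joint_index("AnkleLeft"), :],
                p[:, joint_index("AnkleRight"), :])

    def swing_phase(self, times: np.ndarray) -> dict:
        """Per-foot swing phase u∈[0,1] (NaN in stance) at the given times."""
        t = np.atleast_1d(np.asarray(times, float))
        ank = self._ankles_flu(t)
        return {"L": ank["L"][3], "R": ank["R"][3]}

    def true_parameters(self):
        """(steps, strides, summary) computed from the true placements with
        the standard exclusion rule — the oracle for the whole pipeline."""
        return compute_parameters(self.placements, self.cmd.start_foot)


def simulate_gait(cmd: GaitCommand) -> TrueGait:
    """Construct the ground-truth walker for a command.

    The walker starts in steady state: the starting foot trails by one
    step length and swings first, so its very first swing passes the other
    foot.  Every swing therefore produces exactly one crossing event
    (2·n_strides in total), each at mid-swing when the advancing ankle
    passes the stance ankle — at which instant the stance ankle sits
    exactly at its placement position.
    """
    t0 = cmd.lead_in
    half_swing = cmd.swing_duration / 2.0
    n_events = 2 * cmd.n_strides
    event_times = t0 + half_swing + cmd.step_time * np.arange(n_events)
    # the swinging foot at event j alternates starting with start_foot
    placements = []
    other = {"L": "R", "R": "L"}
    swing = cmd.start_foot
    for j in range(n_events):
        stance = other[swing]
        fwd = (j + 1) * cmd.step_length
        lat = cmd.step_width / 2.0 if stance == "L" else -cmd.step_width / 2.0
        placements.append(FootPlacement(stance, float(event_times[j]),
                                        fwd, lat))
        swing = stance
    duration = (t0 + cmd.step_time + (cmd.n_strides - 1) * cmd.cycle_time
                + cmd.swing_duration + cmd.lead_in)
    return TrueGait(cmd, float(duration), placements, event_times)


# ---------------------------------------------------------------------------
# Corruption


@dataclass
class CorruptionModel:
    """Measurement-degradation parameters (all non-negative; zeros = ideal)."""

    joint_noise_sigma: float = 0.01       # m, isotropic
    lateral_surface_bias: float = 0.0     # m, pull toward the sensor
    occlusion_dropout: bool = True
    occlusion_threshold: float = 0.08     # m, line-of-sight clearance
    timestamp_jitter: float = 0.002       # s
    frame_rate_wobble: float = 0.3        # Hz

    def __post_init__(self) -> None:
        for name in ("joint_noise_sigma", "lateral_surface_bias",
                     "occlusion_threshold", "timestamp_jitter",
                     "frame_rate_wobble"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _segment_point_distances(a0, a1, p):
    """Distance from points p (n,3) to segment [a0, a1] per row."""
    d = a1 - a0
    denom = np.einsum("ij,ij->i", d, d)
    tpar = np.einsum("ij,ij->i", p - a0, d) / np.where(denom > 0, denom, 1.0)
    tpar = np.clip(tpar, 0.0, 1.0)
    closest = a0 + tpar[:, None] * d
    return np.linalg.norm(p - closest, axis=1)


def _ray_segment_occluded(sensor_pos, joints, seg_a, seg_b, threshold):
    """True where the sensor→joint ray passes within ``threshold`` of the
    segment [seg_a, seg_b] strictly between sensor and joint.

    All of ``joints``, ``seg_a``, ``seg_b`` have shape (n, 3).
    """
    n = len(joints)
    occluded = np.zeros(n, dtype=bool)
    ray = joints - sensor_pos                      # (n, 3)
    ray_len = np.linalg.norm(ray, axis=1)
    ok = ray_len > 1e-9
    # sample the occluder segment finely and project onto the ray
    for frac in np.linspace(0.0, 1.0, 9):
        q = seg_a + frac * (seg_b - seg_a)         # (n, 3)
        tpar = np.einsum("ij,ij->i", q - sensor_pos, ray) / np.where(
            ok, ray_len**2, 1.0)
        between = (tpar > 0.0) & (tpar < 1.0 - 1e-6)
        closest = sensor_pos + tpar[:, None] * ray
        dist = np.linalg.norm(q - closest, axis=1)
        occluded |= ok & between & (dist < threshold)
    return occluded


def corrupt_streams(truth: TrueGait, rig: list[SensorModel],
                    corruption: CorruptionModel | None = None,
                    seed: int = 0) -> list[SensorStream]:
    """Sample the true walker through each sensor's imperfect measurement.

    Per sensor: frames at a jittered ~30 Hz clock; joints outside the
    frustum are untracked; far-leg joints whose line of sight grazes the
    near-leg (hip→ankle) segment are untracked (self-occlusion); the rest
    get the lateral surface pull toward the sensor plus isotropic noise,
    expressed in the sensor's local frame.  Deterministic under ``seed``.
    """
    corruption = corruption or CorruptionModel()
    rng = np.random.default_rng(seed)
    streams = []
    for sensor in sorted(rig, key=lambda s: s.sensor_id):
        rate = sensor.frame_rate + rng.uniform(
            -corruption.frame_rate_wobble, corruption.frame_rate_wobble)
        n = int(np.floor(truth.duration * rate))
        t = np.arange(n) / rate
        if corruption.timestamp_jitter > 0 or corruption.frame_rate_wobble > 0:
            # independent frame clocks: random phase plus per-frame jitter
            t = (t + rng.uniform(0.0, 1.0 / rate)
                 + rng.uniform(-corruption.timestamp_jitter,
                               corruption.timestamp_jitter, n))
        t = np.sort(t)
        t = t[(t >= 0) & (t <= truth.duration)]
        pos = truth.positions(t)                    # (n, 25, 3) global, exact
        states = np.full((len(t), N_JOINTS), TRACKED, dtype=int)

        # frustum culling
        vis = sensor.visible(pos)
        states[~vis] = UNTRACKED

        # self-occlusion of the far leg by the near leg
        if corruption.occlusion_dropout:
            near, far = ((_LEFT_LEG, _RIGHT_LEG) if sensor.side_tag == "left"
                         else (_RIGHT_LEG, _LEFT_LEG))
            hip = pos[:, near[0], :]
            ankle = pos[:, near[2], :]
            for j in far:
                occ = _ray_segment_occluded(sensor.position, pos[:, j, :],
                                            hip, ankle,
                                            corruption.occlusion_threshold)
                states[occ, j] = UNTRACKED

        # Lateral surface pull: the joint estimate sits closer to the body
        # surface the sensor actually sees, and limb surfaces face sideways —
        # so the displacement is lateral (perpendicular to the walk), of
        # magnitude b, toward the sensor's side.
        if corruption.lateral_surface_bias > 0:
            h = np.radians(truth.cmd.heading)
            lat_axis = np.array([-np.sin(h), np.cos(h), 0.0])
            side = np.sign((sensor.position[None, None, :] - pos) @ lat_axis)
            pos = pos + (corruption.lateral_surface_bias
                         * side[..., None] * lat_axis[None, None, :])

        if corruption.joint_noise_sigma > 0:
            pos = pos + rng.normal(0.0, corruption.joint_noise_sigma, pos.shape)

        local = sensor.world_to_local.apply(pos)
        local[states == UNTRACKED] = 0.0
        streams.append(SensorStream(sensor.sensor_id, sensor.side_tag,
                                    t, local, states))
    return streams


# ---------------------------------------------------------------------------
# Point clouds for ICP


def default_scene_primitives(x_extent=(-2.5, 9.0), corridor_half=1.1):
    """Planar scene patches: floor, two walls and a box — enough geometry
    to constrain all six degrees of freedom in ICP."""
    x0, x1 = x_extent
    return [
        # (corner, edge1, edge2)
        (np.array([x0, -corridor_half, 0.0]),
         np.array([x1 - x0, 0.0, 0.0]), np.array([0.0, 2 * corridor_half, 0.0])),
        (np.array([x0, -corridor_half, 0.0]),
         np.array([x1 - x0, 0.0, 0.0]), np.array([0.0, 0.0, 2.0])),
        (np.array([x0, corridor_half, 0.0]),
         np.array([x1 - x0, 0.0, 0.0]), np.array([0.0, 0.0, 2.0])),
        (np.array([x1, -corridor_half, 0.0]),
         np.array([0.0, 2 * corridor_half, 0.0]), np.array([0.0, 0.0, 2.0])),
        (np.array([2.0, -0.3, 0.0]),
         np.array([0.6, 0.1, 0.0]), np.array([0.0, 0.1, 0.8])),
    ]


def simulate_point_clouds(rig: list[SensorModel], density: float = 200.0,
                          noise_sigma: float = 0.0, seed: int = 0,
                          primitives=None) -> dict:
    """Per-sensor local-frame point clouds of a shared static scene.

    The same physical surface points (sampled once at ``density`` points
    per m²) are observed by every sensor that has them in its frustum, so
    overlapping clouds correspond exactly when noiseless.
    """
    rng = np.random.default_rng(seed)
    primitives = primitives or default_scene_primitives()
    points = []
    for corner, e1, e2 in primitives:
        area = np.linalg.norm(np.cross(e1, e2))
        n = int(np.round(area * density))
        if n == 0:
            continue
        uv = rng.uniform(0.0, 1.0, (n, 2))
        points.append(corner + uv[:, :1] * e1 + uv[:, 1:] * e2)
    if points:
        points = np.vstack(points)
    else:
        points = np.zeros((0, 3))
    clouds = {}
    for sensor in rig:
        if len(points) == 0:
            clouds[sensor.sensor_id] = np.zeros((0, 3))
            continue
        vis = sensor.visible(points)
        local = sensor.world_to_local.apply(points[vis])
        if noise_sigma > 0:
            local = local + rng.normal(0.0, noise_sigma, local.shape)
        clouds[sensor.sensor_id] = local
    return clouds
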