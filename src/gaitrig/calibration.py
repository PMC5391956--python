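"""Extrinsic calibration of a multi-sensor rig from shared planar markers.

Each depth sensor observes the 3-D corner points of one or more coded
planar markers placed in the scene.  A rigid Procrustes fit of the marker
template onto each observation yields the marker→sensor transform.  Not
every sensor needs to see the marker that defines the global frame (the
"origin marker"): the "sensor s sees marker m" relation forms a bipartite
graph, and as long as that graph is connected every sensor pose can be
obtained by chaining transforms along a path to the origin marker.  The
shortest path is used because each hop adds estimation error.  An optional
point-to-point ICP pass against overlapping point clouds refines the
chained poses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .transforms import RigidTransform, procrustes_fit

__all__ = [
    "MarkerTemplate",
    "MarkerObservation",
    "VisibilityGraph",
    "CalibrationResult",
    "build_visibility_graph",
    "fit_pairwise_transforms",
    "chain_to_origin",
    "calibrate",
    "icp_refine",
    "IcpParams",
    "DisconnectedRigError",
]

# Global-frame convention: the origin marker lies flat on the floor, its first
# in-plane edge is the walking-direction X axis and its plane normal is Z-up.
GLOBAL_FRAME_CONVENTION = "origin-marker plane: X = first edge, Z = plane normal (up)"


def square_marker_template(marker_id: int, side: float = 0.30) -> "MarkerTemplate":
    """Canonical marker: the 4 corners of a square of given side (meters),
    ordered counter-clockwise starting at the dent corner, in the marker's
    own frame (marker centered, lying in its XY plane)."""
    h = side / 2.0
    corners = np.array(
        [[-h, -h, 0.0], [h, -h, 0.0], [h, h, 0.0], [-h, h, 0.0]])
    return MarkerTemplate(marker_id, corners)


@dataclass(frozen=True)
class MarkerTemplate:
    """Marker geometry in its own frame; corner ordering is canonical."""

    marker_id: int
    corner_points: np.ndarray

    def __post_init__(self) -> None:
        if self.marker_id <= 0:
            raise ValueError("marker_id must be a positive integer")
        pts = np.asarray(self.corner_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("corner_points must have shape (n>=3, 3)")
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
            raise ValueError("marker corners must not be collinear")
        object.__setattr__(self, "corner_points", pts)


@dataclass(frozen=True)
class MarkerObservation:
    """Corner points of one marker as measured in one sensor's local frame."""

    sensor_id: int
    marker_id: int
    corner_points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.corner_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("corner_points must have shape (n, 3)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("corner coordinates must be finite")
        object.__setattr__(self, "corner_points", pts)


def _sensor_node(sensor_id) -> tuple:
    return ("sensor", sensor_id)


def _marker_node(marker_id) -> tuple:
    return ("marker", marker_id)


@dataclass
class VisibilityGraph:
    """Bipartite sensor–marker graph; an edge means "sensor sees marker"."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def sensor_nodes(self) -> set:
        return {n[1] for n in self.graph.nodes if n[0] == "sensor"}

    @property
    def marker_nodes(self) -> set:
        return {n[1] for n in self.graph.nodes if n[0] == "marker"}

    @property
    def edges(self) -> set:
        out = set()
        for a, b in self.graph.edges:
            s, m = (a, b) if a[0] == "sensor" else (b, a)
            out.add((s[1], m[1]))
        return out

    def is_connected(self) -> bool:
        if self.graph.number_of_nodes() == 0:
            return True
        return nx.is_connected(self.graph)


class DisconnectedRigError(RuntimeError):
    """Raised when some sensors cannot be chained to the origin marker."""

    def __init__(self, unreachable_sensors: list):
        self.unreachable_sensors = list(unreachable_sensors)
        super().__init__(
            "visibility graph is not connected; sensors with no path to the "
            f"origin marker: {self.unreachable_sensors}")


@dataclass
class CalibrationResult:
    """Per-sensor pose (sensor-local → global frame) with provenance."""

    transforms: dict  # sensor_id -> RigidTransform
    paths: dict       # sensor_id -> node sequence [("sensor", id), ..., ("marker", origin)]
    residuals: dict   # sensor_id -> RMS corner residual (m) along its first hop
    origin_marker_id: int
    refined: bool = False
    frame_convention: str = GLOBAL_FRAME_CONVENTION

    def sensor_ids(self) -> list:
        return sorted(self.transforms)


def build_visibility_graph(observations) -> VisibilityGraph:
    """One edge per distinct (sensor, marker) pair; duplicates collapse."""
    g = nx.Graph()
    for obs in observations:
        g.add_node(_sensor_node(obs.sensor_id))
        g.add_node(_marker_node(obs.marker_id))
        g.add_edge(_sensor_node(obs.sensor_id), _marker_node(obs.marker_id))
    return VisibilityGraph(g)


def fit_pairwise_transforms(observations, templates) -> tuple[dict, dict]:
    """Procrustes-fit every (sensor, marker) edge.

    Multiple observations of the same pair are stacked (corners repeated per
    observation) so the fit uses all the evidence.

    Returns
    -------
    (pairwise, residuals):
        ``pairwise[(sensor_id, marker_id)]`` maps marker-frame coordinates
        into the sensor's local frame; residuals are the RMS corner errors.
    """
    if isinstance(templates, MarkerTemplate):
        templates = {templates.marker_id: templates}
    elif not isinstance(templates, dict):
        templates = {t.marker_id: t for t in templates}
    grouped: dict = {}
    for obs in observations:
        tpl = templates[obs.marker_id]
        if obs.corner_points.shape[0] != tpl.corner_points.shape[0]:
            raise ValueError(
                f"observation of marker {obs.marker_id} by sensor "
                f"{obs.sensor_id} has {obs.corner_points.shape[0]} corners, "
                f"template has {tpl.corner_points.shape[0]}")
        grouped.setdefault((obs.sensor_id, obs.marker_id), []).append(
            obs.corner_points)
    pairwise, residuals = {}, {}
    for (sid, mid), corner_sets in grouped.items():
        tpl = templates[mid].corner_points
        src = np.vstack([tpl] * len(corner_sets))
        tgt = np.vstack(corner_sets)
        pairwise[(sid, mid)], residuals[(sid, mid)] = procrustes_fit(src, tgt)
    return pairwise, residuals


def _shortest_path_deterministic(graph: nx.Graph, source, target):
    """Unweighted BFS shortest path with ties broken by ascending node id."""
    if source == target:
        return [source]
    visited = {source: None}
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node), key=lambda n: (n[0], str(n[1]))):
                if nb not in visited:
                    visited[nb] = node
                    if nb == target:
                        path = [nb]
                        while visited[path[-1]] is not None:
                            path.append(visited[path[-1]])
                        return path[::-1]
                    nxt.append(nb)
        frontier = nxt
    return None


def chain_to_origin(graph: VisibilityGraph, pairwise: dict,
                    origin_marker_id: int,
                    residuals: dict | None = None) -> CalibrationResult:
    """Chain marker→sensor transforms along shortest paths to the origin.

    ``pairwise[(sensor, marker)]`` must map marker-frame points into the
    sensor frame (the output of :func:`fit_pairwise_transforms`).  The
    returned per-sensor transform maps sensor-local coordinates into the
    frame of the origin marker (the global frame).
    """
    g = graph.graph
    origin = _marker_node(origin_marker_id)
    if origin not in g:
        raise ValueError(f"origin marker {origin_marker_id} not in the graph")
    sensors = sorted(graph.sensor_nodes, key=str)
    unreachable = [s for s in sensors
                   if _shortest_path_deterministic(g, _sensor_node(s), origin) is None]
    if unreachable:
        raise DisconnectedRigError(unreachable)

    transforms, paths, rms = {}, {}, {}
    for sid in sensors:
        path = _shortest_path_deterministic(g, _sensor_node(sid), origin)
        total = RigidTransform.identity()
        for a, b in zip(path[:-1], path[1:]):
            if a[0] == "sensor":     # sensor → marker hop: invert marker→sensor
                step = pairwise[(a[1], b[1])].inverse()
            else:                    # marker → sensor hop
                step = pairwise[(b[1], a[1])]
            total = step.compose(total)
        transforms[sid] = total
        paths[sid] = path
        if residuals is not None:
            first = path[1]
            rms[sid] = residuals[(sid, first[1])]
        else:
            rms[sid] = float("nan")
    return CalibrationResult(transforms, paths, rms, origin_marker_id)


def calibrate(observations, templates, origin_marker_id: int = 1) -> CalibrationResult:
    """Full marker-based calibration: graph, pairwise fits, chaining."""
    graph = build_visibility_graph(observations)
    pairwise, residuals = fit_pairwise_transforms(observations, templates)
    return chain_to_origin(graph, pairwise, origin_marker_id, residuals)


@dataclass
class IcpParams:
    max_iterations: int = 30
    convergence_tolerance: float = 1e-7   # m, change in mean NN distance
    max_pair_distance: float = 0.10       # m, correspondence rejection radius
    subsample_fraction: float = 0.20      # uniform subsampling of the moving cloud
    min_pairs: int = 20                   # below this, refinement is skipped


def icp_refine(clouds: dict, initial: CalibrationResult,
               params: IcpParams | None = None,
               rng: np.random.Generator | None = None) -> CalibrationResult:
    """Point-to-point ICP refinement of the chained sensor poses.

    Sensors are refined one at a time in ascending chaining-path-length
    order (ties by sensor id) against the merged global-frame cloud of the
    already-fixed sensors; the first sensor in that order anchors the frame
    and never moves.  A sensor with fewer than ``min_pairs`` matches within
    ``max_pair_distance`` is left at its initial pose with a warning.

    Parameters
    ----------
    clouds:
        ``sensor_id -> (n, 3)`` points in that sensor's LOCAL frame.
    """
    params = params or IcpParams()
    rng = rng or np.random.default_rng(0)
    order = sorted(initial.transforms,
                   key=lambda s: (len(initial.paths[s]), str(s)))
    order = [s for s in order if s in clouds and len(clouds[s]) > 0]
    new_tf = dict(initial.transforms)
    if len(order) < 2:
        warnings.warn("ICP refinement needs at least two non-empty clouds; "
                      "poses left unchanged")
        return CalibrationResult(new_tf, dict(initial.paths),
                                 dict(initial.residuals),
                                 initial.origin_marker_id, refined=False,
                                 frame_convention=initial.frame_convention)

    anchor = order[0]
    fixed_global = [new_tf[anchor].apply(np.asarray(clouds[anchor], float))]
    for sid in order[1:]:
        local = np.asarray(clouds[sid], float)
        pose = new_tf[sid]
        tree = cKDTree(np.vstack(fixed_global))
        n_sub = max(params.min_pairs,
                    int(round(len(local) * params.subsample_fraction)))
        if n_sub < len(local):
            idx = rng.choice(len(local), size=n_sub, replace=False)
            sub = local[idx]
        else:
            sub = local
        prev_mean = np.inf
        for _ in range(params.max_iterations):
            moved = pose.apply(sub)
            dist, nn = tree.query(moved, distance_upper_bound=params.max_pair_distance)
            ok = np.isfinite(dist)
            if ok.sum() >= params.min_pairs:
                # adaptive trim: spurious matches near the frustum boundary sit
                # far beyond the bulk of the true correspondences
                cut = 3.0 * np.median(dist[ok]) + params.convergence_tolerance
                ok &= dist <= cut
            if ok.sum() < params.min_pairs:
                warnings.warn(
                    f"ICP: sensor {sid} has only {int(ok.sum())} matched pairs "
                    f"within {params.max_pair_distance} m; refinement skipped")
                pose = new_tf[sid]
                break
            mean_d = float(dist[ok].mean())
            if abs(prev_mean - mean_d) < params.convergence_tolerance:
                break
            prev_mean = mean_d
            targets = tree.data[nn[ok]]
            step, _ = procrustes_fit(moved[ok], targets)
            pose = step.compose(pose)
        new_tf[sid] = pose
        fixed_global.append(pose.apply(local))
    return CalibrationResult(new_tf, dict(initial.paths),
                             dict(initial.residuals),
                             initial.origin_marker_id, refined=True,
                             frame_convention=initial.frame_convention)
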