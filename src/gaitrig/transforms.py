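"""Rigid (Euclidean) 3-D transforms and least-squares rigid registration.

A :class:`RigidTransform` is a proper rotation plus a translation, the
building block of the extrinsic calibration: every sensor pose and every
marker pose is expressed this way, and poses are chained by composition.
Scaling and reflection are deliberately excluded — the sensors measure
metric geometry, so only distance-preserving maps are admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "procrustes_fit"]

_ORTHO_TOL = 1e-9


def _check_rotation(r: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation matrix is a reflection (det < 0)")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (meters)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points of shape (..., 3) into the target frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``x -> self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    # --- metrics ---------------------------------------------------------
    def rotation_angle(self) -> float:
        """Geodesic rotation angle in radians (0 for identity).

        Computed through the quaternion representation, which stays
        accurate for angles far below the arccos precision floor.
        """
        return float(Rotation.from_matrix(self.rotation).magnitude())

    def error_from(self, other: "RigidTransform") -> tuple[float, float]:
        """(rotation angle rad, translation norm m) of ``self ∘ other⁻¹``."""
        delta = self.compose(other.inverse())
        return delta.rotation_angle(), float(np.linalg.norm(delta.translation))

    # --- serialization ---------------------------------------------------
    def as_quaternion(self) -> np.ndarray:
        """Unit quaternion in scalar-last (x, y, z, w) order."""
        return Rotation.from_matrix(self.rotation).as_quat()

    @classmethod
    def from_quaternion(cls, quat, translation) -> "RigidTransform":
        return cls(Rotation.from_quat(np.asarray(quat, float)).as_matrix(),
                   translation)

    @classmethod
    def from_euler(cls, seq: str, angles, translation=(0.0, 0.0, 0.0),
                   degrees: bool = False) -> "RigidTransform":
        return cls(Rotation.from_euler(seq, angles, degrees=degrees).as_matrix(),
                   translation)

    @classmethod
    def random(cls, rng: np.random.Generator,
               max_translation: float = 1.0) -> "RigidTransform":
        """Uniformly random proper rotation with a bounded random translation."""
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls(rot, t)


def procrustes_fit(source_points: np.ndarray,
                   target_points: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ordered, corresponding point sets.

    Finds the rotation ``R`` (proper, det = +1) and translation ``t``
    minimizing ``Σ‖R s_i + t − p_i‖²`` (Kabsch/Umeyama solution via SVD of
    the cross-covariance, with the singular-value sign correction that
    forbids reflections).  No scale is fitted: a scaled point set leaves a
    nonzero residual by design.

    Parameters
    ----------
    source_points, target_points:
        Arrays of shape (n, 3), n ≥ 3, matched by row order.

    Returns
    -------
    (transform, rms_residual):
        ``transform.apply(source)`` best approximates ``target``;
        the residual is the RMS of the remaining point distances (meters).
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or tgt.shape != src.shape:
        raise ValueError("point sets must both have shape (n, 3)")
    n = src.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(tgt))):
        raise ValueError("point coordinates must be finite")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    # Collinear (rank < 2) sets leave the rotation about the line free.
    if (np.linalg.matrix_rank(src_c, tol=1e-10) < 2
            or np.linalg.matrix_rank(tgt_c, tol=1e-10) < 2):
        raise ValueError("degenerate (collinear) point configuration")

    h = src_c.T @ tgt_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform(rot, t)
    resid = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms
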