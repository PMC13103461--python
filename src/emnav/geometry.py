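"""Pose algebra for 6-DOF rigid transforms and reference-sensor-relative tracking.

Conventions (fixed once, documented in the I/O schema):

* quaternions are **w-first** ``(w, x, y, z)``, unit norm, canonical sign
  ``w >= 0``; rotations are active and frames right-handed;
* all translations and points are in **millimetres**;
* coordinate frames are explicit string labels (``"tracker"``, ``"plan"``,
  ``"sensor:<id>"``, ...).  A :class:`RigidTransform` maps points expressed in
  its ``source_frame`` to the same points expressed in its ``target_frame``,
  and composition/application check that the labels chain.  The labels exist
  because an electromagnetic setup mixes tracker-frame and reference-frame
  quantities freely, and silent frame confusion is the classic navigation bug.

The reference-sensor construction: a third sensor fixed to immobile anatomy
(zygomatic bone) defines the working frame, so that every measurement is
invariant to motion of the patient's head relative to the field generator.
:func:`relative_pose` implements that re-expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

from .errors import FrameError, SynchronizationError

__all__ = [
    "Rotation",
    "RigidTransform",
    "PoseSample",
    "as_point",
    "as_points",
    "compose",
    "apply",
    "relative_pose",
    "rotation_about_point",
    "DEFAULT_SYNC_TOL_S",
]

#: Default timestamp synchronization tolerance: half a 40 Hz sample interval.
DEFAULT_SYNC_TOL_S = 0.005

_UNIT_TOL = 1e-9


def as_point(p) -> np.ndarray:
    """Coerce ``p`` to a finite float64 vector of shape (3,) (millimetres)."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point has non-finite components: {arr}")
    return arr


def as_points(pts) -> np.ndarray:
    """Coerce to a finite (N, 3) float64 array of points."""
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("point array has non-finite components")
    return arr


def _canonical(quat: np.ndarray) -> np.ndarray:
    """Normalize and fix the double-cover sign ambiguity to w >= 0."""
    n = np.linalg.norm(quat)
    if not np.isfinite(n) or n < _UNIT_TOL:
        raise ValueError("quaternion has (near-)zero norm")
    quat = quat / n
    if quat[0] < 0 or (quat[0] == 0 and _first_nonzero_sign(quat) < 0):
        quat = -quat
    return quat


def _first_nonzero_sign(quat: np.ndarray) -> float:
    for c in quat[1:]:
        if c != 0:
            return np.sign(c)
    return 1.0


@dataclass(frozen=True)
class Rotation:
    """A proper 3-D rotation stored as a unit quaternion ``(w, x, y, z)``."""

    quat: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "quat", _canonical(np.asarray(self.quat, dtype=float).reshape(4)))

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_quat(cls, w, x, y, z) -> "Rotation":
        return cls(np.array([w, x, y, z], dtype=float))

    @classmethod
    def from_matrix(cls, matrix) -> "Rotation":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("rotation matrix must be 3x3")
        if abs(np.linalg.det(m) - 1.0) > 1e-6 or not np.allclose(m @ m.T, np.eye(3), atol=1e-6):
            raise ValueError("matrix is not a proper rotation (orthonormal, det +1)")
        q = _ScipyRotation.from_matrix(m).as_quat()  # scipy: (x, y, z, w)
        return cls(np.array([q[3], q[0], q[1], q[2]]))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float) -> "Rotation":
        axis = as_point(axis)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be non-zero")
        q = _ScipyRotation.from_rotvec(axis / n * angle_rad).as_quat()
        return cls(np.array([q[3], q[0], q[1], q[2]]))

    # -- accessors ---------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        w, x, y, z = self.quat
        return _ScipyRotation.from_quat([x, y, z, w]).as_matrix()

    @property
    def angle_rad(self) -> float:
        """Rotation angle in [0, pi]."""
        return 2.0 * np.arccos(np.clip(abs(self.quat[0]), -1.0, 1.0))

    # -- algebra -----------------------------------------------------------
    def inverse(self) -> "Rotation":
        w, x, y, z = self.quat
        return Rotation(np.array([w, -x, -y, -z]))

    def __matmul__(self, other: "Rotation") -> "Rotation":
        w1, x1, y1, z1 = self.quat
        w2, x2, y2, z2 = other.quat
        return Rotation(
            np.array(
                [
                    w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                    w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                    w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                    w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
                ]
            )
        )

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.as_matrix().T

    def isclose(self, other: "Rotation", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.quat, other.quat, atol=atol))


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation (mm) mapping ``source_frame`` to ``target_frame``."""

    rotation: Rotation
    translation: np.ndarray
    source_frame: str = "source"
    target_frame: str = "target"

    def __post_init__(self):
        object.__setattr__(self, "translation", as_point(self.translation))

    @classmethod
    def identity(cls, frame: str = "source") -> "RigidTransform":
        return cls(Rotation.identity(), np.zeros(3), frame, frame)

    @classmethod
    def from_matrix(cls, matrix, source_frame="source", target_frame="target") -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("homogeneous matrix must be 4x4")
        return cls(Rotation.from_matrix(m[:3, :3]), m[:3, 3], source_frame, target_frame)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation.as_matrix()
        m[:3, 3] = self.translation
        return m

    def invert(self) -> "RigidTransform":
        rinv = self.rotation.inverse()
        return RigidTransform(
            rinv, -rinv.apply(self.translation), self.target_frame, self.source_frame
        )

    def apply(self, points) -> np.ndarray:
        return self.rotation.apply(points) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def relabel(self, source_frame=None, target_frame=None) -> "RigidTransform":
        return replace(
            self,
            source_frame=self.source_frame if source_frame is None else source_frame,
            target_frame=self.target_frame if target_frame is None else target_frame,
        )

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return self.rotation.isclose(other.rotation, atol) and bool(
            np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class PoseSample:
    """One timestamped 6-DOF reading: the sensor's pose in the tracker frame."""

    timestamp: float
    sensor_id: str
    pose: RigidTransform = field(default_factory=RigidTransform.identity)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """``a ∘ b``: the transform that applies ``b`` first, then ``a``.

    Requires ``a.source_frame == b.target_frame`` (the frames must chain).
    """
    if a.source_frame != b.target_frame:
        raise FrameError(
            f"cannot compose: left transform expects frame {a.source_frame!r}, "
            f"right transform produces frame {b.target_frame!r}"
        )
    rot = a.rotation @ b.rotation
    trans = a.rotation.apply(b.translation) + a.translation
    return RigidTransform(rot, trans, b.source_frame, a.target_frame)


def apply(t: RigidTransform, p) -> np.ndarray:
    """Apply ``t`` to a point (or (N, 3) array) expressed in ``t.source_frame``."""
    return t.apply(p)


def relative_pose(
    sensor: PoseSample,
    reference: PoseSample,
    sync_tol_s: float = DEFAULT_SYNC_TOL_S,
) -> RigidTransform:
    """Express a sensor's pose in the reference sensor's frame.

    Both samples carry poses measured in the shared tracker (field-generator)
    frame; the result is ``invert(reference.pose) ∘ sensor.pose`` and is
    invariant to any rigid motion applied simultaneously to both poses — this
    is what makes the tracked scene immune to head movement.
    """
    skew = abs(sensor.timestamp - reference.timestamp)
    if skew > sync_tol_s:
        raise SynchronizationError(
            f"pose samples {sensor.sensor_id!r} and {reference.sensor_id!r} "
            f"are {skew * 1e3:.2f} ms apart (tolerance {sync_tol_s * 1e3:.2f} ms)"
        )
    if sensor.pose.target_frame != reference.pose.target_frame:
        raise FrameError(
            "sensor and reference poses must be measured in the same tracker frame"
        )
    return compose(reference.pose.invert(), sensor.pose)


def rotation_about_point(axis, angle_rad: float, center, frame: str = "plan") -> RigidTransform:
    """Rigid transform rotating by ``angle_rad`` about an axis through ``center``.

    Useful for modelling lever-arm placement errors, e.g. a graft pivoting
    about its junction with the residual mandible.
    """
    rot = Rotation.from_axis_angle(axis, angle_rad)
    c = as_point(center)
    return RigidTransform(rot, c - rot.apply(c), frame, frame)
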