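"""Paired-point rigid registration and its error metrics.

The planned bone segments (residual mandible, assembled fibular graft) are
superimposed onto the tracked anatomy by matching named fiducial landmarks:
the solution is the rigid transform minimizing the sum of squared distances
between corresponding points.  We solve it in closed form with Horn's unit
quaternion method: build the 4x4 symmetric matrix N from the cross-covariance
of the centred point sets; the optimal rotation is the eigenvector of N with
the largest eigenvalue, read as a (w, x, y, z) quaternion, and the
translation maps the moving centroid onto the fixed one.  Because the
quaternion parameterization cannot represent a reflection, det(R) = +1 by
construction — even for noisy, near-planar fiducial configurations, where
naive SVD solutions can flip.

Registration quality is reported as

* **FRE** (fiducial registration error) — residual misfit at the fiducials
  themselves, by default the root-mean-square residual distance (a
  mean-absolute variant is available, as the convention is not universal);
* **TRE** (target registration error) — displacement at a clinically
  relevant point *not* used for the registration, e.g. the planned condyle
  or the graft's centre of gravity.  In simulation the truth transform is
  known; on physical data the target is probed instead.

The expected TRE is predicted by Fitzpatrick's formula
``TRE^2(r) = FLE^2/N * (1 + (1/3) * sum_k d_k^2 / f_k^2)`` where ``d_k`` is
the target's distance from the k-th principal axis of the fiducial
configuration and ``f_k`` the RMS fiducial distance from that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    CorrespondenceError,
    DegenerateGeometryError,
    FrameError,
    RegistrationRejectedError,
)
from .geometry import RigidTransform, Rotation, as_point, as_points

__all__ = [
    "LandmarkSet",
    "RegistrationResult",
    "horn_register",
    "horn_register_arrays",
    "compute_fre",
    "compute_tre",
    "center_of_gravity",
    "fitzpatrick_tre_squared",
    "registration_session",
    "FREThresholdPolicy",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Named, ordered 3-D points in a declared frame; order defines correspondence."""

    names: tuple
    points: np.ndarray
    frame: str = "plan"

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "points", as_points(self.points))
        if len(self.names) != len(self.points):
            raise CorrespondenceError(
                f"{len(self.names)} names but {len(self.points)} points"
            )
        if len(set(self.names)) != len(self.names):
            raise CorrespondenceError("landmark names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no landmark named {name!r}") from None

    def subset(self, names: Sequence[str]) -> "LandmarkSet":
        return LandmarkSet(tuple(names), np.array([self[n] for n in names]), self.frame)

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        if t.source_frame != self.frame:
            raise FrameError(
                f"transform expects frame {t.source_frame!r}, landmarks are in {self.frame!r}"
            )
        return LandmarkSet(self.names, t.apply(self.points), t.target_frame)


@dataclass(frozen=True)
class RegistrationResult:
    """One registration attempt: transform plus its error metrics."""

    transform: RigidTransform  # plan frame -> reference frame
    fre_mm: float
    tre_mm: Mapping[str, float] = field(default_factory=dict)
    attempt_index: int = 1
    accepted: bool = True


def _check_pair(moving: LandmarkSet, fixed: LandmarkSet) -> None:
    if len(moving) != len(fixed):
        raise CorrespondenceError(
            f"cardinality mismatch: {len(moving)} moving vs {len(fixed)} fixed landmarks"
        )
    if len(moving) < 3:
        raise DegenerateGeometryError("registration requires at least 3 landmark pairs")
    centered = moving.points - moving.points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("moving landmarks are (near-)collinear")


def _horn_quat(cross_cov: np.ndarray) -> np.ndarray:
    """Quaternion(s) maximizing the Horn criterion for cross-covariance S.

    ``cross_cov``: (..., 3, 3) with S = sum_i p_i' q_i'^T over centred pairs.
    Returns (..., 4) unit quaternions (w, x, y, z), sign-canonicalized.
    """
    S = cross_cov
    Sxx, Sxy, Sxz = S[..., 0, 0], S[..., 0, 1], S[..., 0, 2]
    Syx, Syy, Syz = S[..., 1, 0], S[..., 1, 1], S[..., 1, 2]
    Szx, Szy, Szz = S[..., 2, 0], S[..., 2, 1], S[..., 2, 2]
    N = np.empty(S.shape[:-2] + (4, 4), dtype=float)
    N[..., 0, 0] = Sxx + Syy + Szz
    N[..., 0, 1] = N[..., 1, 0] = Syz - Szy
    N[..., 0, 2] = N[..., 2, 0] = Szx - Sxz
    N[..., 0, 3] = N[..., 3, 0] = Sxy - Syx
    N[..., 1, 1] = Sxx - Syy - Szz
    N[..., 1, 2] = N[..., 2, 1] = Sxy + Syx
    N[..., 1, 3] = N[..., 3, 1] = Szx + Sxz
    N[..., 2, 2] = -Sxx + Syy - Szz
    N[..., 2, 3] = N[..., 3, 2] = Syz + Szy
    N[..., 3, 3] = -Sxx - Syy + Szz
    _, vecs = np.linalg.eigh(N)  # ascending eigenvalues
    quat = vecs[..., :, -1]
    sign = np.where(quat[..., :1] < 0, -1.0, 1.0)
    return quat * sign


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Batched unit quaternion (w,x,y,z) -> rotation matrix, shape (..., 3, 3)."""
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3), dtype=float)
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def horn_register_arrays(moving: np.ndarray, fixed: np.ndarray):
    """Vectorized Horn solution on raw arrays.

    Parameters
    ----------
    moving : (N, 3) array
    fixed : (..., N, 3) array — arbitrary batch dimensions in front.

    Returns
    -------
    R : (..., 3, 3) rotation matrices, det +1
    t : (..., 3) translations, such that ``R @ moving + t ~= fixed``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    mc = moving.mean(axis=-2)
    fc = fixed.mean(axis=-2)
    p = moving - mc
    q = fixed - fc[..., None, :]
    # S = sum_i p_i q_i^T, batched over leading dims of `fixed`
    S = np.einsum("ia,...ib->...ab", p, q)
    quat = _horn_quat(S)
    R = _quat_to_matrix(quat)
    t = fc - np.einsum("...ab,b->...a", R, mc)
    return R, t


def horn_register(moving: LandmarkSet, fixed: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform taking ``moving`` onto ``fixed``.

    Correspondence is by order.  Raises
    :class:`~emnav.errors.DegenerateGeometryError` for fewer than 3 or
    collinear points and :class:`~emnav.errors.CorrespondenceError` on a
    cardinality mismatch.
    """
    _check_pair(moving, fixed)
    mc = moving.points.mean(axis=0)
    fc = fixed.points.mean(axis=0)
    quat = _horn_quat(np.einsum("ia,ib->ab", moving.points - mc, fixed.points - fc))
    rot = Rotation(quat)
    return RigidTransform(rot, fc - rot.apply(mc), moving.frame, fixed.frame)


def compute_fre(
    t: RigidTransform, moving: LandmarkSet, fixed: LandmarkSet, kind: str = "rms"
) -> float:
    """Fiducial registration error of ``t`` on the given correspondence.

    ``kind="rms"`` (default): root-mean-square residual distance;
    ``kind="mean"``: mean absolute residual distance.
    """
    if len(moving) != len(fixed):
        raise CorrespondenceError("moving and fixed landmark counts differ")
    residuals = np.linalg.norm(t.apply(moving.points) - fixed.points, axis=1)
    if kind == "rms":
        return float(np.sqrt(np.mean(residuals**2)))
    if kind == "mean":
        return float(np.mean(residuals))
    raise ValueError(f"unknown FRE kind {kind!r} (expected 'rms' or 'mean')")


def compute_tre(
    estimated: RigidTransform,
    target,
    truth: Optional[RigidTransform] = None,
    measured_point=None,
) -> float:
    """Target registration error at ``target`` (a plan-frame point).

    Exactly one of ``truth`` (simulation mode: the known ground-truth
    transform) or ``measured_point`` (physical/replay mode: a probe-acquired
    position of the target in the fixed frame) must be given.
    """
    if (truth is None) == (measured_point is None):
        raise ValueError("provide exactly one of `truth` or `measured_point`")
    target = as_point(target)
    if truth is not None:
        if (
            truth.source_frame != estimated.source_frame
            or truth.target_frame != estimated.target_frame
        ):
            raise FrameError("estimated and truth transforms must map the same frames")
        reference_position = truth.apply(target)
    else:
        reference_position = as_point(measured_point)
    return float(np.linalg.norm(estimated.apply(target) - reference_position))


def center_of_gravity(cloud) -> np.ndarray:
    """Unweighted centroid of a point cloud (the graft's TRE-CENTER target)."""
    pts = as_points(cloud)
    if len(pts) == 0:
        raise DegenerateGeometryError("cannot take the centroid of an empty cloud")
    return pts.mean(axis=0)


def fitzpatrick_tre_squared(fiducials, target, fle_squared_mm2: float) -> float:
    """Expected squared TRE at ``target`` for fiducial localization error FLE.

    ``fle_squared_mm2`` is E[|FLE|^2] (for isotropic per-axis noise sigma this
    is 3*sigma^2).  Principal axes are those of the fiducial configuration.
    """
    fids = as_points(fiducials)
    target = as_point(target)
    n = len(fids)
    centered = fids - fids.mean(axis=0)
    # principal axes: eigenvectors of the configuration's scatter matrix
    _, _, axes = np.linalg.svd(centered, full_matrices=False)
    rel = target - fids.mean(axis=0)
    ratio = 0.0
    for axis in axes:
        d2 = np.sum(rel**2) - np.dot(rel, axis) ** 2  # target dist^2 from axis
        f2 = np.mean(np.sum(centered**2, axis=1) - (centered @ axis) ** 2)
        ratio += d2 / f2
    return fle_squared_mm2 / n * (1.0 + ratio / 3.0)


class FREThresholdPolicy:
    """Accept an attempt when FRE and every TRE fall under their thresholds."""

    def __init__(self, fre_mm: float, tre_mm: Optional[float] = None):
        self.fre_mm = fre_mm
        self.tre_mm = tre_mm

    def __call__(self, result: RegistrationResult) -> bool:
        if result.fre_mm > self.fre_mm:
            return False
        if self.tre_mm is not None and any(v > self.tre_mm for v in result.tre_mm.values()):
            return False
        return True


def registration_session(
    plan_landmarks: LandmarkSet,
    acquire_fn: Callable[[int], LandmarkSet],
    targets: Mapping[str, np.ndarray],
    accept_policy: Callable[[RegistrationResult], bool],
    truth: Optional[RigidTransform] = None,
    measured_targets: Optional[Mapping[str, np.ndarray]] = None,
    max_attempts: int = 10,
    fre_kind: str = "rms",
) -> RegistrationResult:
    """Repeat-attempt registration loop.

    Each attempt calls ``acquire_fn(attempt_index)`` for a freshly acquired
    fixed landmark set, registers, computes FRE and the TREs at ``targets``
    (plan-frame points, evaluated against ``truth`` or ``measured_targets``),
    and stops at the first attempt ``accept_policy`` accepts.  No default
    acceptance threshold exists — patient-specific judgement is the policy's
    job — so the policy object is required.

    Raises :class:`~emnav.errors.RegistrationRejectedError` carrying the
    best (lowest-FRE) attempt when ``max_attempts`` is exhausted.
    """
    best: Optional[RegistrationResult] = None
    for attempt in range(1, max_attempts + 1):
        fixed = acquire_fn(attempt)
        transform = horn_register(plan_landmarks, fixed)
        fre = compute_fre(transform, plan_landmarks, fixed, kind=fre_kind)
        tre = {}
        for label, point in targets.items():
            if truth is not None:
                tre[label] = compute_tre(transform, point, truth=truth)
            elif measured_targets is not None:
                tre[label] = compute_tre(
                    transform, point, measured_point=measured_targets[label]
                )
        result = RegistrationResult(transform, fre, tre, attempt, accepted=False)
        if best is None or result.fre_mm < best.fre_mm:
            best = result
        if accept_policy(result):
            return RegistrationResult(transform, fre, tre, attempt, accepted=True)
    raise RegistrationRejectedError(
        f"no attempt accepted after {max_attempts} tries (best FRE "
        f"{best.fre_mm:.2f} mm on attempt {best.attempt_index})",
        best_attempt=best,
    )
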