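"""Synthetic phantom and tracking-data generator with known ground truth.

A desk-scale stand-in for the model surgeries: a parametric mandible-like
geometry (prism segments along a circular arc — anatomical realism is
irrelevant to the mathematics being exercised), EMT sensors rigidly mounted
on the residual mandible and the graft, a reference sensor on immobile
anatomy, and pose/probe streams with configurable noise.  Every quantity the
pipeline estimates (registration transforms, FRE/TRE, placement deviations)
has an exactly known truth; with all noise parameters at zero the full
pipeline must recover that truth to machine precision.

The graft is modelled as 2-4 fibular segments laid out as a polyline of
connected prisms: segment 1 carries the reconstructed condyle (CON), the
corner between segments 1 and 2 is the mandibular angle (ANG), and the graft
end adjacent to the residual mandible is the junction (JUN).  Noise model:
isotropic Gaussian positional fiducial-localization error plus independent
small-angle Gaussian orientation noise per pose sample (default positional
sigma 0.3 mm, the order of EMT accuracy; real sensor noise for a clinical
stack is hardware-specific and not calibrated here).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import SpecError
from .geometry import PoseSample, RigidTransform, Rotation
from .navigation import PlannedObject
from .registration import LandmarkSet

__all__ = [
    "PhantomSpec",
    "SyntheticCase",
    "generate_phantom",
    "simulate_probe_stream",
    "simulate_placement",
    "random_rigid_transform",
]

TRACKER = "tracker"
PLAN = "plan"
REFERENCE_SENSOR = "reference"
#: frame label of the reference sensor; all navigation happens in this frame
REFERENCE_FRAME = "sensor:reference"
MANDIBLE_SENSOR = "mandible"
GRAFT_SENSOR = "graft"

_MAX_PLACEMENT_TRANSLATION_MM = 20.0
_MAX_PLACEMENT_ANGLE_DEG = 15.0


@dataclass(frozen=True)
class PhantomSpec:
    """Stated world of one synthetic case.

    Cloud sizes are dense enough to exercise per-point coloring while
    keeping a 25 Hz tick trivial; 5 fiducials per object reflect a typical
    landmark-based clinical registration; 3 segments match a common fibular
    reconstruction (2-4 occur).
    """

    seed: int = 0
    mandible_cloud_size: int = 400
    graft_cloud_size: int = 300
    n_fiducials_mandible: int = 5
    n_fiducials_graft: int = 5
    n_segments: int = 3
    graft_shape_error_mm: float = 0.0
    fle_sigma_mm: float = 0.3
    orientation_sigma_deg: float = 0.05
    stream_rate_hz: float = 40.0
    nav_rate_hz: float = 25.0
    stream_duration_s: float = 1.0
    landmarks_per_segment: int = 3

    def __post_init__(self):
        if not 2 <= self.n_segments <= 4:
            raise SpecError("n_segments must be in 2..4")
        if self.n_fiducials_mandible < 4 or self.n_fiducials_graft < 4:
            raise SpecError("at least 4 fiducials per object are required")
        if self.graft_shape_error_mm < 0 or self.fle_sigma_mm < 0:
            raise SpecError("noise magnitudes must be non-negative")
        if self.mandible_cloud_size < 1 or self.graft_cloud_size < 1:
            raise SpecError("cloud sizes must be positive")


@dataclass
class SyntheticCase:
    """A generated phantom case with its full ground truth."""

    spec: PhantomSpec
    mandible: PlannedObject
    graft: PlannedObject
    segment_assignment: Dict[str, int]  # graft landmark name -> segment number
    truth_registration: Dict[str, RigidTransform]  # object id -> plan->reference
    truth_final_pose: RigidTransform  # graft plan->reference after placement
    sensor_mounts: Dict[str, RigidTransform]  # sensor id -> sensor frame->plan frame
    reference_pose: RigidTransform  # reference sensor frame -> tracker
    streams: Dict[str, List[PoseSample]] = field(default_factory=dict)

    def true_landmark_in_reference(self, name: str) -> np.ndarray:
        """Registered (reference-frame) position of a named landmark."""
        for obj in (self.mandible, self.graft):
            if obj.landmarks is not None and name in obj.landmarks.names:
                return self.truth_registration[obj.object_id].apply(obj.landmarks[name])
        raise KeyError(f"no landmark named {name!r} in this case")

    def placement_deviation(self, name: str) -> float:
        """Distance (mm) a graft landmark ended up from its planned position."""
        x = self.graft.landmarks[name]
        return float(
            np.linalg.norm(
                self.truth_final_pose.apply(x)
                - self.truth_registration[self.graft.object_id].apply(x)
            )
        )


def _rng_for(seed: int, label: str) -> np.random.Generator:
    """Named substream: independent generator derived from the global seed.

    The label is folded in through a stable digest (Python's ``hash`` is
    salted per process and would break run-to-run determinism).
    """
    digest = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(digest,)))


def random_rigid_transform(
    rng: np.random.Generator,
    max_translation_mm: float = 50.0,
    source_frame: str = PLAN,
    target_frame: str = REFERENCE_FRAME,
) -> RigidTransform:
    """Uniformly random rotation plus bounded uniform translation."""
    q = rng.normal(size=4)
    rot = Rotation(q / np.linalg.norm(q))
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(rot, t, source_frame, target_frame)


def _prism_cloud(rng, start, end, half_width: float, n_points: int) -> np.ndarray:
    """Points on the surface of a square prism from ``start`` to ``end``."""
    axis = end - start
    length = np.linalg.norm(axis)
    u = axis / length
    # build an orthonormal cross-section basis
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    s = rng.uniform(0.0, length, size=n_points)
    face = rng.integers(0, 4, size=n_points)
    offset = rng.uniform(-half_width, half_width, size=n_points)
    a = np.where(face < 2, np.where(face == 0, half_width, -half_width), offset)
    b = np.where(face < 2, offset, np.where(face == 2, half_width, -half_width))
    return start + s[:, None] * u + a[:, None] * v + b[:, None] * w


def _split_count(total: int, parts: int) -> List[int]:
    """Distribute ``total`` points over ``parts`` chunks, remainders first."""
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _arc_point(angle_deg: float, radius: float = 50.0) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), 0.0])


def generate_phantom(spec: PhantomSpec) -> SyntheticCase:
    """Build a deterministic synthetic case from ``spec`` (same seed, same case).

    Plan-frame geometry: the residual mandible spans the arc from -90 deg to
    0 deg of a 50 mm circle, the graft continues from 0 deg to +90 deg as
    ``n_segments`` straight prism segments whose far end (segment 1) carries
    the condyle.  Fiducials are sampled on each object's surface and checked
    for non-collinearity; per-segment artificial landmarks emulate the
    measurement points glued onto the physical phantoms.
    """
    rng_geom = _rng_for(spec.seed, "geometry")

    # residual mandible: polyline of prisms along the -90..0 deg arc
    mand_angles = np.linspace(-90.0, 0.0, 4)
    mand_nodes = [_arc_point(a) for a in mand_angles]
    counts = _split_count(spec.mandible_cloud_size, len(mand_nodes) - 1)
    mand_cloud = np.vstack(
        [
            _prism_cloud(rng_geom, mand_nodes[i], mand_nodes[i + 1], 5.0, counts[i])
            for i in range(len(mand_nodes) - 1)
        ]
    )

    # graft: n_segments prisms along 0..+90 deg; segment 1 at the condylar end
    graft_angles = np.linspace(0.0, 90.0, spec.n_segments + 1)
    graft_nodes = [_arc_point(a) for a in graft_angles]
    seg_clouds = []
    counts = _split_count(spec.graft_cloud_size, spec.n_segments)
    for i in range(spec.n_segments):
        seg_clouds.append(
            _prism_cloud(rng_geom, graft_nodes[i], graft_nodes[i + 1], 5.0, counts[i])
        )
    graft_cloud = np.vstack(seg_clouds)
    if spec.graft_shape_error_mm > 0:
        # the physical graft assembled from osteotomized segments never matches
        # the planned shape exactly; emulate with smooth per-segment warping
        graft_cloud = graft_cloud + rng_geom.normal(
            scale=spec.graft_shape_error_mm / np.sqrt(3.0), size=graft_cloud.shape
        )

    # graft node ordering: node[-1] is at 90 deg (condylar end, segment 1),
    # node[0] at 0 deg (junction to the residual mandible)
    seg_number = {i: spec.n_segments - i for i in range(spec.n_segments)}

    def _segment_landmarks() -> Tuple[List[str], List[np.ndarray], Dict[str, int]]:
        names, pts, assign = [], [], {}
        for i in range(spec.n_segments):
            segno = seg_number[i]
            a, b = graft_nodes[i], graft_nodes[i + 1]
            for j in range(spec.landmarks_per_segment):
                frac = (j + 1) / (spec.landmarks_per_segment + 1)
                name = f"S{segno}_L{j + 1}"
                names.append(name)
                # offset off-axis so landmark sets are never collinear
                perp = np.array([0.0, 0.0, 5.0 if j % 2 else -5.0])
                pts.append(a + frac * (b - a) + perp)
                assign[name] = segno
        return names, pts, assign

    seg_names, seg_pts, segment_assignment = _segment_landmarks()
    con = graft_nodes[-1] + np.array([0.0, 0.0, 8.0])  # condylar head, off-plane
    ang = graft_nodes[-2]  # corner between segments 1 and 2
    jun = graft_nodes[0]  # junction with the residual mandible
    for name, pt in (("CON", con), ("ANG", ang), ("JUN", jun)):
        seg_names.append(name)
        seg_pts.append(pt)
    segment_assignment["CON"] = 1

    def _fiducials(rng, cloud, n, prefix) -> LandmarkSet:
        for _ in range(100):
            idx = rng.choice(len(cloud), size=n, replace=False)
            pts = cloud[idx]
            centered = pts - pts.mean(axis=0)
            s = np.linalg.svd(centered, compute_uv=False)
            if s[1] > 1e-6 * max(s[0], 1.0):
                return LandmarkSet(
                    tuple(f"{prefix}_F{i + 1}" for i in range(n)), pts, PLAN
                )
        raise SpecError(f"could not draw {n} non-collinear fiducials for {prefix}")

    mand_fids = _fiducials(rng_geom, mand_cloud, spec.n_fiducials_mandible, "M")
    graft_fids = _fiducials(rng_geom, graft_cloud, spec.n_fiducials_graft, "G")

    graft_landmarks = LandmarkSet(
        tuple(graft_fids.names) + tuple(seg_names),
        np.vstack([graft_fids.points, np.array(seg_pts)]),
        PLAN,
    )
    mandible = PlannedObject("residual_mandible", mand_cloud, mand_fids, frame=PLAN)
    graft = PlannedObject("graft", graft_cloud, graft_landmarks, frame=PLAN)

    rng_pose = _rng_for(spec.seed, "poses")
    truth_registration = {
        "residual_mandible": random_rigid_transform(rng_pose, 30.0),
        "graft": random_rigid_transform(rng_pose, 30.0),
    }
    sensor_mounts = {
        MANDIBLE_SENSOR: random_rigid_transform(
            rng_pose, 20.0, source_frame=f"sensor:{MANDIBLE_SENSOR}", target_frame=PLAN
        ),
        GRAFT_SENSOR: random_rigid_transform(
            rng_pose, 20.0, source_frame=f"sensor:{GRAFT_SENSOR}", target_frame=PLAN
        ),
    }
    reference_pose = random_rigid_transform(
        rng_pose, 100.0, source_frame=REFERENCE_FRAME, target_frame=TRACKER
    )

    case = SyntheticCase(
        spec=spec,
        mandible=mandible,
        graft=graft,
        segment_assignment=segment_assignment,
        truth_registration=truth_registration,
        truth_final_pose=truth_registration["graft"],
        sensor_mounts=sensor_mounts,
        reference_pose=reference_pose,
        streams={},
    )
    case.streams = _generate_streams(case)
    return case


def _object_for_sensor(sensor_id: str) -> str:
    return "residual_mandible" if sensor_id == MANDIBLE_SENSOR else "graft"


def _generate_streams(case: SyntheticCase) -> Dict[str, List[PoseSample]]:
    """Pose streams (sensor -> tracker) for reference, mandible and graft sensors."""
    spec = case.spec
    rng = {s: _rng_for(spec.seed, f"stream:{s}") for s in
           (REFERENCE_SENSOR, MANDIBLE_SENSOR, GRAFT_SENSOR)}
    n = max(2, int(round(spec.stream_rate_hz * spec.stream_duration_s)))
    times = np.arange(n) / spec.stream_rate_hz
    streams: Dict[str, List[PoseSample]] = {s: [] for s in rng}
    for t in times:
        for sensor_id, generator in rng.items():
            if sensor_id == REFERENCE_SENSOR:
                exact = case.reference_pose
            else:
                obj_id = _object_for_sensor(sensor_id)
                pose_plan_ref = (
                    case.truth_final_pose
                    if obj_id == "graft"
                    else case.truth_registration[obj_id]
                )
                exact = case.reference_pose.compose(pose_plan_ref).compose(
                    case.sensor_mounts[sensor_id]
                )
            streams[sensor_id].append(
                PoseSample(float(t), sensor_id, _noisy_pose(exact, spec, generator))
            )
    return streams


def _noisy_pose(exact: RigidTransform, spec: PhantomSpec, rng) -> RigidTransform:
    if spec.fle_sigma_mm == 0 and spec.orientation_sigma_deg == 0:
        return exact
    dt = rng.normal(scale=spec.fle_sigma_mm, size=3) if spec.fle_sigma_mm else np.zeros(3)
    if spec.orientation_sigma_deg:
        rotvec = rng.normal(scale=np.deg2rad(spec.orientation_sigma_deg), size=3)
        drot = Rotation.from_axis_angle(rotvec / max(np.linalg.norm(rotvec), 1e-15),
                                        np.linalg.norm(rotvec))
    else:
        drot = Rotation.identity()
    return RigidTransform(
        drot @ exact.rotation, exact.translation + dt, exact.source_frame, exact.target_frame
    )


def simulate_probe_stream(
    case: SyntheticCase,
    landmark_name: str,
    tremble_sigma_mm: float = 0.1,
    slip_events: Sequence[Tuple[int, float]] = (),
    seed: Optional[int] = None,
    n_points: Optional[int] = None,
) -> np.ndarray:
    """Probe-tip points (reference frame) while holding the probe on a landmark.

    ``tremble_sigma_mm`` is the per-axis Gaussian hand tremor.  Each
    ``(index, magnitude_mm)`` slip event displaces the probe from that sample
    onward by a random direction of the stated magnitude — the probe slipped
    and now rests at a new position, which the acquisition restart rule must
    detect whenever the magnitude exceeds its step threshold.
    """
    truth = case.true_landmark_in_reference(landmark_name)
    rng = _rng_for(case.spec.seed if seed is None else seed, f"probe:{landmark_name}")
    if n_points is None:
        n_points = 60 * (len(slip_events) + 1) + 60
    pts = np.tile(truth, (n_points, 1))
    if tremble_sigma_mm > 0:
        pts = pts + rng.normal(scale=tremble_sigma_mm, size=pts.shape)
    for index, magnitude in slip_events:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts[index:] += magnitude * direction
    return pts


def simulate_placement(case: SyntheticCase, placement_error: RigidTransform) -> SyntheticCase:
    """Apply a graft placement error and refresh the affected streams.

    ``placement_error`` is expressed in the plan frame (maps planned graft
    coordinates to where the surgeon actually fixed them); magnitudes are
    limited to 20 mm / 15 deg — beyond that the scenario is no longer a
    plausible fixation error.  Returns a new case; CON/ANG/JUN displacements
    follow from the truth via :meth:`SyntheticCase.placement_deviation`.
    """
    if placement_error.source_frame != PLAN or placement_error.target_frame != PLAN:
        raise SpecError("placement error must map the plan frame to itself")
    if np.linalg.norm(placement_error.translation) > _MAX_PLACEMENT_TRANSLATION_MM:
        raise SpecError("placement translation exceeds 20 mm")
    if np.rad2deg(placement_error.rotation.angle_rad) > _MAX_PLACEMENT_ANGLE_DEG:
        raise SpecError("placement rotation exceeds 15 degrees")
    updated = dataclasses.replace(
        case,
        truth_final_pose=case.truth_registration["graft"].compose(placement_error),
    )
    updated.streams = _generate_streams(updated)
    return updated
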