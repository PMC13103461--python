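"""Real-time bone-segment guidance: distance maps and color coding.

The tracked and planned bone segments are the *same* virtual point cloud, so
deviation is measured point-by-point at matching indices — no nearest
neighbour search, which would hide rotational error behind surface symmetry.
For each point ``k`` the deviation is the Euclidean distance

    d_k = sqrt(sum_i (q_{k,i} - p_{k,i})^2)

between the tracked position ``p_k`` and its planned counterpart ``q_k``.
The distances are painted onto the tracked cloud through a color scale
running from dark green (deviation below 1.0 mm) to dark red (above
4.0 mm); a renderer consumes the colored points, this module stays headless.

Scene updates are driven by relative sensor poses: the cloud registered at
time of registration is carried along by the sensor's motion since then,
``current = (rel_pose_now ∘ invert(rel_pose_at_registration)) ∘ registered``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .errors import CorrespondenceError, FrameError
from .geometry import RigidTransform, Rotation, as_points, compose
from .registration import LandmarkSet

__all__ = [
    "PlannedObject",
    "DistanceMap",
    "ColorScale",
    "NavigationScene",
    "tracked_cloud",
    "pointwise_distance",
    "color_encode",
    "navigation_tick",
    "snapshot",
    "load_snapshot",
    "DARK_GREEN",
    "DARK_RED",
]

# X11 darkgreen / darkred, as RGB floats in [0, 1]
DARK_GREEN = (0.0, 100 / 255, 0.0)
DARK_RED = (139 / 255, 0.0, 0.0)
_YELLOW = (1.0, 1.0, 0.0)
_ORANGE = (1.0, 165 / 255, 0.0)


@dataclass(frozen=True)
class PlannedObject:
    """A planned bone segment: its point cloud, landmarks and target pose.

    The plan itself defines the target position, so ``target_pose`` defaults
    to the identity on the plan frame.
    """

    object_id: str
    cloud: np.ndarray
    landmarks: Optional[LandmarkSet] = None
    target_pose: Optional[RigidTransform] = None
    frame: str = "plan"

    def __post_init__(self):
        object.__setattr__(self, "cloud", as_points(self.cloud))
        if len(self.cloud) == 0:
            raise ValueError("planned object cloud must be non-empty")
        if self.landmarks is not None and self.landmarks.frame != self.frame:
            raise FrameError(
                f"landmarks are in frame {self.landmarks.frame!r}, object in {self.frame!r}"
            )
        if self.target_pose is None:
            object.__setattr__(self, "target_pose", RigidTransform.identity(self.frame))


@dataclass(frozen=True)
class DistanceMap:
    """Per-point deviations of one tracked object from its plan, plus colors."""

    object_id: str
    distances_mm: np.ndarray
    colors: Optional[np.ndarray] = None
    timestamp: float = 0.0
    tracking_lost: bool = False

    def __post_init__(self):
        d = np.asarray(self.distances_mm, dtype=float)
        if d.ndim != 1 or np.any(d < 0):
            raise ValueError("distances must be a 1-D array of non-negative values")
        object.__setattr__(self, "distances_mm", d)
        if self.colors is not None:
            c = np.asarray(self.colors, dtype=float)
            if c.shape != (len(d), 3):
                raise CorrespondenceError("colors must be an (N, 3) RGB array")
            object.__setattr__(self, "colors", c)

    def summary(self, under_mm: float = 1.0) -> Dict[str, float]:
        d = self.distances_mm
        return {
            "min_mm": float(d.min()),
            "max_mm": float(d.max()),
            "mean_mm": float(d.mean()),
            "fraction_under": float(np.mean(d < under_mm)),
        }


@dataclass(frozen=True)
class ColorScale:
    """Maps deviation (mm) to RGB.

    Below ``lower_mm`` every point gets exactly ``lower_color``; above
    ``upper_mm`` exactly ``upper_color``.  In between, ``continuous`` mode
    interpolates linearly through the optional ``midpoint_colors`` (evenly
    spaced), ``binned`` mode steps in bins of ``bin_width_mm`` colored at
    their centres.  The map is monotone: larger deviation never looks
    greener.
    """

    lower_mm: float = 1.0
    upper_mm: float = 4.0
    lower_color: Tuple[float, float, float] = DARK_GREEN
    upper_color: Tuple[float, float, float] = DARK_RED
    midpoint_colors: Tuple[Tuple[float, float, float], ...] = (_YELLOW, _ORANGE)
    interpolation: str = "continuous"
    bin_width_mm: float = 1.0

    def __post_init__(self):
        if not self.lower_mm < self.upper_mm:
            raise ValueError("lower_mm must be strictly below upper_mm")
        if self.interpolation not in ("continuous", "binned"):
            raise ValueError("interpolation must be 'continuous' or 'binned'")
        if self.bin_width_mm <= 0:
            raise ValueError("bin_width_mm must be positive")

    def severity(self, distances) -> np.ndarray:
        """Normalized position on the scale in [0, 1]; monotone in distance."""
        d = np.asarray(distances, dtype=float)
        t = np.clip((d - self.lower_mm) / (self.upper_mm - self.lower_mm), 0.0, 1.0)
        if self.interpolation == "binned":
            span = self.upper_mm - self.lower_mm
            edges = np.arange(0.0, span, self.bin_width_mm)
            centers = np.minimum(edges + self.bin_width_mm / 2.0, span) / span
            idx = np.clip(
                np.floor((d - self.lower_mm) / self.bin_width_mm).astype(int),
                0,
                len(edges) - 1,
            )
            t_binned = centers[idx]
            t = np.where(d < self.lower_mm, 0.0, np.where(d > self.upper_mm, 1.0, t_binned))
        return t

    def colors(self, distances) -> np.ndarray:
        """RGB for each distance, shape (N, 3)."""
        t = np.atleast_1d(self.severity(distances))
        stops = np.array([self.lower_color, *self.midpoint_colors, self.upper_color])
        positions = np.linspace(0.0, 1.0, len(stops))
        rgb = np.column_stack(
            [np.interp(t, positions, stops[:, ch]) for ch in range(3)]
        )
        return rgb


def tracked_cloud(
    obj: PlannedObject,
    registration: RigidTransform,
    sensor_rel_pose_now: RigidTransform,
    sensor_rel_pose_at_registration: RigidTransform,
) -> np.ndarray:
    """Current positions of the object's cloud in the reference frame.

    ``registration`` maps plan -> reference at registration time; the motion
    of the bone since then is the sensor's relative-pose change.  If the bone
    has not moved, the result equals the registered cloud.
    """
    if registration.source_frame != obj.frame:
        raise FrameError(
            f"registration expects frame {registration.source_frame!r}, "
            f"object is in {obj.frame!r}"
        )
    motion = compose(sensor_rel_pose_now, sensor_rel_pose_at_registration.invert())
    current = compose(motion, registration)
    return current.apply(obj.cloud)


def pointwise_distance(
    tracked, planned, object_id: str = "", timestamp: float = 0.0
) -> DistanceMap:
    """Index-matched Euclidean distances between tracked and planned clouds."""
    p = as_points(tracked)
    q = as_points(planned)
    if len(p) != len(q):
        raise CorrespondenceError(
            f"tracked cloud has {len(p)} points, planned cloud {len(q)}"
        )
    d = np.linalg.norm(q - p, axis=1)
    return DistanceMap(object_id=object_id, distances_mm=d, timestamp=timestamp)


def color_encode(dmap: DistanceMap, scale: ColorScale = ColorScale()) -> DistanceMap:
    """Return a copy of ``dmap`` with colors filled from ``scale``."""
    return replace(dmap, colors=scale.colors(dmap.distances_mm))


@dataclass
class NavigationScene:
    """Registered objects plus the pose bookkeeping needed per tick."""

    objects: Dict[str, PlannedObject] = field(default_factory=dict)
    registrations: Dict[str, RigidTransform] = field(default_factory=dict)
    rel_pose_at_registration: Dict[str, RigidTransform] = field(default_factory=dict)
    sensor_for: Dict[str, str] = field(default_factory=dict)
    last_rel_pose: Dict[str, RigidTransform] = field(default_factory=dict)
    last_pose_time: Dict[str, float] = field(default_factory=dict)
    last_maps: Dict[str, DistanceMap] = field(default_factory=dict)
    scale: ColorScale = field(default_factory=ColorScale)
    rate_hz: float = 25.0
    stale_timeout_s: float = 0.5

    def add_object(
        self,
        obj: PlannedObject,
        registration: RigidTransform,
        sensor_id: str,
        rel_pose_at_registration: RigidTransform,
    ) -> None:
        self.objects[obj.object_id] = obj
        self.registrations[obj.object_id] = registration
        self.sensor_for[obj.object_id] = sensor_id
        self.rel_pose_at_registration[obj.object_id] = rel_pose_at_registration
        self.last_rel_pose[obj.object_id] = rel_pose_at_registration
        self.last_pose_time[obj.object_id] = 0.0


def navigation_tick(
    scene: NavigationScene,
    pose_updates: Mapping[str, RigidTransform],
    timestamp: float,
) -> Dict[str, DistanceMap]:
    """One update cycle: refresh poses, recompute distances and colors.

    ``pose_updates`` maps sensor id to the sensor's current relative pose
    (already in the reference frame).  Objects whose sensor has not reported
    within ``scene.stale_timeout_s`` are flagged ``tracking_lost`` and keep
    their previous distances and colors.  Deterministic given the poses.
    """
    maps: Dict[str, DistanceMap] = {}
    for object_id, obj in scene.objects.items():
        sensor_id = scene.sensor_for[object_id]
        if sensor_id in pose_updates:
            scene.last_rel_pose[object_id] = pose_updates[sensor_id]
            scene.last_pose_time[object_id] = timestamp
        stale = timestamp - scene.last_pose_time[object_id] > scene.stale_timeout_s
        if stale and object_id in scene.last_maps:
            maps[object_id] = replace(
                scene.last_maps[object_id], tracking_lost=True, timestamp=timestamp
            )
            continue
        current = tracked_cloud(
            obj,
            scene.registrations[object_id],
            scene.last_rel_pose[object_id],
            scene.rel_pose_at_registration[object_id],
        )
        planned = obj.target_pose.apply(obj.cloud)
        dmap = pointwise_distance(current, planned, object_id, timestamp)
        dmap = color_encode(dmap, scene.scale)
        maps[object_id] = replace(dmap, tracking_lost=stale)
        scene.last_maps[object_id] = maps[object_id]
    return maps


# ---------------------------------------------------------------------------
# Scene snapshots: a JSON record of the final navigation state, sufficient to
# re-evaluate every distance map bit-for-bit after loading.
# ---------------------------------------------------------------------------


def _transform_to_dict(t: RigidTransform) -> dict:
    return {
        "q": t.rotation.quat.tolist(),
        "p": t.translation.tolist(),
        "source_frame": t.source_frame,
        "target_frame": t.target_frame,
    }


def _transform_from_dict(d: dict) -> RigidTransform:
    return RigidTransform(
        Rotation(np.array(d["q"])), np.array(d["p"]), d["source_frame"], d["target_frame"]
    )


def snapshot(scene: NavigationScene, path) -> None:
    """Serialize the scene to JSON (clouds, transforms, maps, timestamps)."""
    payload = {
        "format": "emnav-scene",
        "version": 1,
        "rate_hz": scene.rate_hz,
        "stale_timeout_s": scene.stale_timeout_s,
        "scale": {
            "lower_mm": scene.scale.lower_mm,
            "upper_mm": scene.scale.upper_mm,
            "lower_color": list(scene.scale.lower_color),
            "upper_color": list(scene.scale.upper_color),
            "midpoint_colors": [list(c) for c in scene.scale.midpoint_colors],
            "interpolation": scene.scale.interpolation,
            "bin_width_mm": scene.scale.bin_width_mm,
        },
        "objects": [],
    }
    for object_id, obj in scene.objects.items():
        entry = {
            "object_id": object_id,
            "frame": obj.frame,
            "cloud": obj.cloud.tolist(),
            "target_pose": _transform_to_dict(obj.target_pose),
            "sensor_id": scene.sensor_for[object_id],
            "registration": _transform_to_dict(scene.registrations[object_id]),
            "rel_pose_at_registration": _transform_to_dict(
                scene.rel_pose_at_registration[object_id]
            ),
            "last_rel_pose": _transform_to_dict(scene.last_rel_pose[object_id]),
            "last_pose_time": scene.last_pose_time[object_id],
        }
        if obj.landmarks is not None:
            entry["landmarks"] = {
                "names": list(obj.landmarks.names),
                "points": obj.landmarks.points.tolist(),
                "frame": obj.landmarks.frame,
            }
        if object_id in scene.last_maps:
            m = scene.last_maps[object_id]
            entry["distance_map"] = {
                "distances_mm": m.distances_mm.tolist(),
                "colors": None if m.colors is None else m.colors.tolist(),
                "timestamp": m.timestamp,
                "tracking_lost": m.tracking_lost,
            }
        payload["objects"].append(entry)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_snapshot(path) -> NavigationScene:
    """Rebuild a scene from :func:`snapshot` output."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "emnav-scene":
        raise ValueError(f"{path} is not an emnav scene snapshot")
    s = payload["scale"]
    scene = NavigationScene(
        scale=ColorScale(
            lower_mm=s["lower_mm"],
            upper_mm=s["upper_mm"],
            lower_color=tuple(s["lower_color"]),
            upper_color=tuple(s["upper_color"]),
            midpoint_colors=tuple(tuple(c) for c in s["midpoint_colors"]),
            interpolation=s["interpolation"],
            bin_width_mm=s["bin_width_mm"],
        ),
        rate_hz=payload["rate_hz"],
        stale_timeout_s=payload["stale_timeout_s"],
    )
    for entry in payload["objects"]:
        landmarks = None
        if "landmarks" in entry:
            lm = entry["landmarks"]
            landmarks = LandmarkSet(tuple(lm["names"]), np.array(lm["points"]), lm["frame"])
        obj = PlannedObject(
            object_id=entry["object_id"],
            cloud=np.array(entry["cloud"]),
            landmarks=landmarks,
            target_pose=_transform_from_dict(entry["target_pose"]),
            frame=entry["frame"],
        )
        scene.add_object(
            obj,
            _transform_from_dict(entry["registration"]),
            entry["sensor_id"],
            _transform_from_dict(entry["rel_pose_at_registration"]),
        )
        scene.last_rel_pose[obj.object_id] = _transform_from_dict(entry["last_rel_pose"])
        scene.last_pose_time[obj.object_id] = entry["last_pose_time"]
        if "distance_map" in entry:
            m = entry["distance_map"]
            scene.last_maps[obj.object_id] = DistanceMap(
                object_id=obj.object_id,
                distances_mm=np.array(m["distances_mm"]),
                colors=None if m["colors"] is None else np.array(m["colors"]),
                timestamp=m["timestamp"],
                tracking_lost=m["tracking_lost"],
            )
    return scene
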