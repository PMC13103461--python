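"""File formats for landmarks, point clouds, pose streams and reports.

Schemas (all coordinates strictly in millimetres):

* landmarks — CSV with columns ``name,x_mm,y_mm,z_mm,frame`` or the JSON
  equivalent ``{"frame": ..., "landmarks": [{"name":..., "p": [x,y,z]}]}``;
* clouds — ASCII/binary STL or ASCII PLY (vertices used as the cloud) or a
  headerless/headered ``x_mm,y_mm,z_mm`` CSV.  STL repeats vertices per
  facet; they are deduplicated by exact (bitwise) coordinate equality
  keeping first-occurrence order, so index correspondence is stable across
  save/load;
* pose streams — JSON lines, one sample per line:
  ``{"t": seconds, "sensor": str, "q": [w,x,y,z], "p": [x_mm,y_mm,z_mm]}``
  (quaternion w-first; see :mod:`emnav.geometry` for the conventions), or a
  CSV dialect with columns ``t,sensor,qw,qx,qy,qz,px,py,pz``;
* probe calibration — JSON ``{"tip_offset_mm": [x, y, z]}``.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import SchemaError
from .geometry import PoseSample, RigidTransform, Rotation
from .registration import LandmarkSet

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_cloud",
    "write_cloud",
    "read_stream",
    "write_stream",
    "read_probe_calibration",
    "RunConfig",
    "load_run_config",
]


# -- landmarks --------------------------------------------------------------

_LANDMARK_COLUMNS = ["name", "x_mm", "y_mm", "z_mm", "frame"]


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _landmarks_from_json(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse landmark CSV: {exc}") from exc
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: landmark CSV is missing column(s) {missing}; coordinates "
            "must be explicit millimetre columns x_mm,y_mm,z_mm"
        )
    frames = df["frame"].unique()
    if len(frames) != 1:
        raise SchemaError(f"{path}: landmark file mixes frames {sorted(frames)}")
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        bad = int(np.argwhere(~np.isfinite(pts))[0][0])
        raise SchemaError(f"{path}: non-finite coordinate on data row {bad + 1}")
    return LandmarkSet(tuple(df["name"].astype(str)), pts, str(frames[0]))


def _landmarks_from_json(path: Path) -> LandmarkSet:
    try:
        data = json.loads(path.read_text())
        names = tuple(str(e["name"]) for e in data["landmarks"])
        pts = np.array([e["p"] for e in data["landmarks"]], dtype=float)
        return LandmarkSet(names, pts, str(data["frame"]))
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: malformed landmark JSON: {exc}") from exc


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "frame": landmarks.frame,
            "landmarks": [
                {"name": n, "p": p.tolist()}
                for n, p in zip(landmarks.names, landmarks.points)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    pd.DataFrame(
        {
            "name": landmarks.names,
            "x_mm": landmarks.points[:, 0],
            "y_mm": landmarks.points[:, 1],
            "z_mm": landmarks.points[:, 2],
            "frame": landmarks.frame,
        }
    ).to_csv(path, index=False)


# -- point clouds -----------------------------------------------------------


def read_cloud(path) -> np.ndarray:
    """Ordered (N, 3) vertex cloud from STL, PLY or CSV."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        verts = _read_stl_vertices(path)
        return _dedup_exact(verts)
    if suffix == ".ply":
        return _read_ply_vertices(path)
    if suffix in (".csv", ".txt", ".xyz"):
        return _read_csv_cloud(path)
    raise SchemaError(f"{path}: unsupported cloud format {suffix!r}")


def _dedup_exact(verts: np.ndarray) -> np.ndarray:
    """Drop duplicated vertices (bitwise-equal coordinates), keep first order."""
    _, idx = np.unique(verts, axis=0, return_index=True)
    return verts[np.sort(idx)]


def _read_stl_vertices(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    if raw[:5].lower() == b"solid" and b"facet" in raw[:500]:
        return _read_stl_ascii(path, raw)
    return _read_stl_binary(path, raw)


def _read_stl_ascii(path: Path, raw: bytes) -> np.ndarray:
    verts: List[List[float]] = []
    for lineno, line in enumerate(raw.decode("ascii", errors="replace").splitlines(), 1):
        tokens = line.split()
        if tokens[:1] == ["vertex"]:
            if len(tokens) != 4:
                raise SchemaError(f"{path}:{lineno}: malformed STL vertex line")
            try:
                verts.append([float(t) for t in tokens[1:]])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric STL vertex") from exc
    if not verts:
        raise SchemaError(f"{path}: ASCII STL contains no vertices")
    return np.array(verts, dtype=float)


def _read_stl_binary(path: Path, raw: bytes) -> np.ndarray:
    if len(raw) < 84:
        raise SchemaError(f"{path}: binary STL shorter than its 84-byte header")
    (n_tri,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n_tri
    if len(raw) < expected:
        raise SchemaError(
            f"{path}: binary STL truncated ({len(raw)} bytes, expected {expected})"
        )
    tri = np.frombuffer(raw, dtype=np.uint8, count=50 * n_tri, offset=84)
    tri = tri.reshape(n_tri, 50)[:, :48].copy().view("<f4").reshape(n_tri, 4, 3)
    return tri[:, 1:, :].reshape(-1, 3).astype(float)  # drop the normal row


def _read_ply_vertices(path: Path) -> np.ndarray:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise SchemaError(f"{path}: not a PLY file")
    n_vertices = None
    header_end = None
    props: List[str] = []
    in_vertex_element = False
    for i, line in enumerate(lines[1:], 1):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "format" and tokens[1] != "ascii":
            raise SchemaError(f"{path}: only ASCII PLY is supported")
        if tokens[0] == "element":
            in_vertex_element = tokens[1] == "vertex"
            if in_vertex_element:
                n_vertices = int(tokens[2])
        elif tokens[0] == "property" and in_vertex_element:
            props.append(tokens[-1])
        elif tokens[0] == "end_header":
            header_end = i
            break
    if n_vertices is None or header_end is None:
        raise SchemaError(f"{path}: PLY header lacks a vertex element")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise SchemaError(f"{path}: PLY vertex element lacks property {axis!r}")
    cols = [props.index(a) for a in ("x", "y", "z")]
    body = lines[header_end + 1 : header_end + 1 + n_vertices]
    if len(body) < n_vertices:
        raise SchemaError(f"{path}: PLY body has fewer vertices than declared")
    try:
        data = np.array([[float(r.split()[c]) for c in cols] for r in body])
    except (ValueError, IndexError) as exc:
        raise SchemaError(f"{path}: malformed PLY vertex row: {exc}") from exc
    return data


def _read_csv_cloud(path: Path) -> np.ndarray:
    df = pd.read_csv(path)
    if {"x_mm", "y_mm", "z_mm"}.issubset(df.columns):
        return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    # headerless numeric triples
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise SchemaError(
            f"{path}: cloud CSV needs columns x_mm,y_mm,z_mm or raw numeric triples"
        ) from exc
    if arr.shape[1] != 3:
        raise SchemaError(f"{path}: cloud CSV must have exactly 3 columns")
    return arr


def write_cloud(cloud: np.ndarray, path) -> None:
    path = Path(path)
    cloud = np.asarray(cloud, dtype=float)
    if path.suffix.lower() == ".ply":
        header = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(cloud)}",
            "property float x",
            "property float y",
            "property float z",
            "end_header",
        ]
        body = [
            f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}" for p in cloud
        ]
        path.write_text("\n".join(header + body) + "\n")
        return
    pd.DataFrame(cloud, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


# -- pose streams -----------------------------------------------------------

_STREAM_COLUMNS = ["t", "sensor", "qw", "qx", "qy", "qz", "px", "py", "pz"]


def _sample_pose(q, p, sensor: str) -> RigidTransform:
    return RigidTransform(
        Rotation(np.asarray(q, dtype=float)),
        np.asarray(p, dtype=float),
        source_frame=f"sensor:{sensor}",
        target_frame="tracker",
    )


def read_stream(path) -> List[PoseSample]:
    """Pose samples from a JSONL or CSV stream file, in file order."""
    path = Path(path)
    samples: List[PoseSample] = []
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                samples.append(
                    PoseSample(
                        float(rec["t"]),
                        str(rec["sensor"]),
                        _sample_pose(rec["q"], rec["p"], rec["sensor"]),
                    )
                )
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise SchemaError(f"{path}:{lineno}: malformed stream record: {exc}") from exc
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _STREAM_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: stream CSV missing column(s) {missing}")
        for rec in df.itertuples(index=False):
            samples.append(
                PoseSample(
                    float(rec.t),
                    str(rec.sensor),
                    _sample_pose((rec.qw, rec.qx, rec.qy, rec.qz), (rec.px, rec.py, rec.pz), rec.sensor),
                )
            )
    _check_monotone(samples, path)
    return samples


def _check_monotone(samples: List[PoseSample], path) -> None:
    last: dict = {}
    for s in samples:
        if s.sensor_id in last and s.timestamp < last[s.sensor_id]:
            raise SchemaError(
                f"{path}: timestamps for sensor {s.sensor_id!r} are not non-decreasing"
            )
        last[s.sensor_id] = s.timestamp


def write_stream(samples, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        lines = [
            json.dumps(
                {
                    "t": s.timestamp,
                    "sensor": s.sensor_id,
                    "q": s.pose.rotation.quat.tolist(),
                    "p": s.pose.translation.tolist(),
                }
            )
            for s in samples
        ]
        path.write_text("\n".join(lines) + "\n")
        return
    # floats serialized via repr for exact (bitwise) round-trips
    rows = [
        {
            "t": repr(float(s.timestamp)),
            "sensor": s.sensor_id,
            "qw": repr(float(s.pose.rotation.quat[0])),
            "qx": repr(float(s.pose.rotation.quat[1])),
            "qy": repr(float(s.pose.rotation.quat[2])),
            "qz": repr(float(s.pose.rotation.quat[3])),
            "px": repr(float(s.pose.translation[0])),
            "py": repr(float(s.pose.translation[1])),
            "pz": repr(float(s.pose.translation[2])),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_STREAM_COLUMNS).to_csv(path, index=False)


def read_probe_calibration(path) -> np.ndarray:
    try:
        data = json.loads(Path(path).read_text())
        offset = np.asarray(data["tip_offset_mm"], dtype=float)
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: malformed probe calibration: {exc}") from exc
    if offset.shape != (3,):
        raise SchemaError(f"{path}: tip_offset_mm must be a 3-vector")
    return offset


# -- run configuration ------------------------------------------------------


class AcquisitionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = 60
    rate_hz: float = 40.0
    max_step_mm: float = 0.5
    max_restarts: Optional[int] = None


class ColorScaleSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lower_mm: float = 1.0
    upper_mm: float = 4.0
    interpolation: str = "continuous"
    bin_width_mm: float = 1.0


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    loa_multiplier: float = 1.96
    alpha: float = 0.05
    lilliefors: bool = False
    fre_kind: str = "rms"


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    output_dir: str = "emnav_out"
    plan_cloud: Optional[str] = None
    plan_landmarks: Optional[str] = None
    stream: Optional[str] = None
    probe_calibration: Optional[str] = None
    acquisition: AcquisitionSettings = Field(default_factory=AcquisitionSettings)
    color_scale: ColorScaleSettings = Field(default_factory=ColorScaleSettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)


def load_run_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:
        raise SchemaError(f"{path}: invalid run configuration: {exc}") from exc
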