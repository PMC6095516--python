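"""YAML file contracts: camera definitions, poses, pool geometry, scenes.

A camera definition carries intrinsics, the five distortion
coefficients in (k1, k2, p1, p2, k3) order, the sensor size and the
surveyed calibration points (world metres + pixel per camera).  Poses
are written back as a row-major 9-number rotation plus a 3-number
translation in the same dialect.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .analytics import PoolGeometry
from .camera import (CalibrationPoint, Camera, CameraPose,
                     DistortionCoefficients, Intrinsics)

__all__ = [
    "load_camera_config",
    "dump_camera_config",
    "load_pose",
    "dump_pose",
    "load_pool_geometry",
    "dump_pool_geometry",
]


def _intrinsics_from_dict(d: dict) -> Intrinsics:
    return Intrinsics(
        fx=float(d["fx"]), fy=float(d.get("fy", d["fx"])),
        cx=float(d["cx"]), cy=float(d["cy"]),
        width=int(d["width"]), height=int(d["height"]),
    )


def load_camera_config(path: str | Path) -> dict:
    """Load a per-camera definition file.

    Returns ``{camera_id: {"camera": Camera, "calibration_points":
    [CalibrationPoint, ...]}}``.  A stored pose is optional (calibration
    fills it in).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for cam_id, spec in doc["cameras"].items():
        intr = _intrinsics_from_dict(spec["intrinsics"])
        coeffs = DistortionCoefficients.from_vector(spec["distortion"])
        pose = CameraPose.identity()
        if "pose" in spec and spec["pose"] is not None:
            pose = _pose_from_dict(spec["pose"])
        points = [
            CalibrationPoint(world=tuple(float(v) for v in p["world"]),
                             pixel=tuple(float(v) for v in p["pixel"]))
            for p in spec.get("calibration_points", [])
        ]
        out[cam_id] = {
            "camera": Camera(intrinsics=intr, distortion=coeffs, pose=pose),
            "calibration_points": points,
        }
    return out


def dump_camera_config(cameras: dict, path: str | Path) -> None:
    doc = {"cameras": {}}
    for cam_id, entry in cameras.items():
        cam: Camera = entry["camera"]
        doc["cameras"][cam_id] = {
            "intrinsics": {
                "fx": cam.intrinsics.fx, "fy": cam.intrinsics.fy,
                "cx": cam.intrinsics.cx, "cy": cam.intrinsics.cy,
                "width": cam.intrinsics.width, "height": cam.intrinsics.height,
            },
            "distortion": [float(v) for v in cam.distortion.as_vector()],
            "pose": _pose_to_dict(cam.pose),
            "calibration_points": [
                {"world": list(p.world), "pixel": list(p.pixel)}
                for p in entry.get("calibration_points", [])
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _pose_from_dict(d: dict) -> CameraPose:
    R = np.array(d["rotation"], dtype=float).reshape(3, 3)
    t = np.array(d["translation"], dtype=float)
    return CameraPose(R, t)


def _pose_to_dict(pose: CameraPose) -> dict:
    return {
        "rotation": [float(v) for v in pose.rotation.reshape(-1)],
        "translation": [float(v) for v in pose.translation],
    }


def load_pose(path: str | Path) -> CameraPose:
    with open(path) as fh:
        return _pose_from_dict(yaml.safe_load(fh))


def dump_pose(pose: CameraPose, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_pose_to_dict(pose), fh, sort_keys=True)


def load_pool_geometry(path: str | Path) -> PoolGeometry:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kwargs = {}
    for key in ("diameter", "max_depth", "shallow_max_depth"):
        if key in d:
            kwargs[key] = float(d[key])
    if d.get("deep_area_polygon"):
        kwargs["deep_area_polygon"] = [tuple(map(float, v))
                                       for v in d["deep_area_polygon"]]
    if d.get("regions"):
        kwargs["regions"] = {name: [tuple(map(float, v)) for v in verts]
                             for name, verts in d["regions"].items()}
    return PoolGeometry(**kwargs)


def dump_pool_geometry(pool: PoolGeometry, path: str | Path) -> None:
    doc = {
        "diameter": pool.diameter,
        "max_depth": pool.max_depth,
        "shallow_max_depth": pool.shallow_max_depth,
        "deep_area_polygon": [list(map(float, v)) for v in pool.deep_area_polygon],
        "regions": {name: [list(map(float, v)) for v in verts]
                    for name, verts in pool.regions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
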