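"""Synthetic pool scenes with known ground truth.

Real pool footage is large, scarce and has no ground truth, so every
pipeline stage is exercised against generated scenes instead: a scripted
3D trajectory inside the default 21 m x 5 m pool, its projection through
two wide-angle cameras mounted about 4 m above the water on opposite
sides (optionally through the refracting water surface and with pixel
noise), and simple rendered frames (uniform background + an ellipse at
the projected position) for the segmentation stage.

Everything is deterministic under a fixed seed.  The generator records
its own bookkeeping (ring boundaries, zone labels, speed profile) from
the generating equations at sampling time, so downstream detections can
be compared against construction-time truth rather than re-derived
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import brentq

import imageio.v3 as iio

from .analytics import PoolGeometry, classify_zone
from .camera import Camera, CameraModelError, CameraPose, project_point
from .reconstruction import PixelTrack, WaterModel

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "Appearance",
    "CircleSegment",
    "DiveSegment",
    "DwellSegment",
    "SceneError",
    "default_cameras",
    "generate_trajectory",
    "project_truth",
    "refracted_pixel",
    "render_frames",
    "write_frames",
]


class SceneError(ValueError):
    pass


def default_cameras(pool: PoolGeometry | None = None,
                    camera_radius_m: float = 11.0,
                    height_m: float = 4.0) -> tuple[Camera, Camera]:
    """Two wide-angle cameras on opposite sides of the pool.

    Cameras sit at the given radius from the pool centre, ``height_m``
    above the water (world z negative up), pitched to look at a point
    one metre below the surface at the pool centre so the whole arena
    stays in view.
    """
    target = (0.0, 0.0, 1.0)
    posA = (camera_radius_m, 0.0, -height_m)
    posB = (-camera_radius_m, 0.0, -height_m)
    return (
        Camera(pose=CameraPose.look_at(posA, target)),
        Camera(pose=CameraPose.look_at(posB, target)),
    )


@dataclass
class SceneConfig:
    """World description for a synthetic session."""

    pool: PoolGeometry = field(default_factory=PoolGeometry)
    cameras: tuple[Camera, Camera] | None = None
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cameras is None:
            self.cameras = default_cameras(self.pool)
        # opposite-side check: horizontal camera positions > 120 deg apart
        a = self.cameras[0].pose.camera_center[:2]
        b = self.cameras[1].pose.camera_center[:2]
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        if cosang > np.cos(np.deg2rad(120)):
            raise SceneError("cameras must be on opposite sides of the pool "
                             "(horizontal separation > 120 degrees)")


# --- motion segments --------------------------------------------------------


@dataclass(frozen=True)
class CircleSegment:
    """Horizontal circling at constant depth and angular rate."""

    duration_s: float
    radius_m: float = 6.0
    centre: tuple[float, float] = (0.0, 0.0)
    depth_m: float = 0.5
    angular_rate_rad_s: float = 0.5
    direction: int = 1              # +1 counter-clockwise, -1 clockwise
    start_angle_rad: float = 0.0

    def position(self, t: float) -> np.ndarray:
        a = self.start_angle_rad + self.direction * self.angular_rate_rad_s * t
        return np.array([self.centre[0] + self.radius_m * np.cos(a),
                         self.centre[1] + self.radius_m * np.sin(a),
                         self.depth_m])

    @classmethod
    def for_turns(cls, n_turns: int, fps: float = 30.0, **kwargs) -> "CircleSegment":
        """A segment on which the *sampled* path completes n full turns.

        Half a second of slack follows the final turn so that detectors
        working on jittered observations can still close it.
        """
        rate = kwargs.get("angular_rate_rad_s", 0.5)
        n_frames = int(np.ceil(2 * np.pi * n_turns * fps / rate) + fps / 2)
        return cls(duration_s=n_frames / fps, **kwargs)


@dataclass(frozen=True)
class DiveSegment:
    """Sinusoidal depth oscillation at a fixed horizontal anchor."""

    duration_s: float
    anchor: tuple[float, float] = (0.0, 0.0)
    min_depth_m: float = 0.2
    max_depth_m: float = 3.0
    period_s: float = 20.0

    def position(self, t: float) -> np.ndarray:
        mid = 0.5 * (self.min_depth_m + self.max_depth_m)
        amp = 0.5 * (self.max_depth_m - self.min_depth_m)
        return np.array([self.anchor[0], self.anchor[1],
                         mid - amp * np.cos(2 * np.pi * t / self.period_s)])


@dataclass(frozen=True)
class DwellSegment:
    """Stationary position plus small isotropic jitter."""

    duration_s: float
    point: tuple[float, float, float] = (5.0, 0.0, 0.3)
    jitter_m: float = 0.02

    def position(self, t: float) -> np.ndarray:
        return np.array(self.point, dtype=float)


MotionSegment = CircleSegment | DiveSegment | DwellSegment


@dataclass
class GroundTruth:
    """Construction-time truth for one synthetic session."""

    positions: np.ndarray                 # (n, 3) metres
    fps: float
    zone_labels: list[str]
    ring_boundaries: list[int]            # frame index closing each full turn
    speeds: np.ndarray                    # (n,) m/s, NaN at frame 0
    pixels: dict[str, np.ndarray] = field(default_factory=dict)   # filled by project_truth
    pixel_valid: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.positions)


def generate_trajectory(config: SceneConfig,
                        segments: Sequence[MotionSegment]) -> GroundTruth:
    """Sample a piecewise motion script at the configured frame rate.

    Ring boundaries are recorded wherever the cumulative azimuth of a
    circle segment about its own centre completes another full turn;
    zone labels come from applying the zone definition to the exact
    generated positions; the speed profile is the exact chord length
    between consecutive samples times fps.  A position outside the pool
    (horizontal radius beyond the wall or depth outside [0 - 0.5, max])
    raises :class:`SceneError`.
    """
    if not segments:
        raise SceneError("motion script is empty")
    rng = np.random.default_rng(config.seed)
    fps = config.fps
    positions = []
    ring_boundaries: list[int] = []
    frame = 0
    for seg in segments:
        n = int(round(seg.duration_s * fps))
        if n <= 0:
            raise SceneError("segment duration shorter than one frame")
        t = np.arange(n) / fps
        pts = np.array([seg.position(ti) for ti in t])
        if isinstance(seg, DwellSegment) and seg.jitter_m > 0:
            pts += rng.normal(0.0, seg.jitter_m, size=pts.shape)
        if isinstance(seg, CircleSegment):
            swept = seg.angular_rate_rad_s * t
            turns = np.floor(swept / (2 * np.pi)).astype(int)
            for k in range(1, int(turns[-1]) + 1):
                ring_boundaries.append(frame + int(np.argmax(swept >= 2 * np.pi * k)))
        positions.append(pts)
        frame += n
    positions = np.vstack(positions)

    pool = config.pool
    horiz = np.linalg.norm(positions[:, :2], axis=1)
    if np.any(horiz > pool.diameter / 2 + 1e-9):
        raise SceneError("trajectory exits the pool wall")
    if np.any(positions[:, 2] < -0.5) or np.any(positions[:, 2] > pool.max_depth + 1e-9):
        raise SceneError("trajectory depth outside the pool")

    zone_labels = [classify_zone(p, pool) or "" for p in positions]
    speeds = np.full(len(positions), np.nan)
    speeds[1:] = np.linalg.norm(np.diff(positions, axis=0), axis=1) * fps
    return GroundTruth(positions=positions, fps=fps, zone_labels=zone_labels,
                       ring_boundaries=ring_boundaries, speeds=speeds)


# --- projection -------------------------------------------------------------


def refracted_pixel(world_point, camera: Camera, water: WaterModel) -> np.ndarray:
    """Project an underwater point through the refracting surface.

    Finds the surface-crossing point on the straight line of sight's
    vertical plane such that the air and water segments satisfy Snell's
    law (Fermat's principle, solved by 1-D root finding on the
    horizontal crossing offset), then projects the air-side ray.
    """
    P = np.asarray(world_point, dtype=float)
    C = camera.pose.camera_center
    if C[2] >= water.surface_z:
        raise SceneError("camera must be above the water surface")
    if P[2] <= water.surface_z:
        return camera.project(P)        # not submerged: ordinary projection
    n = water.refraction_index
    hC, hP = C[:2], P[:2]
    d_h = np.linalg.norm(hP - hC)
    ha = -(C[2] - water.surface_z)      # camera height above surface (> 0)
    hw = P[2] - water.surface_z         # point depth below surface (> 0)
    if d_h < 1e-12:
        return camera.project(np.array([P[0], P[1], water.surface_z]))
    u_hat = (hP - hC) / d_h

    def snell_mismatch(x: float) -> float:
        # x = horizontal offset of the crossing point from the camera
        sin_air = x / np.hypot(x, ha)
        sin_wat = (d_h - x) / np.hypot(d_h - x, hw)
        return sin_air - n * sin_wat

    # sin_air - n*sin_water goes from -n*sin(max) at x=0 to sin(max)>0 at x=d_h
    x = brentq(snell_mismatch, 0.0, d_h, xtol=1e-12, rtol=1e-15)
    S = np.array([hC[0] + x * u_hat[0], hC[1] + x * u_hat[1], water.surface_z])
    return camera.project(S)


def project_truth(gt: GroundTruth, config: SceneConfig, *,
                  refraction: bool = False,
                  pixel_noise_sigma: float = 0.0,
                  water: WaterModel | None = None,
                  seed: int | None = None) -> tuple[PixelTrack, PixelTrack]:
    """Project the true positions into both cameras.

    With ``refraction`` on, submerged positions are projected along the
    Snell-bent light path (the exact forward model matching the
    reconstruction stage's ray bending).  Seeded Gaussian pixel noise of
    the given sigma is added to valid projections; positions behind a
    camera or off the sensor are marked invalid, never fatal.  The true
    noise-free pixel series is stored on ``gt.pixels``.
    """
    water = water or WaterModel()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tracks = []
    for cam_idx, cam in enumerate(config.cameras):
        n = gt.n_frames
        uv = np.full((n, 2), np.nan)
        valid = np.zeros(n, dtype=bool)
        intr = cam.intrinsics
        for i, P in enumerate(gt.positions):
            try:
                if refraction and P[2] > water.surface_z:
                    px = refracted_pixel(P, cam, water)
                else:
                    px = cam.project(P)
            except (CameraModelError, SceneError):
                continue
            if 0 <= px[0] <= intr.width - 1 and 0 <= px[1] <= intr.height - 1:
                uv[i] = px
                valid[i] = True
        key = f"cam{cam_idx}"
        gt.pixels[key] = uv.copy()
        gt.pixel_valid[key] = valid.copy()
        if pixel_noise_sigma > 0:
            noise = rng.normal(0.0, pixel_noise_sigma, size=uv.shape)
            uv = np.where(valid[:, None], uv + noise, uv)
        tracks.append(PixelTrack(uv=uv, valid=valid, fps=gt.fps))
    return tracks[0], tracks[1]


# --- rendering --------------------------------------------------------------


@dataclass(frozen=True)
class Appearance:
    """How the animal and background look in rendered frames."""

    blob_axes_px: tuple[float, float] = (22.0, 12.0)
    contrast: float = 80.0            # grey-level offset of the blob
    background_level: float = 120.0
    background_texture: float = 0.0   # sigma of static background texture
    noise_sigma: float = 0.0          # per-frame grey noise


def render_frames(gt: GroundTruth, config: SceneConfig, appearance: Appearance,
                  camera_index: int = 0, *,
                  seed: int | None = None) -> Iterator[np.ndarray]:
    """Yield uint8 frames: static background plus an ellipse at the true pixel.

    The ellipse is axis-aligned with the configured pixel semi-axes and sits
    at the projected ground-truth position recorded by
    :func:`project_truth` (which must run first).  With a fixed seed the
    byte stream is fully reproducible.
    """
    key = f"cam{camera_index}"
    if key not in gt.pixels:
        raise SceneError("run project_truth before render_frames")
    cam = config.cameras[camera_index]
    h, w = cam.intrinsics.height, cam.intrinsics.width
    ax, ay = appearance.blob_axes_px
    if 2 * ax >= w or 2 * ay >= h:
        raise SceneError("blob larger than the frame")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    background = np.full((h, w), appearance.background_level)
    if appearance.background_texture > 0:
        background = background + rng.normal(
            0.0, appearance.background_texture, size=(h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(gt.n_frames):
        frame = background.copy()
        if gt.pixel_valid[key][i] and appearance.contrast != 0:
            u, v = gt.pixels[key][i]
            ellipse = ((xx - u) / ax) ** 2 + ((yy - v) / ay) ** 2 <= 1.0
            frame = np.where(ellipse, frame + appearance.contrast, frame)
        if appearance.noise_sigma > 0:
            frame = frame + rng.normal(0.0, appearance.noise_sigma, size=(h, w))
        yield np.clip(frame, 0, 255).astype(np.uint8)


def write_frames(frames: Iterator[np.ndarray], out_dir: str | Path,
                 prefix: str = "frame") -> list[Path]:
    """Write a frame iterator as numbered PNGs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
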