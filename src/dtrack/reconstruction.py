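"""From paired pixel centroids to a 3D trajectory in pool coordinates.

The pipeline stage implemented here smooths each camera's centroid
series, back-projects paired centroids to viewing rays, bends the rays
at the water surface (Snell's law, flat interface at z = 0), intersects
them, removes gross outliers with Tukey outer fences, and bridges short
detection gaps by linear interpolation.

World frame: origin at the pool centre on the water surface, z positive
downward (depth in metres).  Cameras sit above the water at z < 0.

Two rays back-projected from real detections never meet exactly, so the
"intersection" is the midpoint of the common perpendicular between the
two lines; the length of that segment (the *gap*) is kept per frame as
a reconstruction-quality score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .camera import Camera, CameraModelError, Ray

__all__ = [
    "PixelTrack",
    "Trajectory3D",
    "WaterModel",
    "ReconstructionError",
    "smooth_pixel_track",
    "refract_ray",
    "triangulate",
    "filter_outliers",
    "interpolate_gaps",
    "reconstruct_trajectory",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

TRAJECTORY_COLUMNS = ["frame", "time_s", "x_m", "y_m", "z_m", "gap_m",
                      "valid", "interpolated"]


class ReconstructionError(ValueError):
    pass


@dataclass
class PixelTrack:
    """Frame-indexed centroid series for one camera."""

    uv: np.ndarray          # (n, 2) float, NaN where invalid
    valid: np.ndarray       # (n,) bool
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float).reshape(-1, 2)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        if len(self.uv) != len(self.valid):
            raise ReconstructionError("uv and valid lengths differ")
        if self.fps <= 0:
            raise ReconstructionError("fps must be positive")

    @classmethod
    def from_centroids(cls, table: pd.DataFrame, fps: float = 30.0) -> "PixelTrack":
        """Build from a centroid table (columns frame, u, v, valid)."""
        n = int(table["frame"].max()) + 1 if len(table) else 0
        uv = np.full((n, 2), np.nan)
        valid = np.zeros(n, dtype=bool)
        for _, row in table.iterrows():
            i = int(row["frame"])
            if bool(row["valid"]) and np.isfinite(row["u"]) and np.isfinite(row["v"]):
                uv[i] = (row["u"], row["v"])
                valid[i] = True
        return cls(uv=uv, valid=valid, fps=fps)


@dataclass
class Trajectory3D:
    """Frame-indexed 3D positions (metres) with timestamps and validity."""

    positions: np.ndarray    # (n, 3), NaN where invalid
    valid: np.ndarray        # (n,) bool
    fps: float = 30.0
    gap_m: np.ndarray | None = None       # triangulation quality per frame
    interpolated: np.ndarray | None = None
    invalidated_by: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        n = len(self.positions)
        if len(self.valid) != n:
            raise ReconstructionError("positions and valid lengths differ")
        if self.gap_m is None:
            self.gap_m = np.full(n, np.nan)
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        self.gap_m = np.asarray(self.gap_m, dtype=float).reshape(-1)
        self.interpolated = np.asarray(self.interpolated, dtype=bool).reshape(-1)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def copy(self) -> "Trajectory3D":
        return Trajectory3D(self.positions.copy(), self.valid.copy(), self.fps,
                            self.gap_m.copy(), self.interpolated.copy(),
                            dict(self.invalidated_by))


@dataclass(frozen=True)
class WaterModel:
    """Flat air-water interface at z = 0 with an effective refraction index.

    The default index of 1.4 is an *effective* value calibrated against
    known in-pool distances rather than the textbook 1.33 for pure
    water; it absorbs residual lens and interface effects and is
    configurable.
    """

    refraction_index: float = 1.4
    surface_z: float = 0.0

    def __post_init__(self) -> None:
        if self.refraction_index < 1.0:
            raise ReconstructionError("refraction index must be >= 1")


# ---------------------------------------------------------------------------
# pixel-space smoothing


def smooth_pixel_track(track: PixelTrack, sigma: float = 32.0) -> PixelTrack:
    """Gaussian-smooth the centroid series to suppress centroid jitter.

    The kernel (default sigma 32 frames, about one second of video)
    is truncated at 4 sigma with reflective boundaries and applied
    independently to each contiguous run of valid frames, so detection
    gaps never bleed information across.
    """
    if sigma < 0:
        raise ReconstructionError("sigma must be >= 0")
    uv = track.uv.copy()
    if sigma > 0:
        for start, stop in _valid_segments(track.valid):
            for c in range(2):
                uv[start:stop, c] = gaussian_filter1d(
                    track.uv[start:stop, c], sigma=sigma,
                    mode="reflect", truncate=4.0)
    return PixelTrack(uv=uv, valid=track.valid.copy(), fps=track.fps)


def _valid_segments(valid: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs."""
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


# ---------------------------------------------------------------------------
# refraction and triangulation


def refract_ray(ray: Ray, water: WaterModel) -> Ray:
    """Continue a downward ray through the water surface by Snell's law.

    The returned ray starts at the surface-crossing point; its direction
    is bent toward the vertical with sin(theta_air) =
    n * sin(theta_water), azimuth preserved.  The incoming ray must start
    above the surface and point downward.
    """
    o, d = ray.origin, ray.direction
    if o[2] > water.surface_z:
        raise ReconstructionError("ray origin must be above the water surface")
    if d[2] <= 1e-12:
        raise ReconstructionError("ray does not point down toward the surface")
    t = (water.surface_z - o[2]) / d[2]
    hit = o + t * d
    horiz = np.array([d[0], d[1], 0.0])
    sin_air = np.linalg.norm(horiz)          # |d| = 1, so |horizontal| = sin(theta)
    if sin_air < 1e-15:
        return Ray(origin=hit, direction=d)  # normal incidence
    sin_water = sin_air / water.refraction_index
    cos_water = np.sqrt(1.0 - sin_water**2)
    new_d = (horiz / sin_air) * sin_water + np.array([0.0, 0.0, cos_water])
    return Ray(origin=hit, direction=new_d)


def _closest_midpoint(rayA: Ray, rayB: Ray, min_angle_rad: float):
    """Midpoint of the common perpendicular between two lines, plus gap."""
    d1, d2 = rayA.direction, rayB.direction
    cross = np.cross(d1, d2)
    sin_angle = np.linalg.norm(cross)
    if sin_angle < np.sin(min_angle_rad):
        raise ReconstructionError("rays are near-parallel; triangulation unstable")
    w0 = rayA.origin - rayB.origin
    b = float(np.dot(d1, d2))
    d = float(np.dot(d1, w0))
    e = float(np.dot(d2, w0))
    denom = 1.0 - b * b
    s = (b * e - d) / denom
    t = (e - b * d) / denom
    p1 = rayA.point_at(s)
    p2 = rayB.point_at(t)
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def triangulate(rayA: Ray, rayB: Ray, water: WaterModel | None = None,
                min_angle_deg: float = 0.5):
    """Intersect two viewing rays; refract them first if the target is submerged.

    Returns ``(position, gap)`` where position is the midpoint of the
    shortest segment between the (generically skew) lines and gap is that
    segment's length in metres.  When the unrefracted midpoint falls
    below the water surface and a :class:`WaterModel` is given, both rays
    are passed through :func:`refract_ray` and the midpoint is recomputed
    on the underwater segments.
    """
    min_angle = np.deg2rad(min_angle_deg)
    pos, gap = _closest_midpoint(rayA, rayB, min_angle)
    if water is not None and pos[2] > water.surface_z:
        rA = refract_ray(rayA, water)
        rB = refract_ray(rayB, water)
        pos, gap = _closest_midpoint(rA, rB, min_angle)
    return pos, gap


# ---------------------------------------------------------------------------
# outlier removal and gap interpolation


def _outer_fences(values: np.ndarray, k: float = 3.0):
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolated quartiles
    iqr = q3 - q1
    # the 1e-9 m pad keeps numerically-constant series (IQR ~ eps) intact
    return q1 - k * iqr - 1e-9, q3 + k * iqr + 1e-9


def filter_outliers(traj: Trajectory3D, fence_factor: float = 3.0) -> Trajectory3D:
    """Invalidate frames beyond the Tukey *outer* fences (major outliers).

    For each coordinate series (x, y, z) and for the per-frame
    displacement magnitude, quartiles are computed over the valid frames
    with linear interpolation between order statistics, and any frame
    with a value outside [Q1 - 3 IQR, Q3 + 3 IQR] is invalidated.  The
    cause is recorded per frame in ``invalidated_by``.  With fewer than 8
    valid frames the input is returned unchanged with a warning.
    """
    out = traj.copy()
    idx = np.flatnonzero(out.valid)
    if len(idx) < 8:
        warnings.warn("fewer than 8 valid frames; outlier filter skipped")
        return out
    drop: dict[int, str] = {}
    for axis, name in enumerate("xyz"):
        series = out.positions[idx, axis]
        lo, hi = _outer_fences(series)
        for i, v in zip(idx, series):
            if v < lo or v > hi:
                drop.setdefault(int(i), f"coordinate_{name}")
    # displacement between consecutive valid frames; a jitter spike shows up
    # as an outlying step both into and out of one frame, so a frame is only
    # flagged when every defined adjacent step is beyond the fence
    steps = np.flatnonzero(np.diff(idx) == 1)
    if len(steps) >= 2:
        disp = np.linalg.norm(
            out.positions[idx[steps + 1]] - out.positions[idx[steps]], axis=1)
        lo, hi = _outer_fences(disp)
        outlying = (disp < lo) | (disp > hi)
        step_in = {int(idx[s + 1]): bool(o) for s, o in zip(steps, outlying)}
        step_out = {int(idx[s]): bool(o) for s, o in zip(steps, outlying)}
        for i in idx:
            i = int(i)
            adjacent = [step_in.get(i), step_out.get(i)]
            defined = [a for a in adjacent if a is not None]
            if defined and all(defined):
                drop.setdefault(i, "displacement")
    for i, cause in drop.items():
        out.valid[i] = False
        out.positions[i] = np.nan
        out.invalidated_by[i] = cause
    return out


def interpolate_gaps(traj: Trajectory3D, max_gap_frames: int = 30) -> Trajectory3D:
    """Linearly bridge invalid runs of at most ``max_gap_frames`` frames.

    Interpolated frames are marked in ``traj.interpolated``; longer gaps
    and gaps touching either end of the series stay invalid.
    """
    out = traj.copy()
    idx = np.flatnonzero(out.valid)
    if len(idx) < 2:
        return out
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap_frames:
            frac = np.arange(1, gap + 1) / (gap + 1)
            out.positions[a + 1:b] = (
                out.positions[a] * (1 - frac[:, None])
                + out.positions[b] * frac[:, None])
            out.valid[a + 1:b] = True
            out.interpolated[a + 1:b] = True
    return out


# ---------------------------------------------------------------------------
# full stage


def reconstruct_trajectory(
    trackA: PixelTrack,
    trackB: PixelTrack,
    cameraA: Camera,
    cameraB: Camera,
    water: WaterModel | None = None,
    *,
    smoothing_sigma: float = 32.0,
    max_depth_m: float = 5.0,
    max_gap_frames: int = 30,
    min_angle_deg: float = 0.5,
    apply_outlier_filter: bool = True,
) -> Trajectory3D:
    """Run smoothing, triangulation, outlier removal and gap bridging.

    Frames missing in either camera, failing triangulation, or landing
    outside the plausible depth band [-0.5, max_depth + 0.5] m are
    invalid (cause recorded); short gaps are then linearly interpolated.
    """
    if len(trackA.valid) != len(trackB.valid):
        raise ReconstructionError("camera tracks cover different frame ranges")
    if trackA.fps != trackB.fps:
        raise ReconstructionError("camera tracks have different frame rates")
    sA = smooth_pixel_track(trackA, smoothing_sigma)
    sB = smooth_pixel_track(trackB, smoothing_sigma)
    n = len(sA.valid)
    positions = np.full((n, 3), np.nan)
    gaps = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    causes: dict[int, str] = {}
    for i in range(n):
        if not (sA.valid[i] and sB.valid[i]):
            causes[i] = "missing_detection"
            continue
        try:
            rA = cameraA.ray(sA.uv[i])
            rB = cameraB.ray(sB.uv[i])
            pos, gap = triangulate(rA, rB, water, min_angle_deg=min_angle_deg)
        except (CameraModelError, ReconstructionError):
            causes[i] = "triangulation_failed"
            continue
        if not (-0.5 <= pos[2] <= max_depth_m + 0.5):
            causes[i] = "depth_out_of_bounds"
            continue
        positions[i] = pos
        gaps[i] = gap
        valid[i] = True
    traj = Trajectory3D(positions, valid, fps=trackA.fps, gap_m=gaps,
                        invalidated_by=causes)
    if apply_outlier_filter:
        traj = filter_outliers(traj)
    return interpolate_gaps(traj, max_gap_frames=max_gap_frames)


# ---------------------------------------------------------------------------
# file contracts


def write_trajectory_csv(traj: Trajectory3D, path: str | Path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "time_s": traj.times,
        "x_m": traj.positions[:, 0],
        "y_m": traj.positions[:, 1],
        "z_m": traj.positions[:, 2],
        "gap_m": traj.gap_m,
        "valid": traj.valid,
        "interpolated": traj.interpolated,
    })
    df.to_csv(path, index=False, float_format="%.9g")


def read_trajectory_csv(path: str | Path, fps: float = 30.0) -> Trajectory3D:
    df = pd.read_csv(path)
    return Trajectory3D(
        positions=df[["x_m", "y_m", "z_m"]].to_numpy(),
        valid=df["valid"].to_numpy(dtype=bool),
        fps=fps,
        gap_m=df["gap_m"].to_numpy(),
        interpolated=df["interpolated"].to_numpy(dtype=bool),
    )
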