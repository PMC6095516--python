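"""Pinhole camera model with radial-tangential lens distortion.

Wide-angle action cameras mounted around a pool introduce strong barrel
("fish-eye") distortion.  This module models each camera as an ideal
pinhole plus a polynomial radial-tangential distortion, and provides the
conversions the tracking pipeline needs:

* world point -> pixel (:func:`project_point`),
* pixel -> 3D viewing ray in the world frame (:func:`pixel_to_ray`),
* camera pose from >=5 surveyed landmarks with RANSAC-robust
  Perspective-n-Point estimation (:func:`estimate_pose_ransac_pnp`).

Conventions
-----------
Pixels are 0-based, origin at the top-left corner, ``u`` = column,
``v`` = row.  The world frame has its origin at the pool centre on the
water surface with ``z`` positive downward (depth in metres).  A pose
maps world to camera coordinates: ``X_cam = R @ X_world + t``.

Distortion coefficients are stored in the order ``(k1, k2, p1, p2, k3)``:
three radial terms and two tangential terms, the common five-element
layout for this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

__all__ = [
    "Intrinsics",
    "DistortionCoefficients",
    "CameraPose",
    "CalibrationPoint",
    "Ray",
    "Camera",
    "RansacConfig",
    "PoseEstimate",
    "CameraModelError",
    "distort_point",
    "undistort_point",
    "project_point",
    "pixel_to_ray",
    "estimate_pose_ransac_pnp",
]

# Default calibration of the 170-degree action cameras used for the pool
# recordings: a single focal length for both axes and the principal point
# at the centre of the 0-based 1280x720 sensor.
DEFAULT_FOCAL_PX = 654.55
DEFAULT_WIDTH = 1280
DEFAULT_HEIGHT = 720
DEFAULT_DISTORTION = (-0.335050702095, 0.120226070285, 0.0, 0.0, -0.0201695654541)


class CameraModelError(ValueError):
    """Raised for geometric preconditions the camera model cannot satisfy."""


@dataclass(frozen=True)
class Intrinsics:
    """Internal camera parameters (focal lengths and principal point, pixels)."""

    fx: float = DEFAULT_FOCAL_PX
    fy: float = DEFAULT_FOCAL_PX
    cx: float = (DEFAULT_WIDTH - 1) / 2
    cy: float = (DEFAULT_HEIGHT - 1) / 2
    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise CameraModelError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise CameraModelError("principal point must lie inside the sensor")


@dataclass(frozen=True)
class DistortionCoefficients:
    """Radial (k1, k2, k3) and tangential (p1, p2) lens distortion terms."""

    k1: float = DEFAULT_DISTORTION[0]
    k2: float = DEFAULT_DISTORTION[1]
    p1: float = DEFAULT_DISTORTION[2]
    p2: float = DEFAULT_DISTORTION[3]
    k3: float = DEFAULT_DISTORTION[4]

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.k1, self.k2, self.p1, self.p2, self.k3])):
            raise CameraModelError("distortion coefficients must be finite")

    @classmethod
    def zero(cls) -> "DistortionCoefficients":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "DistortionCoefficients":
        """Build from the five-element (k1, k2, p1, p2, k3) vector."""
        k1, k2, p1, p2, k3 = (float(v) for v in vec)
        return cls(k1, k2, p1, p2, k3)

    def as_vector(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])


@dataclass(frozen=True)
class CameraPose:
    """Rigid world->camera transform: ``X_cam = rotation @ X_world + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise CameraModelError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise CameraModelError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "CameraPose":
        return cls(np.eye(3), np.zeros(3))

    @property
    def camera_center(self) -> np.ndarray:
        """Camera focal point in world coordinates."""
        return -self.rotation.T @ self.translation

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def camera_to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.translation) @ self.rotation

    @classmethod
    def look_at(
        cls,
        position: Sequence[float],
        target: Sequence[float],
        down: Sequence[float] = (0.0, 0.0, 1.0),
    ) -> "CameraPose":
        """Pose for a camera at ``position`` whose optical axis points at ``target``.

        ``down`` is the world direction that should map to increasing image
        row ``v``; the default is world +z (depth), so the water surface
        appears "up" in the image.
        """
        position = np.asarray(position, dtype=float)
        z_cam = np.asarray(target, dtype=float) - position
        nrm = np.linalg.norm(z_cam)
        if nrm == 0:
            raise CameraModelError("camera position and target coincide")
        z_cam = z_cam / nrm
        down = np.asarray(down, dtype=float)
        y_cam = down - np.dot(down, z_cam) * z_cam
        ynrm = np.linalg.norm(y_cam)
        if ynrm < 1e-12:
            raise CameraModelError("optical axis parallel to the 'down' direction")
        y_cam = y_cam / ynrm
        x_cam = np.cross(y_cam, z_cam)
        R = np.vstack([x_cam, y_cam, z_cam])
        return cls(R, -R @ position)


@dataclass(frozen=True)
class CalibrationPoint:
    """A surveyed landmark: world position (m) and its pixel in one view."""

    world: tuple[float, float, float]
    pixel: tuple[float, float]


@dataclass(frozen=True)
class Ray:
    """Half-line from a camera centre, in world coordinates."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise CameraModelError("ray direction must be finite and nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction


@dataclass(frozen=True)
class Camera:
    """A fully specified view: intrinsics, distortion and (optionally) pose."""

    intrinsics: Intrinsics = field(default_factory=Intrinsics)
    distortion: DistortionCoefficients = field(default_factory=DistortionCoefficients)
    pose: CameraPose = field(default_factory=CameraPose.identity)

    def project(self, world_point) -> np.ndarray:
        return project_point(world_point, self.intrinsics, self.distortion, self.pose)

    def ray(self, uv) -> Ray:
        return pixel_to_ray(uv, self.intrinsics, self.distortion, self.pose)


# ---------------------------------------------------------------------------
# distortion


def _distort_xy(x: np.ndarray, y: np.ndarray, c: DistortionCoefficients):
    r2 = x * x + y * y
    radial = 1.0 + r2 * (c.k1 + r2 * (c.k2 + r2 * c.k3))
    xd = x * radial + 2.0 * c.p1 * x * y + c.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + c.p1 * (r2 + 2.0 * y * y) + 2.0 * c.p2 * x * y
    return xd, yd


def distort_point(normalized_xy, coeffs: DistortionCoefficients):
    """Apply radial-tangential distortion to normalized camera coordinates.

    ``normalized_xy`` is ``(x', y') = (x/z, y/z)`` on the z = 1 plane.
    Returns the distorted normalized coordinates::

        x_d = x'(1 + k1 r^2 + k2 r^4 + k3 r^6) + 2 p1 x'y' + p2 (r^2 + 2 x'^2)

    and symmetrically for ``y_d``, with ``r^2 = x'^2 + y'^2``.
    """
    x, y = (float(v) for v in normalized_xy)
    if not (np.isfinite(x) and np.isfinite(y)):
        raise CameraModelError("normalized coordinates must be finite")
    xd, yd = _distort_xy(np.float64(x), np.float64(y), coeffs)
    return float(xd), float(yd)


def undistort_point(
    distorted_xy,
    coeffs: DistortionCoefficients,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Invert :func:`distort_point` by fixed-point iteration.

    Converges for points inside the invertible region of the lens model
    (for the default coefficients, normalized radius below ~1.5).
    """
    xd, yd = (float(v) for v in distorted_xy)
    if not (np.isfinite(xd) and np.isfinite(yd)):
        raise CameraModelError("distorted coordinates must be finite")
    x, y = xd, yd
    for _ in range(max_iter):
        r2 = x * x + y * y
        radial = 1.0 + r2 * (coeffs.k1 + r2 * (coeffs.k2 + r2 * coeffs.k3))
        if radial <= 0 or not np.isfinite(radial):
            raise CameraModelError(
                f"undistortion diverged for point ({xd:.4g}, {yd:.4g})"
            )
        dx = 2.0 * coeffs.p1 * x * y + coeffs.p2 * (r2 + 2.0 * x * x)
        dy = coeffs.p1 * (r2 + 2.0 * y * y) + 2.0 * coeffs.p2 * x * y
        x_new = (xd - dx) / radial
        y_new = (yd - dy) / radial
        shift = max(abs(x_new - x), abs(y_new - y))
        x, y = x_new, y_new
        if shift < tol:
            break
    else:
        raise CameraModelError(
            f"undistortion did not converge for point ({xd:.4g}, {yd:.4g})"
        )
    return x, y


# ---------------------------------------------------------------------------
# projection and back-projection


def project_point(world_point, intr: Intrinsics, coeffs: DistortionCoefficients,
                  pose: CameraPose) -> np.ndarray:
    """Project a world point (metres) to pixel coordinates ``(u, v)``.

    The returned pixel may fall outside the sensor; callers that care
    filter on ``intr.width`` / ``intr.height``.  A point at or behind the
    camera plane (camera-frame z <= 0) raises :class:`CameraModelError`.
    """
    p_cam = pose.world_to_camera(np.asarray(world_point, dtype=float))[0]
    z = p_cam[2]
    if z <= 1e-12:
        raise CameraModelError("point at or behind the camera plane")
    xd, yd = distort_point((p_cam[0] / z, p_cam[1] / z), coeffs)
    return np.array([intr.fx * xd + intr.cx, intr.fy * yd + intr.cy])


def pixel_to_ray(uv, intr: Intrinsics, coeffs: DistortionCoefficients,
                 pose: CameraPose) -> Ray:
    """Back-project a pixel to its viewing ray in the world frame.

    Undistorts the pixel, takes the camera-frame points at z = 0 (the
    focal point) and z = 1 (the normalized image plane), and maps both
    through the inverse pose; the ray passes through the two images.
    """
    u, v = (float(c) for c in uv)
    if not (-0.5 <= u <= intr.width - 0.5 and -0.5 <= v <= intr.height - 0.5):
        raise CameraModelError(f"pixel ({u:.1f}, {v:.1f}) outside image bounds")
    x, y = undistort_point(((u - intr.cx) / intr.fx, (v - intr.cy) / intr.fy), coeffs)
    p0 = pose.camera_to_world(np.array([0.0, 0.0, 0.0]))[0]   # camera centre
    p1 = pose.camera_to_world(np.array([x, y, 1.0]))[0]
    return Ray(origin=p0, direction=p1 - p0)


# ---------------------------------------------------------------------------
# pose estimation (RANSAC Perspective-n-Point)


@dataclass(frozen=True)
class RansacConfig:
    """Parameters of the robust pose search."""

    n_iterations: int = 200
    inlier_threshold_px: float = 5.0
    seed: int = 0
    min_sample: int = 5


@dataclass(frozen=True)
class PoseEstimate:
    pose: CameraPose
    inliers: np.ndarray           # indices into the input point list
    reprojection_errors: np.ndarray  # per input point, pixels


def _reprojection_errors(pose: CameraPose, world: np.ndarray, pixels: np.ndarray,
                         intr: Intrinsics, coeffs: DistortionCoefficients) -> np.ndarray:
    errs = np.empty(len(world))
    for i, (w, px) in enumerate(zip(world, pixels)):
        try:
            proj = project_point(w, intr, coeffs, pose)
            errs[i] = np.linalg.norm(proj - px)
        except CameraModelError:
            errs[i] = np.inf
    return errs


def _pose_from_params(params: np.ndarray) -> CameraPose:
    R = Rotation.from_rotvec(params[:3]).as_matrix()
    return CameraPose(R, params[3:6])


def _refine_pose(initial: CameraPose, world: np.ndarray, norm_xy: np.ndarray) -> CameraPose:
    """Nonlinear least-squares on the undistorted (normalized) residuals."""

    def residual(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        cam = world @ R.T + params[3:6]
        z = np.where(np.abs(cam[:, 2]) < 1e-9, 1e-9, cam[:, 2])
        return np.concatenate([cam[:, 0] / z - norm_xy[:, 0],
                               cam[:, 1] / z - norm_xy[:, 1]])

    x0 = np.concatenate([Rotation.from_matrix(initial.rotation).as_rotvec(),
                         initial.translation])
    sol = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14)
    return _pose_from_params(sol.x)


def _solve_translation(R: np.ndarray, world: np.ndarray, norm_xy: np.ndarray) -> np.ndarray:
    """Linear least-squares for t given R: x' (r3.X + tz) = r1.X + tx etc."""
    n = len(world)
    A = np.zeros((2 * n, 3))
    b = np.zeros(2 * n)
    rw = world @ R.T  # R @ X per point
    A[0::2, 0] = -1.0
    A[0::2, 2] = norm_xy[:, 0]
    b[0::2] = rw[:, 0] - norm_xy[:, 0] * rw[:, 2]
    A[1::2, 1] = -1.0
    A[1::2, 2] = norm_xy[:, 1]
    b[1::2] = rw[:, 1] - norm_xy[:, 1] * rw[:, 2]
    t, *_ = np.linalg.lstsq(A, b, rcond=None)
    return t


def _coarse_orientation_grid(n_dirs: int = 64, n_rolls: int = 8):
    """Quasi-uniform optical-axis directions (Fibonacci sphere) x roll angles."""
    i = np.arange(n_dirs)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    zc = 1.0 - 2.0 * (i + 0.5) / n_dirs
    r = np.sqrt(np.maximum(0.0, 1.0 - zc * zc))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), zc])
    rolls = np.linspace(0.0, 2.0 * np.pi, n_rolls, endpoint=False)
    for d in dirs:
        # build any frame with optical axis d, then spin about it
        a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        x = np.cross(a, d)
        x /= np.linalg.norm(x)
        y = np.cross(d, x)
        base = np.vstack([x, y, d])
        for roll in rolls:
            c, s = np.cos(roll), np.sin(roll)
            spin = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
            yield spin @ base


def _solve_pnp_coarse(world: np.ndarray, norm_xy: np.ndarray) -> CameraPose | None:
    """Minimal-sample solver: exhaustive coarse orientation search.

    For each candidate rotation on a coarse grid, the translation is the
    linear least-squares fit; the best candidate by normalized residual
    seeds the nonlinear refinement.
    """
    best = None
    best_err = np.inf
    for R in _coarse_orientation_grid():
        t = _solve_translation(R, world, norm_xy)
        cam = world @ R.T + t
        if np.any(cam[:, 2] <= 1e-6):
            continue
        xy = cam[:, :2] / cam[:, 2:3]
        err = float(np.sum((xy - norm_xy) ** 2))
        if err < best_err:
            best_err = err
            best = CameraPose(R, t)
    if best is None:
        return None
    try:
        pose = _refine_pose(best, world, norm_xy)
    except CameraModelError:
        return None
    return pose


def _solve_pnp_dlt(world: np.ndarray, norm_xy: np.ndarray) -> CameraPose | None:
    """Direct linear transform on normalized coordinates (needs >=6 points)."""
    n = len(world)
    A = np.zeros((2 * n, 12))
    X = np.column_stack([world, np.ones(n)])
    A[0::2, 0:4] = X
    A[0::2, 8:12] = -norm_xy[:, 0:1] * X
    A[1::2, 4:8] = X
    A[1::2, 8:12] = -norm_xy[:, 1:2] * X
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    M = P[:, :3]
    # recover scale and sign so that M is a rotation with points in front
    scale = np.linalg.det(M)
    if abs(scale) < 1e-12:
        return None
    P = P * np.sign(scale) / abs(scale) ** (1.0 / 3.0)
    M = P[:, :3]
    U, _, Vt2 = np.linalg.svd(M)
    R = U @ Vt2
    if np.linalg.det(R) < 0:
        R = -R
    t = np.linalg.solve(M, P[:, 3])  # undo the non-orthogonal part on t
    t = R @ t
    try:
        pose = _refine_pose(CameraPose(R, t), world, norm_xy)
    except (CameraModelError, np.linalg.LinAlgError):
        return None
    return pose


def estimate_pose_ransac_pnp(
    points: Sequence[CalibrationPoint],
    intr: Intrinsics,
    coeffs: DistortionCoefficients,
    config: RansacConfig | None = None,
) -> PoseEstimate:
    """Estimate the camera pose from landmark correspondences, robustly.

    Runs RANSAC over minimal samples of the calibration points; each
    sample is solved by PnP (direct linear transform for samples of six
    or more, exhaustive coarse orientation search for five), candidate
    poses are scored by pixel reprojection error, and the pose is refit
    on the full consensus set before returning.

    Raises :class:`CameraModelError` with fewer than five points or when
    no consensus set of at least five inliers exists.
    """
    config = config or RansacConfig()
    points = list(points)
    n = len(points)
    if n < 5:
        raise CameraModelError(f"pose estimation needs >=5 landmarks, got {n}")
    world = np.array([p.world for p in points], dtype=float)
    pixels = np.array([p.pixel for p in points], dtype=float)
    for u, v in pixels:
        if not (-0.5 <= u <= intr.width - 0.5 and -0.5 <= v <= intr.height - 0.5):
            raise CameraModelError(f"calibration pixel ({u}, {v}) outside image bounds")
    norm_xy = np.array(
        [undistort_point(((u - intr.cx) / intr.fx, (v - intr.cy) / intr.fy), coeffs)
         for u, v in pixels]
    )

    sample_size = max(config.min_sample, 5)
    sample_size = min(max(sample_size, 6), n) if n >= 6 else 5
    rng = np.random.default_rng(config.seed)

    best_pose: CameraPose | None = None
    best_inliers: np.ndarray | None = None
    n_iter = 1 if sample_size == n else config.n_iterations
    for _ in range(n_iter):
        idx = rng.choice(n, size=sample_size, replace=False)
        solver = _solve_pnp_dlt if sample_size >= 6 else _solve_pnp_coarse
        pose = solver(world[idx], norm_xy[idx])
        if pose is None:
            continue
        errs = _reprojection_errors(pose, world, pixels, intr, coeffs)
        inliers = np.flatnonzero(errs <= config.inlier_threshold_px)
        if best_inliers is None or len(inliers) > len(best_inliers):
            best_pose, best_inliers = pose, inliers
            if len(inliers) == n:
                break
    if best_pose is None or best_inliers is None or len(best_inliers) < 5:
        raise CameraModelError("RANSAC found no consensus set of >=5 landmarks")

    # final refit on every inlier
    refined = _refine_pose(best_pose, world[best_inliers], norm_xy[best_inliers])
    errs = _reprojection_errors(refined, world, pixels, intr, coeffs)
    inliers = np.flatnonzero(errs <= config.inlier_threshold_px)
    return PoseEstimate(pose=refined, inliers=inliers, reprojection_errors=errs)
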