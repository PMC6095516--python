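"""Behavioural summaries of a reconstructed 3D trajectory.

Given per-frame positions in pool coordinates this module computes:

* zone occupancy — the pool is partitioned into *Bottom* (anything
  deeper than the shallow-area maximum depth, 1.4 m by default),
  *Deep Area* (at or above that depth and horizontally over the
  maximal-depth floor region) and *Shallow Area* (the rest);
* per-frame speeds from consecutive-frame displacements, a three-band
  speed classification, and time-in-band summaries;
* "swimming rings": complete circuits around the pool, detected as
  2*pi accumulations of unwrapped azimuth about the deep-area centre,
  with per-ring size, duration and speed metrics;
* time spent inside named regions of interest (trainer station, gates).

Speed bands follow the equal-width-thirds convention: the observed
maximum speed is split into three equal intervals (for a 5.1 m/s
maximum: 0-1.7 low, 1.7-3.4 intermediate, 3.4-5.1 high).  A
rank-based (true data-tertile) mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from shapely.geometry import Point, Polygon

from .reconstruction import Trajectory3D

__all__ = [
    "PoolGeometry",
    "SpeedSeries",
    "Ring",
    "RingSet",
    "AnalyticsError",
    "compute_speeds",
    "frame_interval_ms",
    "speed_category_bounds",
    "speed_time_summary",
    "classify_zone",
    "occupancy_summary",
    "detect_rings",
    "ring_metrics",
    "region_time",
    "ZONE_LABELS",
]

ZONE_LABELS = ("Deep Area", "Shallow Area", "Bottom")
SPEED_LABELS = ("low", "intermediate", "high")


class AnalyticsError(ValueError):
    pass


def _regular_polygon(radius: float, n: int = 24, centre=(0.0, 0.0)) -> list[tuple[float, float]]:
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return [(centre[0] + radius * np.cos(a), centre[1] + radius * np.sin(a))
            for a in ang]


@dataclass
class PoolGeometry:
    """Geometry of the circular experimental pool.

    Defaults describe a 21 m diameter pool with a 5 m maximum depth whose
    shallow shelf reaches about 1.4 m; the deep-area footprint defaults
    to a 7 m radius regular polygon around the pool centre and can be
    replaced by a surveyed vertex list.  ``regions`` holds named
    horizontal polygons such as the trainer station or viewing gates.
    """

    diameter: float = 21.0
    max_depth: float = 5.0
    shallow_max_depth: float = 1.4
    deep_area_polygon: Sequence[tuple[float, float]] | None = None
    regions: dict[str, Sequence[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.shallow_max_depth < self.max_depth):
            raise AnalyticsError("need 0 < shallow_max_depth < max_depth")
        if self.deep_area_polygon is None:
            self.deep_area_polygon = _regular_polygon(self.diameter / 3.0)
        self._deep = Polygon(self.deep_area_polygon)
        if not self._deep.is_valid or self._deep.area <= 0:
            raise AnalyticsError("deep_area_polygon must be a simple polygon")
        self._regions = {}
        for name, verts in self.regions.items():
            poly = Polygon(verts)
            if not poly.is_valid or poly.area <= 0:
                raise AnalyticsError(f"region '{name}' polygon is degenerate")
            self._regions[name] = poly

    @property
    def deep_polygon(self) -> Polygon:
        return self._deep

    @property
    def deep_area_centre(self) -> tuple[float, float]:
        c = self._deep.centroid
        return (c.x, c.y)

    def region_polygon(self, name: str) -> Polygon:
        return self._regions[name]


@dataclass
class SpeedSeries:
    """Per-frame speed (m/s) with the three-band classification."""

    speeds: np.ndarray              # NaN where undefined (first frame, gaps)
    fps: float
    max_speed: float
    bounds: tuple[float, float]     # (low_upper, mid_upper)
    from_interpolated: np.ndarray   # speed involves an interpolated position

    def categories(self) -> np.ndarray:
        """Per-frame band index: 0 low, 1 intermediate, 2 high, -1 undefined."""
        cats = np.full(len(self.speeds), -1, dtype=int)
        defined = np.isfinite(self.speeds)
        b1, b2 = self.bounds
        cats[defined & (self.speeds < b1)] = 0
        cats[defined & (self.speeds >= b1) & (self.speeds < b2)] = 1
        cats[defined & (self.speeds >= b2)] = 2
        return cats


@dataclass(frozen=True)
class Ring:
    """One complete circuit around the ring centre."""

    start_frame: int
    end_frame: int
    duration_frames: int
    duration_s: float
    path_length_m: float
    start_end_distance_m: float
    mean_speed_mps: float
    mean_radius_m: float
    direction: int                  # +1 counter-clockwise, -1 clockwise


@dataclass
class RingSet:
    rings: list[Ring] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rings)

    def __iter__(self):
        return iter(self.rings)


# ---------------------------------------------------------------------------
# speeds


def compute_speeds(traj: Trajectory3D, *, rank_tertiles: bool = False) -> SpeedSeries:
    """Per-frame speed from consecutive-frame displacements.

    ``speed[i] = |P_i - P_{i-1}| * fps`` wherever frames i-1 and i are
    both valid; the frame after a gap carries no speed.  The maximum is
    taken over speeds not involving interpolated positions, and the
    band bounds split [0, max] into equal thirds (or, with
    ``rank_tertiles``, at the 33.3/66.7 percentiles of observed speeds).
    """
    pos, valid = traj.positions, traj.valid
    n = len(pos)
    speeds = np.full(n, np.nan)
    from_interp = np.zeros(n, dtype=bool)
    pair = valid[1:] & valid[:-1]
    if not np.any(pair):
        raise AnalyticsError("no consecutive pair of valid frames")
    disp = np.linalg.norm(pos[1:] - pos[:-1], axis=1)
    speeds[1:][pair] = disp[pair] * traj.fps
    from_interp[1:] = traj.interpolated[1:] | traj.interpolated[:-1]
    measured = np.isfinite(speeds) & ~from_interp
    if not np.any(measured):
        measured = np.isfinite(speeds)
    max_speed = float(np.max(speeds[measured]))
    if rank_tertiles:
        vals = speeds[np.isfinite(speeds)]
        b1, b2 = (float(v) for v in np.percentile(vals, [100 / 3, 200 / 3]))
        bounds = (b1, b2)
    else:
        bounds = speed_category_bounds(max_speed) if max_speed > 0 else (0.0, 0.0)
    return SpeedSeries(speeds=speeds, fps=traj.fps, max_speed=max_speed,
                       bounds=bounds, from_interpolated=from_interp)


def frame_interval_ms(fps: float) -> float:
    """Duration of one frame in milliseconds, rounded to 2 decimals."""
    if fps <= 0:
        raise AnalyticsError("fps must be positive")
    return round(1000.0 / fps, 2)


def speed_category_bounds(max_speed: float) -> tuple[float, float]:
    """Equal-width three-band split of [0, max_speed]."""
    if max_speed <= 0:
        raise AnalyticsError("max_speed must be positive")
    return (max_speed / 3.0, 2.0 * max_speed / 3.0)


def speed_time_summary(speeds: SpeedSeries, fps: float | None = None) -> dict:
    """Time and percentage spent in each speed band.

    Bands are low [0, b1), intermediate [b1, b2), high [b2, max];
    percentages are over frames with a defined speed and sum to 100.
    """
    fps = fps or speeds.fps
    cats = speeds.categories()
    total = int(np.sum(cats >= 0))
    out = {}
    for k, name in enumerate(SPEED_LABELS):
        count = int(np.sum(cats == k))
        out[name] = {
            "frames": count,
            "minutes": count / fps / 60.0,
            "percent": 100.0 * count / total if total else 0.0,
        }
    out["max_speed_mps"] = speeds.max_speed
    out["bounds_mps"] = list(speeds.bounds)
    return out


# ---------------------------------------------------------------------------
# zones


def classify_zone(position, pool: PoolGeometry) -> str | None:
    """Assign one of Bottom / Deep Area / Shallow Area to a position.

    Depth wins: anything deeper than ``shallow_max_depth`` is Bottom
    regardless of horizontal location; at or above that depth the
    horizontal point is Deep Area inside the deep-area footprint
    (boundary included) and Shallow Area outside.  Invalid (non-finite)
    positions get no label.
    """
    p = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(p)):
        return None
    if p[2] > pool.shallow_max_depth:
        return "Bottom"
    if pool.deep_polygon.covers(Point(p[0], p[1])):
        return "Deep Area"
    return "Shallow Area"


def classify_zones(traj: Trajectory3D, pool: PoolGeometry) -> np.ndarray:
    """Vector of zone labels per frame ('' for invalid frames)."""
    labels = np.array([""] * traj.n_frames, dtype=object)
    for i in np.flatnonzero(traj.valid):
        labels[i] = classify_zone(traj.positions[i], pool) or ""
    return labels


def occupancy_summary(traj: Trajectory3D, pool: PoolGeometry,
                      fps: float | None = None) -> dict:
    """Per-zone minutes and percentage of valid frames."""
    fps = fps or traj.fps
    labels = classify_zones(traj, pool)
    total = int(np.sum(labels != ""))
    out = {}
    for zone in ZONE_LABELS:
        count = int(np.sum(labels == zone))
        out[zone] = {
            "frames": count,
            "minutes": count / fps / 60.0,
            "percent": 100.0 * count / total if total else 0.0,
        }
    out["total_valid_minutes"] = total / fps / 60.0
    return out


# ---------------------------------------------------------------------------
# swimming rings


def detect_rings(traj: Trajectory3D, pool: PoolGeometry, *,
                 centre: tuple[float, float] | None = None,
                 min_radius_m: float = 2.0) -> RingSet:
    """Find complete circuits around the pool.

    The azimuth of each valid position about the ring centre (the
    deep-area centroid by default) is unwrapped; a ring is a maximal
    frame span whose cumulative angle change reaches 2*pi in either
    direction.  The frame at which the accumulation first reaches
    +/-2*pi closes the ring and opens the next, with the overshoot
    carried over so k uniform turns yield k equal rings.  Candidate
    spans whose mean horizontal radius is below ``min_radius_m`` are
    rejected (dwelling near the centre is not circling).
    """
    cx, cy = centre if centre is not None else pool.deep_area_centre
    idx = np.flatnonzero(traj.valid)
    rings: list[Ring] = []
    if len(idx) < 3:
        return RingSet(rings)
    # 1e-9 rad slack keeps exact full-turn paths symmetric under reversal
    full_turn = 2 * np.pi - 1e-9
    confirm_w = 5   # samples whose median must also be past the turn
    # rings never span detection gaps: process each contiguous run alone
    run_breaks = np.flatnonzero(np.diff(idx) != 1) + 1
    for run in np.split(np.arange(len(idx)), run_breaks):
        if len(run) < 3:
            continue
        frames = idx[run]
        rel = traj.positions[frames, :2] - (cx, cy)
        theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        radius = np.linalg.norm(rel, axis=1)
        if len(theta) >= 9:
            # local linear fit: exact for steady circling (edges included),
            # suppresses per-frame jitter in the turn boundaries
            theta = savgol_filter(theta, 9, 1, mode="interp")
        seg_start, carry = 0, 0.0
        for k in range(1, len(frames)):
            cum = theta[k] - theta[seg_start] + carry
            if abs(cum) < full_turn:
                continue
            # confirm against position jitter: the median accumulated angle
            # over the next few samples must also be past the full turn
            # (a no-op on monotone, noise-free azimuth)
            w = theta[k:k + confirm_w] - theta[seg_start] + carry
            if float(np.median(np.sign(cum) * w)) < full_turn:
                continue
            if float(np.mean(radius[seg_start:k + 1])) >= min_radius_m:
                rings.append(ring_metrics(
                    (int(frames[seg_start]), int(frames[k])), traj, traj.fps,
                    centre=(cx, cy),
                    direction=1 if cum > 0 else -1))
            carry = cum - np.sign(cum) * 2 * np.pi
            seg_start = k
    return RingSet(rings)


def ring_metrics(span: tuple[int, int], traj: Trajectory3D,
                 fps: float | None = None, *,
                 centre: tuple[float, float] = (0.0, 0.0),
                 direction: int = 0) -> Ring:
    """Size, duration and speed metrics for one ring span (inclusive)."""
    fps = fps or traj.fps
    start, end = span
    if end <= start:
        raise AnalyticsError("ring span must cover at least two frames")
    pos = traj.positions[start:end + 1]
    pos = pos[np.all(np.isfinite(pos), axis=1)]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path_length = float(np.sum(steps))
    start_end = float(np.linalg.norm(pos[-1] - pos[0]))
    duration_frames = end - start
    duration_s = duration_frames / fps
    rel = pos[:, :2] - np.asarray(centre)
    return Ring(
        start_frame=start,
        end_frame=end,
        duration_frames=duration_frames,
        duration_s=duration_s,
        path_length_m=path_length,
        start_end_distance_m=start_end,
        mean_speed_mps=path_length / duration_s if duration_s > 0 else 0.0,
        mean_radius_m=float(np.mean(np.linalg.norm(rel, axis=1))),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# regions of interest


def region_time(traj: Trajectory3D, region: Sequence[tuple[float, float]] | Polygon,
                fps: float | None = None) -> dict:
    """Minutes and percentage of valid frames spent over a horizontal region."""
    fps = fps or traj.fps
    poly = region if isinstance(region, Polygon) else Polygon(region)
    if not poly.is_valid or poly.area <= 0:
        raise AnalyticsError("region polygon is degenerate")
    idx = np.flatnonzero(traj.valid)
    inside = sum(
        1 for i in idx if poly.covers(Point(traj.positions[i, 0],
                                            traj.positions[i, 1])))
    total = len(idx)
    return {
        "frames": int(inside),
        "minutes": inside / fps / 60.0,
        "percent": 100.0 * inside / total if total else 0.0,
    }
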