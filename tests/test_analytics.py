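"""Zone occupancy, speed bands, swimming rings and region time."""

import numpy as np
import pytest

from dtrack.analytics import (AnalyticsError, PoolGeometry, classify_zone,
                              compute_speeds, detect_rings, frame_interval_ms,
                              occupancy_summary, region_time, ring_metrics,
                              speed_category_bounds, speed_time_summary)
from dtrack.reconstruction import Trajectory3D

FPS = 30.0


def make_traj(xyz, valid=None, fps=FPS):
    xyz = np.asarray(xyz, dtype=float)
    if valid is None:
        valid = np.ones(len(xyz), dtype=bool)
    return Trajectory3D(positions=xyz, valid=valid, fps=fps)


def circle_traj(radius=6.0, turns=2.0, n=300, depth=0.5, direction=1,
                centre=(0.0, 0.0)):
    ang = direction * 2 * np.pi * turns * np.arange(n) / (n - 1)
    return make_traj(np.column_stack([
        centre[0] + radius * np.cos(ang),
        centre[1] + radius * np.sin(ang),
        np.full(n, depth)]))


@pytest.fixture
def pool():
    return PoolGeometry()


class TestSpeeds:
    def test_tenth_metre_per_frame_is_three_mps(self):
        xyz = np.column_stack([np.arange(10) * 0.1, np.zeros(10), np.zeros(10)])
        speeds = compute_speeds(make_traj(xyz))
        assert np.allclose(speeds.speeds[1:], 3.0)
        assert np.isnan(speeds.speeds[0])

    def test_stationary_trajectory_zero_speed(self):
        speeds = compute_speeds(make_traj(np.tile([(1.0, 1.0, 0.5)], (10, 1))))
        assert np.allclose(speeds.speeds[1:], 0.0)

    def test_circular_motion_matches_chord_formula(self):
        r, omega, n = 5.0, 0.04, 200  # omega in rad/frame
        ang = omega * np.arange(n)
        traj = make_traj(np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                          np.full(n, 0.5)]))
        speeds = compute_speeds(traj)
        expected = 2 * r * np.sin(omega / 2) * FPS
        assert np.allclose(speeds.speeds[1:], expected, atol=1e-9)

    def test_gap_frames_carry_no_speed(self):
        valid = np.ones(10, dtype=bool)
        valid[4] = False
        speeds = compute_speeds(make_traj(np.random.default_rng(0).uniform(
            0, 1, (10, 3)), valid))
        assert np.isnan(speeds.speeds[4]) and np.isnan(speeds.speeds[5])

    def test_no_consecutive_pair_rejected(self):
        valid = np.array([True, False, True, False, True])
        with pytest.raises(AnalyticsError):
            compute_speeds(make_traj(np.zeros((5, 3)), valid))


class TestConversions:
    @pytest.mark.parametrize("fps,expected", [(30, 33.33), (1000, 1.0), (25, 40.0)])
    def test_frame_interval_ms(self, fps, expected):
        assert frame_interval_ms(fps) == expected

    def test_non_positive_fps_rejected(self):
        with pytest.raises(AnalyticsError):
            frame_interval_ms(0)

    @pytest.mark.parametrize("max_speed,expected", [
        (5.1, (1.7, 3.4)), (3.0, (1.0, 2.0)), (9.0, (3.0, 6.0)),
    ])
    def test_equal_width_speed_bands(self, max_speed, expected):
        assert speed_category_bounds(max_speed) == pytest.approx(expected)

    def test_non_positive_max_speed_rejected(self):
        with pytest.raises(AnalyticsError):
            speed_category_bounds(0.0)


class TestSpeedSummary:
    def test_single_speed_occupies_one_band(self):
        xyz = np.column_stack([np.arange(61) * 0.1, np.zeros(61), np.zeros(61)])
        summary = speed_time_summary(compute_speeds(make_traj(xyz)))
        # constant 3 m/s = the max, so everything lands in the high band
        assert summary["high"]["percent"] == pytest.approx(100.0)
        assert summary["low"]["frames"] == summary["intermediate"]["frames"] == 0

    def test_scripted_bands_counted_exactly(self):
        # per-frame steps scripted to give speeds 1, 3 and 5 m/s
        steps = [1.0 / FPS] * 30 + [3.0 / FPS] * 30 + [5.0 / FPS] * 30
        x = np.concatenate([[0.0], np.cumsum(steps)])
        summary = speed_time_summary(compute_speeds(make_traj(
            np.column_stack([x, np.zeros(91), np.zeros(91)]))))
        # max 5 -> bands [0, 5/3), [5/3, 10/3), [10/3, 5]
        for band in ("low", "intermediate", "high"):
            assert summary[band]["frames"] == 30
            assert summary[band]["percent"] == pytest.approx(100.0 / 3)
        total = sum(summary[b]["percent"] for b in ("low", "intermediate", "high"))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_minutes_from_frame_counts(self):
        xyz = np.column_stack([np.arange(1801) * 0.01, np.zeros(1801),
                               np.zeros(1801)])
        summary = speed_time_summary(compute_speeds(make_traj(xyz)))
        assert summary["high"]["minutes"] == pytest.approx(1.0)


class TestZones:
    def test_deep_depth_is_bottom_anywhere(self, pool):
        assert classify_zone((0.0, 0.0, 3.0), pool) == "Bottom"
        assert classify_zone((9.0, 3.0, 3.0), pool) == "Bottom"

    def test_surface_inside_deep_polygon(self, pool):
        assert classify_zone((0.0, 0.0, 0.2), pool) == "Deep Area"

    def test_surface_outside_deep_polygon(self, pool):
        assert classify_zone((9.5, 0.0, 0.2), pool) == "Shallow Area"

    def test_boundary_depth_is_not_bottom(self, pool):
        assert classify_zone((0.0, 0.0, 1.4), pool) == "Deep Area"

    def test_invalid_position_unlabelled(self, pool):
        assert classify_zone((np.nan, 0.0, 1.0), pool) is None

    def test_every_position_gets_exactly_one_zone(self, pool):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = (rng.uniform(-10, 10), rng.uniform(-10, 10), rng.uniform(0, 5))
            assert classify_zone(p, pool) in ("Deep Area", "Shallow Area",
                                              "Bottom")


class TestOccupancy:
    def test_single_zone_full_occupancy(self, pool):
        traj = make_traj(np.tile([(0.0, 0.0, 0.2)], (1800, 1)))
        summary = occupancy_summary(traj, pool)
        assert summary["Deep Area"]["minutes"] == pytest.approx(1.0)
        assert summary["Deep Area"]["percent"] == pytest.approx(100.0)

    def test_469_frames_is_15_63_seconds(self, pool):
        traj = make_traj(np.tile([(0.0, 0.0, 0.2)], (469, 1)))
        summary = occupancy_summary(traj, pool)
        assert summary["Deep Area"]["minutes"] * 60 == pytest.approx(15.63,
                                                                     abs=0.005)

    def test_scripted_schedule_recovered(self, pool):
        xyz = np.vstack([
            np.tile([(0.0, 0.0, 0.2)], (300, 1)),    # Deep Area
            np.tile([(9.5, 0.0, 0.2)], (150, 1)),    # Shallow Area
            np.tile([(0.0, 0.0, 3.0)], (150, 1)),    # Bottom
        ])
        summary = occupancy_summary(make_traj(xyz), pool)
        assert summary["Deep Area"]["frames"] == 300
        assert summary["Shallow Area"]["frames"] == 150
        assert summary["Bottom"]["frames"] == 150
        pct = sum(summary[z]["percent"] for z in
                  ("Deep Area", "Shallow Area", "Bottom"))
        assert pct == pytest.approx(100.0, abs=1e-9)
        minutes = sum(summary[z]["minutes"] for z in
                      ("Deep Area", "Shallow Area", "Bottom"))
        assert minutes == pytest.approx(summary["total_valid_minutes"], abs=1e-6)


class TestRings:
    def test_two_turns_give_two_rings(self, pool):
        rings = detect_rings(circle_traj(turns=2.0, n=301), pool)
        assert len(rings) == 2
        durations = [r.duration_frames for r in rings]
        assert all(abs(d - 150) <= 2 for d in durations)

    def test_back_and_forth_arc_gives_no_ring(self, pool):
        n = 200
        ang = np.pi * np.sin(np.linspace(0, 2 * np.pi, n))  # sweeps +/-180 deg
        traj = make_traj(np.column_stack([
            6 * np.cos(ang), 6 * np.sin(ang), np.full(n, 0.5)]))
        assert len(detect_rings(traj, pool)) == 0

    def test_jitter_does_not_change_ring_count(self, pool):
        # a few frames of margin past the third turn, as a generator would add
        clean = circle_traj(turns=3.05, n=458)
        rng = np.random.default_rng(7)
        noisy = make_traj(clean.positions + rng.normal(0, 0.1, (458, 3)))
        assert len(detect_rings(noisy, pool)) == len(detect_rings(clean, pool)) == 3

    def test_reversed_trajectory_same_rings(self, pool):
        traj = circle_traj(turns=2.0, n=301)
        rev = make_traj(traj.positions[::-1])
        r1 = detect_rings(traj, pool)
        r2 = detect_rings(rev, pool)
        assert len(r1) == len(r2)
        assert sorted(r.duration_frames for r in r1) == sorted(
            r.duration_frames for r in r2)

    def test_small_radius_circling_rejected(self, pool):
        rings = detect_rings(circle_traj(radius=1.0, turns=3.0, n=300), pool,
                             min_radius_m=2.0)
        assert len(rings) == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_k_turn_recovery(self, pool, k):
        rings = detect_rings(circle_traj(turns=float(k), n=150 * k + 1), pool)
        assert len(rings) == k


class TestRingMetrics:
    def test_469_frame_ring_duration(self):
        traj = circle_traj(turns=1.0, n=470)
        ring = ring_metrics((0, 469), traj, FPS)
        assert ring.duration_frames == 469
        assert ring.duration_s == pytest.approx(15.63, abs=0.005)

    def test_closed_circle_geometry(self):
        r = 6.0
        traj = circle_traj(radius=r, turns=1.0, n=301)
        ring = ring_metrics((0, 300), traj, FPS)
        assert ring.start_end_distance_m == pytest.approx(0.0, abs=1e-9)
        assert ring.path_length_m == pytest.approx(2 * np.pi * r, rel=1e-3)
        assert ring.mean_radius_m == pytest.approx(r, abs=1e-9)

    def test_sampled_circle_chord_sum(self):
        r, n = 5.0, 100
        ang = 2 * np.pi * np.arange(n + 1) / n
        traj = make_traj(np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                          np.full(n + 1, 0.5)]))
        ring = ring_metrics((0, n), traj, FPS)
        assert ring.path_length_m == pytest.approx(
            n * 2 * r * np.sin(np.pi / n), abs=1e-9)

    def test_path_never_shorter_than_endpoints(self):
        rng = np.random.default_rng(4)
        traj = make_traj(rng.uniform(-5, 5, (50, 3)))
        ring = ring_metrics((0, 49), traj, FPS)
        assert ring.path_length_m >= ring.start_end_distance_m


class TestRegions:
    square = [(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)]

    def test_never_inside(self):
        traj = make_traj(np.tile([(5.0, 5.0, 0.5)], (100, 1)))
        out = region_time(traj, self.square)
        assert out["frames"] == 0 and out["percent"] == 0.0

    def test_always_inside(self):
        traj = make_traj(np.tile([(0.0, 0.0, 0.5)], (100, 1)))
        assert region_time(traj, self.square)["percent"] == pytest.approx(100.0)

    def test_quarter_schedule(self):
        xyz = np.vstack([np.tile([(0.0, 0.0, 0.5)], (25, 1)),
                         np.tile([(5.0, 5.0, 0.5)], (75, 1))])
        out = region_time(make_traj(xyz), self.square)
        assert out["percent"] == pytest.approx(25.0)
        assert out["minutes"] == pytest.approx(25 / FPS / 60)

    def test_degenerate_polygon_rejected(self):
        traj = make_traj(np.zeros((10, 3)))
        with pytest.raises(AnalyticsError):
            region_time(traj, [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])


class TestPoolGeometry:
    def test_depth_ordering_enforced(self):
        with pytest.raises(AnalyticsError):
            PoolGeometry(shallow_max_depth=6.0, max_depth=5.0)

    def test_degenerate_region_rejected(self):
        with pytest.raises(AnalyticsError):
            PoolGeometry(regions={"bad": [(0, 0), (1, 1), (2, 2)]})
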