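import numpy as np
import pytest

from ramtrack import behavior, metrics, synthetic
from ramtrack.metrics import (
    Trajectory,
    average_speed,
    build_report,
    detect_s_spots,
    path_length,
    region_time_fractions,
    zone_histogram,
)
from ramtrack.tracker import TargetPos


def make_traj(xy, cm_per_px=0.4, period=0.05, found=None):
    xy = np.asarray(xy, float)
    n = xy.shape[0]
    found = np.ones(n, bool) if found is None else np.asarray(found, bool)
    return Trajectory(
        t=np.arange(n) * period,
        x=xy[:, 0],
        y=xy[:, 1],
        found=found,
        source=["single-outline"] * n,
        cm_per_px=cm_per_px,
        sample_period=period,
    )


def path_traj(geo, arm_visits, fps=20.0, speed=12.0, pause=2.0):
    wps, pauses = synthetic.session_waypoints(geo, arm_visits, food_pause_s=pause)
    path = synthetic.scripted_path(geo, wps, speed, fps, pauses)
    pts = [
        TargetPos(float(t), float(x), float(y), True, "single-outline")
        for t, (x, y) in zip(path.t, path.positions)
    ]
    traj = Trajectory.from_points(pts, geo.cm_per_px, 1.0 / fps)
    return traj, pts


class TestPathLength:
    def test_single_point(self):
        assert path_length(make_traj([(10, 10)])) == 0.0

    def test_two_points(self):
        # 100 px apart at 0.25 cm/px -> 25 cm -> 0.25 m
        traj = make_traj([(0, 0), (100, 0)], cm_per_px=0.25)
        assert path_length(traj) == pytest.approx(0.25)

    def test_square_loop(self, geo):
        """1 m square loop (sides along the axes) has length 4 m."""
        side_px = 100.0 / geo.cm_per_px  # 1 m
        c = np.array(geo.center) - side_px / 2
        corners = [c, c + (side_px, 0), c + (side_px, side_px), c + (0, side_px), c]
        pts = []
        for a, b in zip(corners[:-1], corners[1:]):
            for f in np.linspace(0, 1, 50, endpoint=False):
                pts.append(a + f * (np.asarray(b) - a))
        pts.append(corners[-1])
        traj = make_traj(pts, cm_per_px=geo.cm_per_px)
        assert path_length(traj) == pytest.approx(4.0, rel=1e-6)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 100, (50, 2))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert path_length(make_traj(xy @ rot.T)) == pytest.approx(path_length(make_traj(xy)))

    def test_carried_forward_adds_no_displacement(self):
        xy = [(0, 0), (10, 0), (10, 0), (10, 0), (20, 0)]
        found = [True, True, False, False, True]
        traj = make_traj(xy, cm_per_px=1.0, found=found)
        assert path_length(traj) == pytest.approx(0.20)


class TestSpeed:
    def test_static(self):
        assert average_speed(make_traj([(5, 5)] * 10)) == 0.0

    def test_constant_speed_script(self, geo):
        """Scripted 12 cm/s motion recovers within 2%."""
        wps = [geo.center, geo.food_zone_center(0, segment=8)]
        path = synthetic.scripted_path(geo, wps, 12.0, 20.0)
        traj = make_traj(path.positions, cm_per_px=geo.cm_per_px)
        assert average_speed(traj) == pytest.approx(12.0, rel=0.02)

    def test_identity_speed_times_duration(self):
        rng = np.random.default_rng(8)
        traj = make_traj(rng.uniform(0, 200, (30, 2)))
        assert average_speed(traj) * traj.duration == pytest.approx(100 * path_length(traj))

    def test_zero_duration_error(self):
        with pytest.raises(ValueError):
            average_speed(make_traj([(0, 0)]))


class TestRegionFractions:
    def test_all_platform(self, geo):
        traj = make_traj([geo.center] * 20, cm_per_px=geo.cm_per_px)
        assert region_time_fractions(traj, geo, [2]) == (100.0, 0.0, 0.0)

    def test_half_baited(self, geo):
        tip = geo.food_zone_center(1)  # arm number 2
        xy = [geo.center] * 10 + [tip] * 10
        traj = make_traj(xy, cm_per_px=geo.cm_per_px)
        assert region_time_fractions(traj, geo, [2]) == (50.0, 50.0, 0.0)

    def test_nonbaited_and_outside(self, geo):
        tip = geo.food_zone_center(2)  # arm number 3, not baited
        out = (2.0, 2.0)
        xy = [geo.center] * 5 + [tip] * 10 + [out] * 5
        traj = make_traj(xy, cm_per_px=geo.cm_per_px)
        plat, baited, nonb = region_time_fractions(traj, geo, [2])
        assert (plat, baited, nonb) == (25.0, 0.0, 50.0)
        assert plat + baited + nonb <= 100.0

    def test_scripted_dwell(self, geo):
        """Scripted session: recovered fractions within one sample period of
        the classification of the true positions."""
        traj, _ = path_traj(geo, [2, 5], pause=3.0)
        plat, baited, nonb = region_time_fractions(traj, geo, [2, 4])
        from ramtrack.geometry import classify_points

        region, arm, _ = classify_points(geo, traj.x, traj.y)
        n = len(traj)
        tol = 100.0 / n
        assert plat == pytest.approx(100 * np.mean(region == 0), abs=tol)
        assert baited == pytest.approx(100 * np.mean((region == 1) & (arm == 1)), abs=tol)


class TestSSpots:
    def test_stationary_session(self):
        traj = make_traj([(50, 50)] * 1201, period=0.05)  # 60 s
        spots = detect_s_spots(traj, radius_cm=2.5, min_duration_s=2.0)
        assert len(spots) == 1
        assert spots[0].duration == pytest.approx(60.0, abs=0.1)

    def test_constant_motion_no_spots(self):
        xy = [(i * 0.5 / 0.4, 0) for i in range(400)]  # 10 cm/s at 0.05 s ticks
        traj = make_traj(xy, period=0.05)
        assert detect_s_spots(traj, radius_cm=2.5, min_duration_s=2.0) == []

    def test_move_pause_script(self):
        """move, pause 10 s, move, pause 5 s -> two spots of those durations."""
        period, v = 0.05, 2.5  # px/tick = 12.5 cm/s at 0.4 cm/px
        xy = []
        xy += [(i * v, 0) for i in range(100)]
        xy += [(xy[-1][0] + v, 0)] * 200  # 10 s pause
        x1 = xy[-1][0]
        xy += [(x1 + i * v, 100) for i in range(100)]
        xy += [(xy[-1][0] + v, 100)] * 100  # 5 s pause
        traj = make_traj(xy, period=period)
        spots = detect_s_spots(traj, radius_cm=2.5, min_duration_s=2.0)
        assert len(spots) == 2
        assert spots[0].duration == pytest.approx(10.0, abs=0.15)
        assert spots[1].duration == pytest.approx(5.0, abs=0.15)

    def test_spots_disjoint_and_bounded(self, geo):
        traj, _ = path_traj(geo, [2, 7, 4], pause=3.0)
        spots = detect_s_spots(traj, 2.5, 2.0)
        total = sum(s.duration for s in spots)
        assert total <= traj.duration
        for a, b in zip(spots[:-1], spots[1:]):
            assert a.end <= b.start


class TestZoneHistogram:
    def test_single_zone(self, geo):
        traj = make_traj([geo.center] * 17, cm_per_px=geo.cm_per_px)
        counts = zone_histogram(traj, geo)
        assert counts[0] == 17 and counts.sum() == 17

    def test_conservation(self, geo):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 479, (500, 2))
        traj = make_traj(xy, cm_per_px=geo.cm_per_px)
        counts = zone_histogram(traj, geo)
        from ramtrack.geometry import classify_points

        region, _, _ = classify_points(geo, xy[:, 0], xy[:, 1])
        assert counts.sum() == int(np.sum(region >= 0))

    def test_uniform_occupancy_tracks_zone_areas(self, geo):
        """Uniform in-footprint samples land in each zone in proportion to its
        raster area (binomial 3-sigma bounds, one borderline zone tolerated
        among the 89 simultaneous comparisons)."""
        rng = np.random.default_rng(12)
        ys, xs = np.nonzero(geo.mask)
        idx = rng.integers(0, xs.size, 20_000)
        traj = make_traj(np.column_stack([xs[idx], ys[idx]]), cm_per_px=geo.cm_per_px)
        counts = zone_histogram(traj, geo)
        n = counts.sum()
        areas = np.bincount(geo.zone_map[geo.mask], minlength=geo.n_zones)
        p = areas / areas.sum()
        sigma = np.sqrt(n * p * (1 - p))
        dev = np.abs(counts - n * p) / sigma
        assert int(np.sum(dev > 3)) <= 1
        assert int(np.sum(dev > 4)) == 0


class TestReport:
    def test_perfect_rat(self, geo):
        """Visits the four baited arms once each: no errors, four entries."""
        traj, pts = path_traj(geo, [2, 4, 6, 8])
        state = behavior.score_trajectory(pts, geo, [2, 4, 6, 8])
        rep = build_report(traj, state, geo)
        assert (rep.short_term_errors, rep.long_term_errors) == (0, 0)
        assert sum(rep.entries) == 4
        assert rep.complete and rep.latency_s > 0
        assert rep.arm_sequence == (2, 4, 6, 8)

    def test_impaired_rat_reentries(self, geo):
        """Three re-entries into already-visited arms score three
        working-memory errors."""
        traj, pts = path_traj(geo, [2, 2, 4, 2, 6, 4, 8])
        state = behavior.score_trajectory(pts, geo, [2, 4, 6, 8])
        rep = build_report(traj, state, geo)
        assert rep.short_term_errors == 3
        assert rep.long_term_errors == 0

    def test_zero_baited(self, geo):
        traj, pts = path_traj(geo, [3])
        state = behavior.score_trajectory(pts, geo, [])
        rep = build_report(traj, state, geo)
        assert rep.latency_s == pytest.approx(0.0)
        assert rep.short_term_errors == 0 and rep.long_term_errors == 0

    def test_report_is_pure_function(self, geo):
        traj, pts = path_traj(geo, [2, 7, 4])
        state = behavior.score_trajectory(pts, geo, [2, 4])
        r1 = build_report(traj, state, geo)
        r2 = build_report(traj, state, geo)
        assert r1 == r2
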