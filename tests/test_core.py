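"""Geometric predicates, domain types, and the plain-text IO layer."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from mousepheno import (
    ArenaGeometry,
    StrategyCategory,
    StrategyLabel,
    Trajectory,
    distance_to_wall,
    in_corridor,
    platform_center_for_quadrant,
    quadrant_of,
    start_point,
)
from mousepheno.io import (
    read_arena_json,
    read_trajectory_csv,
    write_arena_json,
    write_trajectory_csv,
)

POOL = ArenaGeometry.pool()


class TestQuadrantOf:
    def test_quadrant_bisectors(self):
        # interior points on each quadrant's bisector
        for q in range(1, 5):
            px, py = platform_center_for_quadrant(q, POOL)
            assert quadrant_of((px, py), POOL) == q

    def test_center_tie_break(self):
        # angle of the exact center is undefined; the half-open convention
        # puts it in quadrant 1
        assert quadrant_of((0.0, 0.0), POOL) == 1

    def test_uniform_circle_splits_evenly(self):
        angs = np.radians(np.arange(360))
        qs = [quadrant_of((50 * math.cos(a), 50 * math.sin(a)), POOL) for a in angs]
        assert [qs.count(q) for q in (1, 2, 3, 4)] == [90, 90, 90, 90]

    def test_outside_arena_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            quadrant_of((80.0, 0.0), POOL)

    @given(
        r=st.floats(0.5, 76.0),
        ang=st.floats(0.0, 2 * math.pi, exclude_max=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_rotation_by_90_degrees_advances_quadrant(self, r, ang):
        # the exact center is a tie-break special case, hence r > 0
        p = (r * math.cos(ang), r * math.sin(ang))
        p_rot = (-p[1], p[0])  # +90 degrees
        q = quadrant_of(p, POOL)
        assert quadrant_of(p_rot, POOL) == q % 4 + 1


class TestDistanceToWall:
    def test_center_is_full_radius(self):
        assert distance_to_wall((0.0, 0.0), POOL) == 77.0

    def test_interior_point(self):
        assert distance_to_wall((70.0, 0.0), POOL) == pytest.approx(7.0)

    def test_outside_clipped_and_flagged(self):
        d, oob = distance_to_wall((78.0, 0.0), POOL, return_oob=True)
        assert d == 0.0 and oob

    def test_vectorized(self):
        d = distance_to_wall(np.array([[0.0, 0.0], [0.0, 70.0]]), POOL)
        assert np.allclose(d, [77.0, 7.0])


class TestInCorridor:
    START = (0.0, 73.0)
    PLATFORM = (27.2235, -27.2235)

    def test_midpoint_inside(self):
        mid = ((self.START[0] + self.PLATFORM[0]) / 2,
               (self.START[1] + self.PLATFORM[1]) / 2)
        assert in_corridor(mid, self.START, self.PLATFORM)

    def test_boundary_inclusive_at_half_width(self):
        s = np.array(self.START)
        p = np.array(self.PLATFORM)
        u = (p - s) / np.linalg.norm(p - s)
        n = np.array([-u[1], u[0]])
        mid = (s + p) / 2
        assert in_corridor(tuple(mid + 10.0 * n), self.START, self.PLATFORM)
        assert not in_corridor(tuple(mid + 10.5 * n), self.START, self.PLATFORM)

    def test_projection_capped_at_endpoints(self):
        s = np.array(self.START)
        p = np.array(self.PLATFORM)
        u = (p - s) / np.linalg.norm(p - s)
        behind = tuple(s - 1.0 * u)
        assert not in_corridor(behind, self.START, self.PLATFORM)

    def test_degenerate_corridor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            in_corridor((0, 0), (1.0, 1.0), (1.0, 1.0))

    @given(
        along=st.floats(-20.0, 130.0),
        perp=st.floats(-30.0, 30.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_reflection_symmetry_across_axis(self, along, perp):
        # stay clear of the inclusive band boundary, where 1-ulp rounding
        # of the constructed points can legitimately flip membership
        length = math.dist(self.START, self.PLATFORM)
        assume(abs(perp) < 9.99 or abs(perp) > 10.01)
        assume(abs(along) > 1e-3 and abs(along - length) > 1e-3)
        s = np.array(self.START)
        p = np.array(self.PLATFORM)
        u = (p - s) / np.linalg.norm(p - s)
        n = np.array([-u[1], u[0]])
        a = tuple(s + along * u + perp * n)
        b = tuple(s + along * u - perp * n)
        assert in_corridor(a, self.START, self.PLATFORM) == \
            in_corridor(b, self.START, self.PLATFORM)


class TestArenaGeometry:
    def test_platform_placement_half_way(self):
        arena = ArenaGeometry.pool(platform_quadrant=4)
        r = math.dist(arena.platform_center, arena.center)
        assert r == pytest.approx(154 / 4)

    def test_platform_outside_pool_rejected(self):
        with pytest.raises(ValueError):
            ArenaGeometry(kind="pool", platform_center=(70.0, 0.0))

    def test_platform_not_half_way_rejected(self):
        with pytest.raises(ValueError, match="half-way"):
            ArenaGeometry(kind="pool", platform_center=(10.0, 0.0))

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            ArenaGeometry(diameter_cm=-1.0)

    def test_start_points_on_cardinal_angles(self):
        n = start_point("N", POOL)
        assert n[0] == pytest.approx(0.0, abs=1e-9)
        assert n[1] == pytest.approx(73.0)
        e = start_point("E", POOL)
        assert e == (pytest.approx(73.0), pytest.approx(0.0, abs=1e-9))

    def test_json_round_trip(self, tmp_path):
        arena = ArenaGeometry.pool(platform_quadrant=2)
        path = tmp_path / "arena.json"
        write_arena_json(arena, path)
        assert read_arena_json(path) == arena


class TestStrategyLabel:
    def test_spatial_partition(self):
        spatial = {l for l in StrategyLabel if l.category is StrategyCategory.SPATIAL}
        assert spatial == {StrategyLabel.DSe, StrategyLabel.FS,
                           StrategyLabel.DSw, StrategyLabel.P}
        non_spatial = set(StrategyLabel) - spatial
        assert non_spatial == {StrategyLabel.T, StrategyLabel.RS,
                               StrategyLabel.S, StrategyLabel.C}


class TestTrajectory:
    def _mk(self, times, pts, **kw):
        return Trajectory(times=np.asarray(times), points=np.asarray(pts),
                          arena=POOL, **kw)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            self._mk([0.0], [[0, 0]])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            self._mk([0.0, 0.0], [[0, 0], [1, 1]])

    def test_point_outside_wall_rejected(self):
        with pytest.raises(ValueError, match="outside the arena"):
            self._mk([0.0, 1.0], [[0, 0], [0, 79.0]])

    def test_jitter_tolerance_inside_one_cm(self):
        traj = self._mk([0.0, 1.0], [[0, 0], [0, 77.9]])
        assert traj.n_samples == 2

    def test_duration_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            self._mk([0.0, 61.0], [[0, 0], [1, 1]], trial_type="swim")
        with pytest.raises(ValueError, match="cap"):
            self._mk([0.0, 31.0], [[0, 0], [1, 1]], trial_type="probe")

    def test_csv_round_trip(self, tmp_path):
        traj = self._mk([0.0, 0.1, 0.2], [[0, 0], [1, 1], [2, 0]],
                        start_position="N", platform_quadrant=4)
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        back = read_trajectory_csv(path, POOL, start_position="N",
                                   platform_quadrant=4)
        assert np.allclose(back.times, traj.times)
        assert np.allclose(back.points, traj.points)

    def test_csv_bad_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,x,y\n0.0,1.0,2.0\n0.1,oops,2.0\n")
        with pytest.raises(ValueError, match="rows 3"):
            read_trajectory_csv(path, POOL)
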