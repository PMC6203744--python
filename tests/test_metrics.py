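"""Trajectory metrics against analytic cases and independent oracles."""

import math

import numpy as np
import pytest

import oracles
from mousepheno import (
    ArenaGeometry,
    StrategyLabel,
    Trajectory,
    binned_speed,
    central_zone_path,
    corridor_percent_path,
    count_stops,
    extract_strides,
    latency,
    mean_speed,
    path_efficiency_ratio,
    path_length,
    quadrant_occupancy,
    simulate_open_field,
    simulate_stride_series,
    simulate_swim,
)
from mousepheno.simulate import SwimSimConfig

POOL = ArenaGeometry.pool(platform_quadrant=4)


def _traj(times, pts, trial_type="swim", **kw):
    return Trajectory(times=np.asarray(times, float),
                      points=np.asarray(pts, float),
                      arena=POOL, trial_type=trial_type, **kw)


def _sim(strategy, seed, noise=0.3, speed=0.22):
    cfg = SwimSimConfig(strategy=strategy, heading_noise_sd=noise,
                        speed_mps=speed)
    traj, _ = simulate_swim(cfg, start="N", platform_quadrant=4,
                            previous_platform_quadrant=3,
                            rng=np.random.default_rng(seed))
    return traj


class TestPathLengthAndSpeed:
    def test_stationary_trace_has_zero_length(self):
        traj = _traj([0, 30, 60], [[5, 5]] * 3)
        assert path_length(traj) == 0.0

    def test_straight_100cm_segment(self):
        traj = _traj([0, 10], [[-50, 0], [50, 0]])
        assert path_length(traj) == pytest.approx(1.0)
        assert mean_speed(traj) == pytest.approx(0.1)

    def test_simulated_path_matches_fsum_oracle(self):
        traj = _sim(StrategyLabel.C, seed=7)
        assert path_length(traj) == pytest.approx(
            oracles.polyline_length_m(traj.points), rel=1e-12)

    def test_constant_speed_walk_has_equal_bins(self):
        t = np.arange(0, 1200.1, 0.5)
        pts = np.column_stack([20 * np.cos(t / 40), 20 * np.sin(t / 40)])
        traj = _traj(t, pts, trial_type="open_field")
        bins = binned_speed(traj)
        assert len(bins) == 4
        assert max(bins) - min(bins) < 1e-9

    def test_bins_average_back_to_overall_mean(self):
        # non-uniform speed path (includes near-stationary stretches)
        t = np.arange(0, 1200.1, 0.5)
        pts = np.column_stack([
            50 * np.sin(0.01 * t + 2 * np.sin(0.003 * t)),
            30 * np.cos(0.007 * t),
        ])
        traj = _traj(t, pts, trial_type="open_field")
        assert np.mean(binned_speed(traj)) == pytest.approx(
            mean_speed(traj), rel=1e-9)

    def test_partial_final_bin_rejected(self):
        t = np.arange(0, 1000, 0.5)
        pts = np.column_stack([np.linspace(0, 10, len(t)), np.zeros(len(t))])
        traj = _traj(t, pts, trial_type="open_field")
        with pytest.raises(ValueError, match="whole"):
            binned_speed(traj)


class TestLatency:
    def test_direct_swim_latency_is_distance_over_speed(self):
        traj = _sim(StrategyLabel.DSw, seed=1, noise=0.0)
        direct = math.dist(traj.start(), traj.platform_point()) - 12.0
        lat, censored = latency(traj)
        assert not censored
        assert lat == pytest.approx(direct / 22.0, rel=1e-9)

    def test_thigmotaxis_is_censored_at_cap(self):
        traj = _sim(StrategyLabel.T, seed=2)
        lat, censored = latency(traj)
        assert censored and lat == 60.0

    def test_focal_search_matches_dense_first_crossing(self):
        traj = _sim(StrategyLabel.FS, seed=3)
        lat, censored = latency(traj)
        oracle = oracles.first_crossing_dense(
            traj.times, traj.points, traj.platform_point(), 12.0, factor=400)
        assert not censored
        assert lat == pytest.approx(oracle, abs=traj.times[1] / 400 * 2 + 1e-9)


class TestCorridorPercent:
    def test_straight_swim_is_100(self):
        traj = _sim(StrategyLabel.DSw, seed=1, noise=0.0)
        assert corridor_percent_path(traj) == pytest.approx(100.0, abs=1e-6)

    def test_far_half_path_is_zero(self):
        # swim confined to the quadrant opposite the start->platform band
        t = np.arange(0, 10.1, 0.1)
        pts = np.column_stack([-50 + 5 * np.cos(t), 50 + 5 * np.sin(t)])
        traj = _traj(t, pts)
        assert corridor_percent_path(
            traj, start=(0.0, 73.0), platform_center=POOL.platform_center
        ) == 0.0

    def test_wall_orbit_matches_shapely_oracle(self):
        traj = _sim(StrategyLabel.T, seed=5)
        ours = corridor_percent_path(traj)
        ref = oracles.corridor_percent_shapely(
            traj.points, traj.start(), traj.platform_point())
        assert 0.0 < ours < 15.0
        assert ours == pytest.approx(ref, abs=0.1)

    def test_in_and_out_shares_sum_to_100(self):
        traj = _sim(StrategyLabel.S, seed=8)
        inside = corridor_percent_path(traj)
        # recompute "outside" by flipping the clip: total minus inside
        assert 0.0 <= inside <= 100.0
        ref = oracles.corridor_percent_shapely(
            traj.points, traj.start(), traj.platform_point())
        assert inside == pytest.approx(ref, abs=0.1)

    def test_time_weighting_option(self):
        traj = _sim(StrategyLabel.DSe, seed=9)
        # constant-speed simulation: path- and time-weighted shares agree
        assert corridor_percent_path(traj, weight="time") == pytest.approx(
            corridor_percent_path(traj, weight="path"), abs=0.5)


class TestEfficiencyRatio:
    def test_straight_path_scores_one(self):
        traj = _sim(StrategyLabel.DSw, seed=1, noise=0.0)
        assert path_efficiency_ratio(traj) == pytest.approx(1.0, abs=1e-9)

    def test_doubled_path_scores_two(self):
        start = (0.0, 73.0)
        plat = POOL.platform_center
        direct = math.dist(start, plat) - 12.0
        # out-and-back detour of exactly one direct length, then straight
        u = (np.asarray(plat) - np.asarray(start))
        u /= np.linalg.norm(u)
        detour = np.asarray(start) + u * direct / 2.0
        pts = [start, tuple(detour), start, tuple(np.asarray(start) + u * direct)]
        traj = _traj([0, 5, 10, 20], pts, platform_quadrant=4)
        assert path_efficiency_ratio(traj) == pytest.approx(2.0, rel=1e-9)

    def test_random_swim_matches_oracle(self):
        traj = _sim(StrategyLabel.RS, seed=11)
        direct = math.dist(traj.start(), traj.platform_point()) - 12.0
        ref = oracles.polyline_length_m(traj.points) * 100.0 / direct
        assert path_efficiency_ratio(traj) == pytest.approx(ref, rel=1e-9)

    def test_rotation_invariance(self):
        traj = _sim(StrategyLabel.RS, seed=13)
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        plat = tuple(rot @ np.asarray(traj.platform_point()))
        rotated = Trajectory(
            times=traj.times, points=traj.points @ rot.T,
            arena=ArenaGeometry(kind="pool", platform_center=plat),
            trial_type="swim",
        )
        assert path_efficiency_ratio(rotated) == pytest.approx(
            path_efficiency_ratio(traj), rel=1e-9)


class TestOccupancyAndZones:
    def test_confined_probe_path(self):
        t = np.arange(0, 30.1, 0.1)
        pts = np.column_stack([40 + 5 * np.cos(t), -40 + 5 * np.sin(t)])
        traj = _traj(t, pts, trial_type="probe")
        occ = quadrant_occupancy(traj)
        assert occ == pytest.approx((0.0, 0.0, 0.0, 100.0))

    def test_centered_orbit_splits_evenly(self):
        t = np.linspace(0, 30, 3001)
        ang = 2 * math.pi * t / 30 + 0.123
        pts = np.column_stack([40 * np.cos(ang), 40 * np.sin(ang)])
        traj = _traj(t, pts, trial_type="probe")
        occ = quadrant_occupancy(traj)
        assert occ == pytest.approx((25.0, 25.0, 25.0, 25.0), abs=0.05)

    def test_scanning_path_matches_dense_oracle(self):
        traj = _sim(StrategyLabel.S, seed=21)
        occ = quadrant_occupancy(traj)
        ref = oracles.quadrant_occupancy_dense(traj.times, traj.points)
        assert np.allclose(occ, ref, atol=0.1)
        assert sum(occ) == pytest.approx(100.0, abs=1e-6)

    def test_central_zone_path_matches_shapely(self):
        traj = _sim(StrategyLabel.S, seed=22)
        ours = central_zone_path(traj, zone_radius_cm=26.0)
        ref = oracles.central_zone_path_shapely(traj.points, 26.0)
        assert ours == pytest.approx(ref, abs=1e-3)


class TestStops:
    def test_constant_walk_has_no_stops(self):
        t = np.arange(0, 60.1, 0.1)
        pts = np.column_stack([np.linspace(-70, 70, len(t)), np.zeros(len(t))])
        traj = _traj(t, pts, trial_type="open_field")
        assert count_stops(traj) == 0

    def test_single_inserted_pause_detected(self):
        t = np.arange(0, 60.1, 0.1)
        x = np.concatenate([
            np.linspace(-50, 0, 300),
            np.zeros(20),  # 2-s pause
            np.linspace(0, 28, len(t) - 320),
        ])
        traj = _traj(t, np.column_stack([x, np.zeros(len(t))]),
                     trial_type="open_field")
        assert count_stops(traj) == 1

    def test_generator_ground_truth_recovered(self):
        for seed in (3, 4, 5):
            traj, truth = simulate_open_field(seed=seed)
            assert count_stops(traj) == truth["n_stops"]


class TestStrides:
    def test_noise_free_strides_exact(self):
        t, pts, _ = simulate_stride_series(8, stride_mean_cm=8.0,
                                           stride_sd_cm=0.0,
                                           tracking_noise_cm=0.0)
        res = extract_strides(t, pts)
        assert res.stride_lengths_cm == pytest.approx([8.0] * 8, abs=0.01)

    def test_noisy_strides_recover_generator_truth(self):
        t, pts, truth = simulate_stride_series(10, stride_sd_cm=0.5, seed=5)
        res = extract_strides(t, pts)
        assert len(res.stride_lengths_cm) == len(truth["strides_cm"])
        assert res.mean_stride_cm == pytest.approx(
            float(np.mean(truth["strides_cm"])), abs=0.2)

    def test_continuous_slide_rejected(self):
        t = np.arange(0, 5, 1 / 60)
        pts = np.column_stack([np.linspace(0, 80, len(t)), np.zeros(len(t))])
        with pytest.raises(ValueError, match="stance"):
            extract_strides(t, pts)

    def test_backwards_series_rejected(self):
        t = np.arange(0, 5, 1 / 60)
        pts = np.column_stack([np.linspace(80, 0, len(t)), np.zeros(len(t))])
        with pytest.raises(ValueError, match="forward"):
            extract_strides(t, pts)


class TestSampleRateRobustness:
    """Metrics on dt-resampled copies of one continuous path agree within 2%."""

    @staticmethod
    def _continuous(dt):
        # analytic spiral-with-drift path, 40 s, inside the pool
        t = np.arange(0, 40 + dt / 2, dt)
        ang = 0.35 * t
        r = 20 + 40 * np.sin(0.08 * t) ** 2
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        return Trajectory(times=t, points=pts, arena=POOL, trial_type="swim")

    @pytest.mark.parametrize("dt", [0.04, 0.1, 0.2])
    def test_metrics_stable_across_dt(self, dt):
        ref = self._continuous(0.01)
        test = self._continuous(dt)
        assert path_length(test) == pytest.approx(path_length(ref), rel=0.02)
        assert corridor_percent_path(test) == pytest.approx(
            corridor_percent_path(ref), rel=0.02, abs=0.5)
        assert np.allclose(quadrant_occupancy(test),
                           quadrant_occupancy(ref), rtol=0.02, atol=0.5)
        assert path_efficiency_ratio(test) == pytest.approx(
            path_efficiency_ratio(ref), rel=0.02)
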