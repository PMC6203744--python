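"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the study conditions the analysis targets: swim
trials in a 154-cm pool with a 12-cm-radius platform capped at 60 s,
20-min open-field sessions in the same-size tub, hindlimb tracking on a
92-cm beam, and Nissl-like blob images with known cell counts.  Each
generator emits its ground truth (strategy label, stop episodes, stride
lengths, cell count) alongside the data so downstream recovery can be
scored, and is byte-reproducible under a fixed seed.

Swim paths are correlated-heading walks: at each 0.1-s step the heading
relaxes toward a strategy-specific desired direction and is perturbed by
von Mises noise.  The eight steering rules produce the classical search
archetypes: thigmotaxis orbits the wall, chaining orbits the annulus at
the platform's radial distance, scanning wanders the central zone, random
swim is an unbiased walk, directed search zig-zags along the start-to-
platform corridor, focal search and perseverance home in on (and then
search around) the current or previous goal, and direct swim heads
straight for the platform.  A trial ends at first platform contact
(center distance <= platform radius) or at the 60-s cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ArenaGeometry,
    StrategyLabel,
    Trajectory,
    platform_center_for_quadrant,
    start_point,
)

__all__ = [
    "SwimSimConfig",
    "CohortSimConfig",
    "simulate_swim",
    "simulate_open_field",
    "simulate_stride_series",
    "simulate_section_image",
    "simulate_cohort",
    "GROUP_PRESETS",
]

TWO_PI = 2.0 * math.pi

#: Swim speeds (m/s) emulating the printed strain means, and open-field
#: locomotion presets (moving speed m/s, pause onset rate 1/s).
GROUP_PRESETS = {
    "b6": {"swim_speed_mps": 0.22, "of_move_speed_mps": 0.13, "of_pause_rate": 1 / 60.0},
    "btbr": {"swim_speed_mps": 0.31, "of_move_speed_mps": 0.24, "of_pause_rate": 1 / 90.0},
}


@dataclass
class SwimSimConfig:
    """Configuration for one simulated swim trial."""

    strategy: StrategyLabel
    speed_mps: float = 0.22
    heading_noise_sd: float = 0.3  # radians / step; 0 = deterministic archetype
    dt_s: float = 0.1
    max_duration_s: float = 60.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry.pool)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.strategy = StrategyLabel(self.strategy)
        if self.speed_mps <= 0:
            raise ValueError("speed must be positive")
        if self.dt_s <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.max_duration_s <= 60.0):
            raise ValueError("swim trials are capped at 60 s")


def _ang_diff(a: float, b: float) -> float:
    """Signed smallest rotation from b to a, in (-pi, pi]."""
    return (a - b + math.pi) % TWO_PI - math.pi


def _orbit_heading(x, y, cx, cy, r_target, direction, gain) -> float:
    """Desired heading that orbits (cx, cy) at radius ``r_target``.

    ``direction`` +1 = counter-clockwise; the radial error feeds back into
    the heading so the walker spirals onto the target ring.
    """
    phi = math.atan2(y - cy, x - cx)
    err = math.hypot(x - cx, y - cy) - r_target
    return phi + direction * (math.pi / 2.0 + math.atan(gain * err))


def simulate_swim(
    cfg: SwimSimConfig,
    start: str = "N",
    platform_quadrant: int = 4,
    previous_platform_quadrant: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Trajectory, StrategyLabel]:
    """Simulate one swim trial; returns the trajectory and its true label."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    strategy = cfg.strategy
    if strategy is StrategyLabel.P and previous_platform_quadrant is None:
        raise ValueError("perseverance requires a previous platform quadrant")

    arena = cfg.arena
    if arena.platform_center is None:
        arena = ArenaGeometry.pool(
            platform_quadrant,
            diameter_cm=cfg.arena.diameter_cm,
            platform_radius_cm=cfg.arena.platform_radius_cm,
        )
    R = arena.radius_cm
    px, py = arena.platform_center
    p_rad = arena.platform_radius_cm
    prev = (
        platform_center_for_quadrant(previous_platform_quadrant, arena)
        if previous_platform_quadrant is not None
        else None
    )
    x, y = start_point(start, arena)
    sx, sy = x, y
    speed = cfg.speed_mps * 100.0  # cm/s
    dt = cfg.dt_s
    step = speed * dt
    sd = cfg.heading_noise_sd
    kappa = 1.0 / (sd * sd) if sd > 0 else None
    n_max = int(round(cfg.max_duration_s / dt))
    wall_r = R - 2.0  # reflection radius

    # --- per-strategy setup -------------------------------------------------
    inward = math.atan2(-y, -x)
    heading = inward
    orbit_dir = 1.0 if rng.random() < 0.5 else -1.0
    state: dict = {}
    if strategy is StrategyLabel.DSe:
        state["zig_phase"] = rng.uniform(0.0, TWO_PI)
    elif strategy in (StrategyLabel.FS, StrategyLabel.P):
        cx, cy = (px, py) if strategy is StrategyLabel.FS else prev
        ang = rng.uniform(0.0, TWO_PI)
        rr = 8.0 * math.sqrt(rng.random())
        state["anchor"] = (cx + rr * math.cos(ang), cy + rr * math.sin(ang))
        state["goal"] = (cx, cy)
        state["search_t0"] = None
        state["floor"] = 13.0 if strategy is StrategyLabel.FS else 14.0
        # perseverance swims back through the middle before heading to the
        # old goal, so the return leg cannot skewer the current platform
        state["via_center"] = strategy is StrategyLabel.P
    elif strategy is StrategyLabel.RS:
        # launch obliquely so the opening chord does not skewer the platform
        heading = inward + math.radians(rng.uniform(44.0, 55.0)) * orbit_dir
    elif strategy is StrategyLabel.C:
        # orbit the long way round toward the platform so the chaining ring
        # is actually travelled before the platform interrupts it
        phi_s = math.atan2(y, x)
        phi_p = math.atan2(py, px)
        ccw_arc = (phi_p - phi_s) % TWO_PI
        orbit_dir = 1.0 if ccw_arc >= math.pi else -1.0

    times = [0.0]
    xs = [x]
    ys = [y]
    t = 0.0
    for _ in range(n_max):
        # --- desired heading ------------------------------------------------
        if strategy is StrategyLabel.DSw:
            desired = math.atan2(py - y, px - x)
        elif strategy is StrategyLabel.DSe:
            zig = 1.5 * math.sin(TWO_PI * t / 1.2 + state["zig_phase"])
            desired = math.atan2(py - y, px - x) + zig
        elif strategy in (StrategyLabel.FS, StrategyLabel.P):
            gx, gy = state["goal"]
            if state["search_t0"] is None:
                if state.get("via_center") and math.hypot(x, y) > 12.0:
                    desired = math.atan2(-y, -x)
                else:
                    state["via_center"] = False
                    ax, ay = state["anchor"]
                    desired = math.atan2(ay - y, ax - x)
                if math.hypot(gx - x, gy - y) <= 24.0:
                    state["search_t0"] = t
            else:
                r_t = max(state["floor"], 19.0 - 0.35 * (t - state["search_t0"]))
                desired = _orbit_heading(x, y, gx, gy, r_t, orbit_dir, 0.15)
        elif strategy is StrategyLabel.T:
            desired = _orbit_heading(x, y, 0.0, 0.0, R - 5.0, orbit_dir, 0.3)
        elif strategy is StrategyLabel.C:
            desired = _orbit_heading(x, y, 0.0, 0.0, arena.diameter_cm / 4.0,
                                     orbit_dir, 0.12)
        elif strategy is StrategyLabel.S:
            r = math.hypot(x, y)
            desired = math.atan2(-y, -x) if r > 30.0 else heading
        else:  # RS: unbiased correlated walk
            desired = heading

        heading = heading + _ang_diff(desired, heading)
        if kappa is not None:
            heading += rng.vonmises(0.0, kappa)

        nx = x + step * math.cos(heading)
        ny = y + step * math.sin(heading)
        r_n = math.hypot(nx, ny)
        if r_n > wall_r:
            # reflect the heading off the wall tangent and clamp inside
            nhat = (nx / r_n, ny / r_n)
            dx, dy = math.cos(heading), math.sin(heading)
            dot = dx * nhat[0] + dy * nhat[1]
            dx, dy = dx - 2 * dot * nhat[0], dy - 2 * dot * nhat[1]
            heading = math.atan2(dy, dx)
            nx, ny = nhat[0] * wall_r, nhat[1] * wall_r
        prev_x, prev_y = x, y
        x, y = nx, ny
        if math.hypot(x - px, y - py) <= p_rad:
            # clip the final sample to the exact platform-contact point so
            # path length and escape latency are free of step overshoot
            vx, vy = x - prev_x, y - prev_y
            ox, oy = prev_x - px, prev_y - py
            a = vx * vx + vy * vy
            b = 2.0 * (ox * vx + oy * vy)
            c = ox * ox + oy * oy - p_rad * p_rad
            disc = max(b * b - 4 * a * c, 0.0)
            s = (-b - math.sqrt(disc)) / (2 * a) if a > 0 else 0.0
            s = min(max(s, 1e-9), 1.0)
            x, y = prev_x + s * vx, prev_y + s * vy
            t += s * dt
            times.append(t)
            xs.append(x)
            ys.append(y)
            break
        t += dt
        times.append(t)
        xs.append(x)
        ys.append(y)

    traj = Trajectory(
        times=np.asarray(times),
        points=np.column_stack([xs, ys]),
        arena=arena,
        trial_type="swim",
        start_position=start,
        platform_quadrant=platform_quadrant,
        previous_platform_quadrant=previous_platform_quadrant,
    )
    return traj, strategy


# ---------------------------------------------------------------------------
# open field


def simulate_open_field(
    duration_s: float = 1200.0,
    move_speed_mps: float = 0.13,
    pause_rate_per_s: float = 1 / 60.0,
    pause_dwell_s: tuple[float, float] = (2.0, 4.0),
    heading_noise_sd: float = 0.4,
    dt_s: float = 0.1,
    arena: Optional[ArenaGeometry] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Trajectory, dict]:
    """Simulate a 20-min open-field session.

    The walker alternates between a bounded correlated walk at
    ``move_speed_mps`` and explicit pause episodes (onset is a Poisson
    process with rate ``pause_rate_per_s``; dwell is uniform in
    ``pause_dwell_s``), so the number of stops is known exactly.  Returns
    the trajectory and a ground-truth dict with the pause episodes.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if arena is None:
        arena = ArenaGeometry.open_field()
    R = arena.radius_cm
    wall_r = R - 2.0
    # released in the central zone
    ang = rng.uniform(0, TWO_PI)
    rr = 10.0 * math.sqrt(rng.random())
    x, y = rr * math.cos(ang), rr * math.sin(ang)
    heading = rng.uniform(0, TWO_PI)
    speed = move_speed_mps * 100.0
    step = speed * dt_s
    kappa = 1.0 / (heading_noise_sd ** 2) if heading_noise_sd > 0 else None
    n = int(round(duration_s / dt_s))

    times = [0.0]
    xs = [x]
    ys = [y]
    pause_until = -1.0
    last_pause_end = -math.inf
    episodes: list[tuple[float, float]] = []
    t = 0.0
    for _ in range(n):
        if t < pause_until:
            # tracking jitter while stationary
            x += rng.normal(0.0, 0.05)
            y += rng.normal(0.0, 0.05)
        else:
            # stops are distinct episodes: a short refractory walk separates
            # them, and none starts so late that it would be truncated
            can_pause = (
                pause_rate_per_s > 0
                and t - last_pause_end >= 3.0
                and t < duration_s - (pause_dwell_s[1] + 1.0)
            )
            if can_pause and rng.random() < pause_rate_per_s * dt_s:
                dwell = rng.uniform(*pause_dwell_s)
                pause_until = t + dwell
                last_pause_end = pause_until
                episodes.append((t, dwell))
                x += rng.normal(0.0, 0.05)
                y += rng.normal(0.0, 0.05)
            else:
                if kappa is not None:
                    heading += rng.vonmises(0.0, kappa)
                nx = x + step * math.cos(heading)
                ny = y + step * math.sin(heading)
                r_n = math.hypot(nx, ny)
                if r_n > wall_r:
                    nhat = (nx / r_n, ny / r_n)
                    dx, dy = math.cos(heading), math.sin(heading)
                    dot = dx * nhat[0] + dy * nhat[1]
                    dx, dy = dx - 2 * dot * nhat[0], dy - 2 * dot * nhat[1]
                    heading = math.atan2(dy, dx)
                    nx, ny = nhat[0] * wall_r, nhat[1] * wall_r
                x, y = nx, ny
        t += dt_s
        times.append(t)
        xs.append(x)
        ys.append(y)

    traj = Trajectory(
        times=np.asarray(times),
        points=np.column_stack([xs, ys]),
        arena=arena,
        trial_type="open_field",
    )
    truth = {
        "n_stops": sum(1 for _, d in episodes if d >= 1.0),
        "episodes": episodes,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# balance beam


def simulate_stride_series(
    n_strides: int,
    stride_mean_cm: float = 8.0,
    stride_sd_cm: float = 0.5,
    stance_s: float = 0.18,
    swing_s: float = 0.12,
    dt_s: float = 1.0 / 60.0,
    tracking_noise_cm: float = 0.03,
    beam_length_cm: float = 92.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate a tracked hindlimb point series on the balance beam.

    The limb alternates zero-velocity stance plateaus with smooth forward
    swings; stride lengths are drawn once and returned as ground truth.
    Strides that would carry the limb past the end of the beam are not
    taken, so the realized stride count may be lower than requested.
    Returns ``(times, points, truth)`` where points is an (n, 2) array
    (beam axis, vertical jitter).
    """
    if n_strides < 1:
        raise ValueError("need at least one stride")
    if rng is None:
        rng = np.random.default_rng(seed)
    strides = []
    pos = 2.0
    landings = [pos]
    for _ in range(n_strides):
        s = max(float(rng.normal(stride_mean_cm, stride_sd_cm)), 0.5) \
            if stride_sd_cm > 0 else stride_mean_cm
        if pos + s > beam_length_cm - 2.0:
            break
        pos += s
        strides.append(s)
        landings.append(pos)
    if not strides:
        raise ValueError("beam too short for a single stride")

    xs: list[float] = []
    for k, land in enumerate(landings):
        xs.extend([land] * int(round(stance_s / dt_s)))
        if k < len(landings) - 1:
            n_swing = max(int(round(swing_s / dt_s)), 2)
            frac = np.linspace(0, 1, n_swing + 1)[1:-1]
            ease = 3 * frac ** 2 - 2 * frac ** 3  # smooth takeoff/landing
            xs.extend(land + ease * (landings[k + 1] - land))
    xs_arr = np.asarray(xs)
    if tracking_noise_cm > 0:
        xs_arr = xs_arr + rng.normal(0.0, tracking_noise_cm, size=len(xs_arr))
    times = np.arange(len(xs_arr)) * dt_s
    points = np.column_stack([xs_arr, rng.normal(0.0, 0.02, size=len(xs_arr))])
    truth = {"strides_cm": strides, "landings_cm": landings}
    return times, points, truth


# ---------------------------------------------------------------------------
# section images


def simulate_section_image(
    n_cells: int,
    n_touching_pairs: int = 0,
    radius_px: tuple[int, int] = (5, 9),
    intensity: tuple[int, int] = (105, 150),
    background: int = 230,
    shape: tuple[int, int] = (512, 512),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict]:
    """Synthetic Nissl-like section: dark disks on a light background.

    Disk intensities fall inside ``intensity`` (within the standard 90-180
    detection band); ``n_touching_pairs`` adds pairs of slightly
    overlapping disks to exercise watershed separation.  Returns the
    uint8 image and a ground-truth dict (total count, centers, pairs).
    """
    if n_cells < 0 or n_touching_pairs < 0:
        raise ValueError("counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background, dtype=np.uint8)
    centers: list[tuple[float, float, float]] = []  # (row, col, r)
    pairs: list[tuple[int, int]] = []

    def _free(r0, c0, rad) -> bool:
        margin = 4.0
        if not (rad + 2 <= r0 <= h - rad - 2 and rad + 2 <= c0 <= w - rad - 2):
            return False
        return all(
            math.hypot(r0 - rr, c0 - cc) >= rad + pr + margin
            for rr, cc, pr in centers
        )

    def _place_single() -> tuple[float, float, float]:
        for _ in range(10_000):
            rad = rng.uniform(*radius_px)
            r0 = rng.uniform(0, h)
            c0 = rng.uniform(0, w)
            if _free(r0, c0, rad):
                return r0, c0, rad
        raise RuntimeError("could not place disk; image too crowded")

    for _ in range(n_cells):
        centers.append(_place_single())
    for _ in range(n_touching_pairs):
        for _ in range(10_000):
            r1 = rng.uniform(*radius_px)
            r2 = rng.uniform(*radius_px)
            r0 = rng.uniform(0, h)
            c0 = rng.uniform(0, w)
            ang = rng.uniform(0, TWO_PI)
            d = r1 + r2 - 1.5  # slight overlap: one merged blob
            r0b = r0 + d * math.sin(ang)
            c0b = c0 + d * math.cos(ang)
            if _free(r0, c0, r1 + d) and _free(r0b, c0b, r2 + d):
                i = len(centers)
                centers.append((r0, c0, r1))
                centers.append((r0b, c0b, r2))
                pairs.append((i, i + 1))
                break
        else:
            raise RuntimeError("could not place touching pair")

    rows, cols = np.ogrid[:h, :w]
    for r0, c0, rad in centers:
        val = int(rng.integers(intensity[0], intensity[1] + 1))
        mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad ** 2
        img[mask] = val

    truth = {
        "count": len(centers),
        "centers": [(r, c) for r, c, _ in centers],
        "pairs": pairs,
    }
    return img, truth


# ---------------------------------------------------------------------------
# cohorts

#: Per-category strategy splits used when expanding a spatial-weight
#: schedule into a full 8-class mixture.
_SPATIAL_SPLIT = {
    StrategyLabel.DSe: 0.5, StrategyLabel.FS: 0.2,
    StrategyLabel.DSw: 0.2, StrategyLabel.P: 0.1,
}
_NON_SPATIAL_SPLIT = {
    StrategyLabel.RS: 0.35, StrategyLabel.S: 0.25,
    StrategyLabel.C: 0.25, StrategyLabel.T: 0.15,
}

#: Spatial-strategy weight per reversal-training day.  The control-like
#: schedule climbs from 44% to 87% of trials; the model-strain-like
#: schedule stays nearly flat (31% -> 36%), mirroring the divergence the
#: strategy analysis is designed to expose.
SPATIAL_SCHEDULES = {
    "b6": [0.44, 0.55, 0.66, 0.77, 0.87],
    "btbr": [0.31, 0.32, 0.33, 0.34, 0.36],
}


@dataclass
class CohortSimConfig:
    """A two-group reversal-training cohort."""

    n_per_group: int = 8
    days: int = 5
    trials_per_day: int = 4
    groups: tuple[str, str] = ("b6", "btbr")
    platform_quadrant: int = 4
    previous_platform_quadrant: int = 3
    heading_noise_sd: float = 0.3
    dt_s: float = 0.1
    seed: Optional[int] = None
    #: optional fixed 8-class mixture applied to every group and day
    #: (overrides the per-day spatial schedules)
    mixture_override: Optional[dict] = None

    def mixture(self, group: str, day: int) -> dict[StrategyLabel, float]:
        if self.mixture_override is not None:
            mix = {StrategyLabel(k): float(v)
                   for k, v in self.mixture_override.items()}
            total = sum(mix.values())
            if total <= 0 or any(v < 0 for v in mix.values()):
                raise ValueError("mixture weights must be non-negative, sum > 0")
            return {k: v / total for k, v in mix.items()}
        sched = SPATIAL_SCHEDULES[group]
        w_sp = sched[min(day - 1, len(sched) - 1)]
        mix = {lab: w_sp * f for lab, f in _SPATIAL_SPLIT.items()}
        mix.update(
            {lab: (1 - w_sp) * f for lab, f in _NON_SPATIAL_SPLIT.items()}
        )
        total = sum(mix.values())
        return {lab: v / total for lab, v in mix.items()}


def simulate_cohort(cfg: CohortSimConfig):
    """Simulate every trial of a cohort.

    Returns ``(manifest, trajectories)``: a tidy DataFrame with one row per
    trial (subject, group, day, trial, start position, true strategy,
    trial_id) and a dict mapping trial_id to its Trajectory.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    trajs: dict[str, Trajectory] = {}
    starts = np.array(["N", "W", "S", "E"])
    for group in cfg.groups:
        speed = GROUP_PRESETS[group]["swim_speed_mps"]
        for mouse in range(cfg.n_per_group):
            subject = f"{group}_{mouse:02d}"
            for day in range(1, cfg.days + 1):
                mix = cfg.mixture(group, day)
                labels = list(mix)
                probs = np.array([mix[l] for l in labels])
                order = rng.permutation(4)
                for trial in range(1, cfg.trials_per_day + 1):
                    strat = labels[rng.choice(len(labels), p=probs)]
                    start = str(starts[order[(trial - 1) % 4]])
                    swim_cfg = SwimSimConfig(
                        strategy=strat,
                        speed_mps=speed,
                        heading_noise_sd=cfg.heading_noise_sd,
                        dt_s=cfg.dt_s,
                    )
                    traj, label = simulate_swim(
                        swim_cfg,
                        start=start,
                        platform_quadrant=cfg.platform_quadrant,
                        previous_platform_quadrant=cfg.previous_platform_quadrant,
                        rng=rng,
                    )
                    traj.subject = subject
                    traj.group = group
                    traj.day = day
                    traj.trial = trial
                    trial_id = f"{subject}_d{day}_t{trial}"
                    rows.append(
                        {
                            "trial_id": trial_id,
                            "subject": subject,
                            "group": group,
                            "day": day,
                            "trial": trial,
                            "trial_type": "swim",
                            "start_position": start,
                            "platform_quadrant": cfg.platform_quadrant,
                            "previous_platform_quadrant": cfg.previous_platform_quadrant,
                            "true_strategy": label.value,
                        }
                    )
                    trajs[trial_id] = traj
    return pd.DataFrame(rows), trajs
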