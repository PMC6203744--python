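"""Per-trial trajectory measures.

Water-maze measures: escape latency, swim path length and speed, the
corridor error index (percentage of the swim path inside a 20-cm-wide band
from the start point to the platform), the path efficiency ratio
(actual path length / straight-line start-to-platform distance), and
probe-trial quadrant occupancy.  Open-field measures: overall and
central-zone path length, overall and 5-min-binned speed, and stop counts.
Balance-beam measure: stride lengths extracted from a tracked hindlimb
point series.

All polyline quantities treat the track as piecewise linear between
samples, and region-restricted lengths/times are computed by exact
parametric clipping of each segment against the region, so results are
stable under resampling of the same continuous path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Trajectory, TrialMetrics

__all__ = [
    "path_length",
    "mean_speed",
    "binned_speed",
    "latency",
    "corridor_percent_path",
    "path_efficiency_ratio",
    "quadrant_occupancy",
    "central_zone_path",
    "count_stops",
    "extract_strides",
    "BeamTrialResult",
    "swim_trial_metrics",
    "open_field_metrics",
]

CM_PER_M = 100.0


def _segments(traj: Trajectory):
    p = traj.points
    return p[:-1], p[1:], np.diff(traj.times)


def path_length(traj: Trajectory) -> float:
    """Total polyline length in meters."""
    d = np.diff(traj.points, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum()) / CM_PER_M


def mean_speed(traj: Trajectory) -> float:
    """Overall speed: path length / duration (m/s)."""
    return path_length(traj) / traj.duration_s


def binned_speed(traj: Trajectory, bin_s: float = 300.0) -> list[float]:
    """Mean speed (m/s) in consecutive windows of ``bin_s`` seconds.

    The trajectory duration must tile into whole bins (the 20-min
    open-field protocol gives exactly four 5-min bins); a leftover partial
    bin is rejected rather than silently averaged over less time.
    """
    dur = traj.duration_s
    n_bins = round(dur / bin_s)
    if n_bins < 1 or abs(dur - n_bins * bin_s) > 1e-6 * max(dur, bin_s):
        raise ValueError(
            f"duration {dur:.3f}s does not divide into whole {bin_s:.0f}-s bins"
        )
    t0 = traj.times[0]
    p0, p1, dt = _segments(traj)
    seg_len = np.hypot(*(p1 - p0).T)
    ta = traj.times[:-1] - t0
    tb = traj.times[1:] - t0
    speeds = []
    for k in range(n_bins):
        lo, hi = k * bin_s, (k + 1) * bin_s
        # overlap fraction of each segment's time interval with the bin
        ov = np.clip(np.minimum(tb, hi) - np.maximum(ta, lo), 0.0, None)
        frac = np.divide(ov, dt, out=np.zeros_like(ov), where=dt > 0)
        speeds.append(float((seg_len * frac).sum()) / CM_PER_M / bin_s)
    return speeds


def latency(
    traj: Trajectory,
    platform_center: Optional[tuple[float, float]] = None,
    platform_radius_cm: Optional[float] = None,
    cap_s: float = 60.0,
) -> tuple[float, bool]:
    """Time (s) of first platform contact, or ``(cap_s, True)`` if censored.

    Contact means the tracked point comes within the platform radius of the
    platform center; the crossing instant is interpolated linearly inside
    the straddling sample interval.
    """
    if platform_center is None:
        platform_center = traj.platform_point()
    if platform_radius_cm is None:
        platform_radius_cm = traj.arena.platform_radius_cm
    c = np.asarray(platform_center, float)
    d = np.hypot(*(traj.points - c).T)
    hit = np.nonzero(d <= platform_radius_cm)[0]
    if len(hit) == 0:
        return cap_s, True
    i = int(hit[0])
    if i == 0:
        return float(traj.times[0] - traj.times[0]), False
    # solve |p0 + s*(p1-p0) - c| = r for s in [0, 1]
    p0 = traj.points[i - 1] - c
    v = traj.points[i] - traj.points[i - 1]
    a = float(v @ v)
    b = 2.0 * float(p0 @ v)
    cc = float(p0 @ p0) - platform_radius_cm ** 2
    if a == 0.0:
        s = 0.0
    else:
        disc = max(b * b - 4 * a * cc, 0.0)
        s = (-b - math.sqrt(disc)) / (2 * a)
        s = min(max(s, 0.0), 1.0)
    t_hit = traj.times[i - 1] + s * (traj.times[i] - traj.times[i - 1])
    return float(t_hit - traj.times[0]), False


# ---------------------------------------------------------------------------
# region-clipped lengths and times


def _corridor_frame(start, platform_center):
    s = np.asarray(start, float)
    p = np.asarray(platform_center, float)
    axis = p - s
    length = float(np.hypot(*axis))
    if length == 0.0:
        raise ValueError("degenerate corridor: start equals platform center")
    u = axis / length
    n = np.array([-u[1], u[0]])
    return s, u, n, length


def _clip_fraction_rect(p0, p1, s, u, n, length, half_w):
    """Fraction of segment p0->p1 inside the corridor rectangle (exact)."""
    a0 = (p0 - s) @ u
    a1 = (p1 - s) @ u
    b0 = (p0 - s) @ n
    b1 = (p1 - s) @ n
    lo, hi = 0.0, 1.0
    for c0, c1, cmin, cmax in ((a0, a1, 0.0, length), (b0, b1, -half_w, half_w)):
        dc = c1 - c0
        if dc == 0.0:
            if not (cmin <= c0 <= cmax):
                return 0.0
            continue
        t_at_min = (cmin - c0) / dc
        t_at_max = (cmax - c0) / dc
        t_lo, t_hi = min(t_at_min, t_at_max), max(t_at_min, t_at_max)
        lo, hi = max(lo, t_lo), min(hi, t_hi)
        if lo >= hi:
            return 0.0
    return hi - lo


def corridor_percent_path(
    traj: Trajectory,
    start: Optional[tuple[float, float]] = None,
    platform_center: Optional[tuple[float, float]] = None,
    width_cm: float = 20.0,
    weight: str = "path",
) -> float:
    """Corridor error index: percentage of the swim inside the 20-cm band
    from the start point to the platform (higher = more accurate swim).

    ``weight="path"`` (default) weights by polyline length;
    ``weight="time"`` weights by time, assuming constant speed within each
    sample interval.
    """
    if start is None:
        start = traj.start()
    if platform_center is None:
        platform_center = traj.platform_point()
    s, u, n, length = _corridor_frame(start, platform_center)
    half_w = width_cm / 2.0
    p0s, p1s, dts = _segments(traj)
    seg_len = np.hypot(*(p1s - p0s).T)
    total_len = float(seg_len.sum())
    fracs = np.array(
        [_clip_fraction_rect(p0, p1, s, u, n, length, half_w)
         for p0, p1 in zip(p0s, p1s)]
    )
    if weight == "path":
        if total_len == 0.0:
            raise ValueError("zero-length path")
        return 100.0 * float((fracs * seg_len).sum()) / total_len
    elif weight == "time":
        return 100.0 * float((fracs * dts).sum()) / float(dts.sum())
    raise ValueError(f"weight must be 'path' or 'time', got {weight!r}")


def path_efficiency_ratio(
    traj: Trajectory,
    start: Optional[tuple[float, float]] = None,
    platform_center: Optional[tuple[float, float]] = None,
    platform_radius_cm: Optional[float] = None,
) -> float:
    """Actual path length / direct start-to-platform distance.

    Because a swim ends the moment the animal touches the platform, the
    direct distance is measured to the platform's near edge (center
    distance minus the platform radius); a perfectly straight escape then
    scores exactly 1.0, and larger values mean longer, less efficient
    paths.  Pass ``platform_radius_cm=0`` to measure to the center instead.
    """
    if start is None:
        start = traj.start()
    if platform_center is None:
        platform_center = traj.platform_point()
    if platform_radius_cm is None:
        platform_radius_cm = traj.arena.platform_radius_cm
    direct = math.dist(start, platform_center) - platform_radius_cm
    if direct <= 0.0:
        raise ValueError("start lies on (or inside) the platform")
    return path_length(traj) * CM_PER_M / direct


def _split_times_linear(c0: float, c1: float) -> list[float]:
    """Parameter values in (0,1) where the linear value c0->c1 crosses 0."""
    if (c0 > 0 and c1 < 0) or (c0 < 0 and c1 > 0):
        return [c0 / (c0 - c1)]
    return []


def quadrant_occupancy(traj: Trajectory) -> tuple[float, float, float, float]:
    """Time-weighted percentage spent in each quadrant 1..4 (sums to 100).

    Each sample interval is split exactly where the interpolated path
    crosses a quadrant axis, and each piece is assigned by its midpoint.
    """
    arena = traj.arena
    th = math.radians(arena.quadrant_axes_deg)
    rot = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    rel = (traj.points - np.asarray(arena.center)) @ rot.T
    occ = np.zeros(4)
    for i in range(len(rel) - 1):
        p0, p1 = rel[i], rel[i + 1]
        dt = traj.times[i + 1] - traj.times[i]
        cuts = sorted(
            set([0.0, 1.0])
            | set(_split_times_linear(p0[0], p1[0]))
            | set(_split_times_linear(p0[1], p1[1]))
        )
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = p0 + 0.5 * (a + b) * 0 + ((a + b) / 2.0) * (p1 - p0)
            ang = math.atan2(mid[1], mid[0]) % (2 * math.pi)
            q = int(ang // (math.pi / 2))
            occ[q] += (b - a) * dt
    occ = 100.0 * occ / occ.sum()
    return tuple(float(v) for v in occ)


def central_zone_path(traj: Trajectory, zone_radius_cm: Optional[float] = None) -> float:
    """Polyline length (m) inside the central zone disk.

    Defaults to the arena's central zone (52-cm diameter for the open
    field); each segment is clipped exactly against the circle.
    """
    arena = traj.arena
    if zone_radius_cm is None:
        zone_radius_cm = arena.central_zone_radius_cm
    c = np.asarray(arena.center, float)
    total = 0.0
    for i in range(len(traj.points) - 1):
        p0 = traj.points[i] - c
        p1 = traj.points[i + 1] - c
        v = p1 - p0
        a = float(v @ v)
        seg_len = math.sqrt(a)
        if a == 0.0:
            continue
        b = 2.0 * float(p0 @ v)
        cc = float(p0 @ p0) - zone_radius_cm ** 2
        disc = b * b - 4 * a * cc
        if disc <= 0:
            inside = cc <= 0  # fully inside or fully outside
            total += seg_len if inside else 0.0
            continue
        sq = math.sqrt(disc)
        t0 = (-b - sq) / (2 * a)
        t1 = (-b + sq) / (2 * a)
        lo, hi = max(t0, 0.0), min(t1, 1.0)
        if hi > lo:
            total += (hi - lo) * seg_len
    return total / CM_PER_M


# ---------------------------------------------------------------------------
# open-field stops


def count_stops(
    traj: Trajectory,
    speed_thresh_cm_s: float = 2.0,
    min_dwell_s: float = 1.0,
    smooth_s: float = 0.5,
) -> int:
    """Number of stops: maximal intervals where the smoothed instantaneous
    speed stays below ``speed_thresh_cm_s`` for at least ``min_dwell_s``.

    Speed is the per-interval displacement rate, smoothed with a centered
    moving average of width ``smooth_s``.
    """
    p0, p1, dt = _segments(traj)
    speed = np.hypot(*(p1 - p0).T) / dt  # cm/s at interval midpoints
    tmid = (traj.times[:-1] + traj.times[1:]) / 2.0
    if smooth_s > 0 and len(speed) > 1:
        half = smooth_s / 2.0
        sm = np.empty_like(speed)
        j0 = np.searchsorted(tmid, tmid - half, side="left")
        j1 = np.searchsorted(tmid, tmid + half, side="right")
        csum = np.concatenate([[0.0], np.cumsum(speed * dt)])
        cdt = np.concatenate([[0.0], np.cumsum(dt)])
        denom = cdt[j1] - cdt[j0]
        sm = np.divide(csum[j1] - csum[j0], denom,
                       out=speed.copy(), where=denom > 0)
    else:
        sm = speed
    below = sm < speed_thresh_cm_s
    n_stops = 0
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            t_start = traj.times[i]
            t_end = traj.times[j]  # end of last below-threshold interval
            if t_end - t_start >= min_dwell_s:
                n_stops += 1
            i = j
        else:
            i += 1
    return n_stops


# ---------------------------------------------------------------------------
# balance beam strides


@dataclass
class BeamTrialResult:
    """Stride lengths and traverse latency for one beam trial."""

    stride_lengths_cm: list[float]
    latency_s: float
    n_slips: Optional[int] = None
    stance_positions_cm: list[float] = field(default_factory=list)

    @property
    def mean_stride_cm(self) -> float:
        return float(np.mean(self.stride_lengths_cm))


def extract_strides(
    times: np.ndarray,
    positions: np.ndarray,
    speed_thresh_cm_s: float = 10.0,
    min_stance_s: float = 0.05,
    n_slips: Optional[int] = None,
) -> BeamTrialResult:
    """Stride lengths from a tracked hindlimb point series on the beam.

    ``positions`` is the hindlimb coordinate along the beam axis (cm), or an
    (n, 2) array whose first column is taken as the beam axis.  Stance
    phases are detected as near-zero-velocity plateaus; each stride is the
    distance between the takeoff position of one stance and the landing
    position of the next.  Latency is the series duration.
    """
    times = np.asarray(times, float)
    positions = np.asarray(positions, float)
    if positions.ndim == 2:
        positions = positions[:, 0]
    if len(times) < 3:
        raise ValueError("hindlimb series too short")
    net = positions[-1] - positions[0]
    if net <= 0:
        raise ValueError("series must progress forward along the beam")
    dt = np.diff(times)
    speed = np.abs(np.diff(positions)) / dt
    below = speed < speed_thresh_cm_s
    stances: list[tuple[int, int]] = []  # sample index ranges [i, j]
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if times[j] - times[i] >= min_stance_s:
                stances.append((i, j))
            i = j
        else:
            i += 1
    if len(stances) < 2:
        raise ValueError(
            f"found {len(stances)} stance phase(s); need at least 2 "
            "(continuous sliding has no detectable strides)"
        )
    stance_pos = [float(np.median(positions[i:j + 1])) for i, j in stances]
    strides = [b - a for a, b in zip(stance_pos[:-1], stance_pos[1:])]
    return BeamTrialResult(
        stride_lengths_cm=strides,
        latency_s=float(times[-1] - times[0]),
        n_slips=n_slips,
        stance_positions_cm=stance_pos,
    )


# ---------------------------------------------------------------------------
# bundled per-trial summaries


def swim_trial_metrics(traj: Trajectory) -> TrialMetrics:
    """All water-maze measures for one swim trial."""
    start = traj.start()
    platform = traj.platform_point()
    lat, censored = latency(traj)
    return TrialMetrics(
        latency_s=lat,
        latency_censored=censored,
        path_length_m=path_length(traj),
        mean_speed_mps=mean_speed(traj),
        corridor_percent=corridor_percent_path(traj, start, platform),
        path_efficiency_ratio=path_efficiency_ratio(traj, start, platform),
    )


def open_field_metrics(traj: Trajectory) -> TrialMetrics:
    """All open-field measures for one 20-min session."""
    return TrialMetrics(
        path_length_m=path_length(traj),
        mean_speed_mps=mean_speed(traj),
        central_zone_path_m=central_zone_path(traj),
        n_stops=count_stops(traj),
        binned_speed_mps=binned_speed(traj),
    )
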