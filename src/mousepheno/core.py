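"""Shared domain model: arenas, trajectories, strategy labels, and geometric predicates.

Conventions used throughout the package:

* the arena frame has its origin at the arena center, units are centimetres
  for positions and seconds for time;
* compass start positions N/W/S/E sit on the pool perimeter at angles
  90/180/270/0 degrees (counter-clockwise from the +x axis);
* quadrants 1..4 are the four 90-degree sectors starting at the
  ``quadrant_axes_deg`` orientation, assigned with a half-open angular
  convention so that every point (including boundaries and the exact
  center) receives exactly one quadrant.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ArenaGeometry",
    "Trajectory",
    "StrategyLabel",
    "StrategyCategory",
    "TrialMetrics",
    "quadrant_of",
    "distance_to_wall",
    "in_corridor",
    "start_point",
    "platform_center_for_quadrant",
    "START_ANGLES_DEG",
    "WALL_TOLERANCE_CM",
]

#: Angular position (degrees CCW from +x) of the four cardinal start positions.
START_ANGLES_DEG = {"N": 90.0, "W": 180.0, "S": 270.0, "E": 0.0}

#: Tracking jitter allowance: points may fall this far outside the wall.
WALL_TOLERANCE_CM = 1.0

#: Animals enter the water facing the wall; the start point sits this far
#: inside the wall so the first tracked sample is inside the pool.
START_INSET_CM = 4.0


class StrategyCategory(str, enum.Enum):
    NON_SPATIAL = "non_spatial"
    SPATIAL = "spatial"


class StrategyLabel(str, enum.Enum):
    """The eight swim search strategies.

    Non-spatial: thigmotaxis (T), random swim (RS), scanning (S),
    chaining (C).  Spatial: directed search (DSe), focal search (FS),
    direct swim (DSw), perseverance (P).
    """

    T = "T"
    RS = "RS"
    S = "S"
    C = "C"
    DSe = "DSe"
    FS = "FS"
    DSw = "DSw"
    P = "P"

    @property
    def category(self) -> StrategyCategory:
        if self in _SPATIAL:
            return StrategyCategory.SPATIAL
        return StrategyCategory.NON_SPATIAL

    @property
    def is_spatial(self) -> bool:
        return self in _SPATIAL


_SPATIAL = frozenset(
    {StrategyLabel.DSe, StrategyLabel.FS, StrategyLabel.DSw, StrategyLabel.P}
)


@dataclass(frozen=True)
class ArenaGeometry:
    """Geometry of a circular pool / open field or of a balance beam.

    The default dimensions are those of the standard apparatus this package
    targets: a 154-cm circular pool (and open-field tub of the same size), a
    12-cm-radius escape platform placed half-way between the pool center and
    the wall, a ~52-cm central zone for the open field, and a 92 x 1 cm beam.
    """

    kind: str = "pool"  # pool | open_field | beam
    diameter_cm: float = 154.0
    center: tuple[float, float] = (0.0, 0.0)
    platform_center: Optional[tuple[float, float]] = None
    platform_radius_cm: float = 12.0
    central_zone_diameter_cm: float = 52.0
    quadrant_axes_deg: float = 0.0
    beam_length_cm: float = 92.0
    beam_width_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("pool", "open_field", "beam"):
            raise ValueError(f"unknown arena kind {self.kind!r}")
        for name in ("diameter_cm", "platform_radius_cm",
                     "central_zone_diameter_cm", "beam_length_cm",
                     "beam_width_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kind == "open_field" and \
                self.central_zone_diameter_cm >= self.diameter_cm:
            raise ValueError("central zone must be smaller than the arena")
        if self.platform_center is not None:
            r = math.dist(self.platform_center, self.center)
            if r + self.platform_radius_cm > self.radius_cm:
                raise ValueError("platform is not fully inside the pool")
            # platform sits half-way between center and wall, i.e. at
            # radial distance diameter/4; allow a small placement slack
            if abs(r - self.diameter_cm / 4.0) > 2.0:
                raise ValueError(
                    "platform center must lie ~half-way between the pool "
                    f"center and the wall (expected r~{self.diameter_cm / 4:.1f} cm, "
                    f"got {r:.1f} cm)"
                )

    @property
    def radius_cm(self) -> float:
        return self.diameter_cm / 2.0

    @property
    def central_zone_radius_cm(self) -> float:
        return self.central_zone_diameter_cm / 2.0

    @classmethod
    def pool(cls, platform_quadrant: Optional[int] = None, **kw) -> "ArenaGeometry":
        """A 154-cm pool, optionally with the platform in quadrant 1..4."""
        arena = cls(kind="pool", **kw)
        if platform_quadrant is not None:
            pc = platform_center_for_quadrant(platform_quadrant, arena)
            arena = replace(arena, platform_center=pc)
        return arena

    @classmethod
    def open_field(cls, **kw) -> "ArenaGeometry":
        return cls(kind="open_field", **kw)

    @classmethod
    def beam(cls, **kw) -> "ArenaGeometry":
        return cls(kind="beam", **kw)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "diameter_cm": self.diameter_cm,
            "center": list(self.center),
            "platform_radius_cm": self.platform_radius_cm,
            "central_zone_diameter_cm": self.central_zone_diameter_cm,
            "quadrant_axes_deg": self.quadrant_axes_deg,
            "beam_length_cm": self.beam_length_cm,
            "beam_width_cm": self.beam_width_cm,
        }
        if self.platform_center is not None:
            d["platform_center"] = list(self.platform_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        d = dict(d)
        if "center" in d:
            d["center"] = tuple(d["center"])
        if d.get("platform_center") is not None:
            d["platform_center"] = tuple(d["platform_center"])
        return cls(**d)


def platform_center_for_quadrant(quadrant: int, arena: ArenaGeometry) -> tuple[float, float]:
    """Platform center on the bisector of ``quadrant``, half-way to the wall."""
    if quadrant not in (1, 2, 3, 4):
        raise ValueError("quadrant must be 1..4")
    ang = math.radians(arena.quadrant_axes_deg + 45.0 + 90.0 * (quadrant - 1))
    r = arena.diameter_cm / 4.0
    cx, cy = arena.center
    return (cx + r * math.cos(ang), cy + r * math.sin(ang))


def start_point(position: str, arena: ArenaGeometry) -> tuple[float, float]:
    """Release point for a cardinal start position, just inside the wall."""
    try:
        ang = math.radians(START_ANGLES_DEG[position])
    except KeyError:
        raise ValueError(f"start position must be one of N/W/S/E, got {position!r}")
    r = arena.radius_cm - START_INSET_CM
    cx, cy = arena.center
    return (cx + r * math.cos(ang), cy + r * math.sin(ang))


# Trial duration caps (s) by protocol.
TRIAL_CAPS_S = {"swim": 60.0, "probe": 30.0, "open_field": 1200.0}


@dataclass
class Trajectory:
    """A time-stamped 2-D path in the arena frame (cm, s) plus trial metadata."""

    times: np.ndarray
    points: np.ndarray
    arena: ArenaGeometry
    trial_type: str = "swim"  # swim | probe | open_field
    start_position: Optional[str] = None
    platform_quadrant: Optional[int] = None
    previous_platform_quadrant: Optional[int] = None
    day: Optional[int] = None
    trial: Optional[int] = None
    subject: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if self.points.shape != (len(self.times), 2):
            raise ValueError("points must have shape (n_samples, 2)")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.trial_type not in TRIAL_CAPS_S:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        cap = TRIAL_CAPS_S[self.trial_type]
        if self.duration_s > cap + 1e-9:
            raise ValueError(
                f"duration {self.duration_s:.2f}s exceeds the "
                f"{cap:.0f}s cap for {self.trial_type} trials"
            )
        if self.arena.kind != "beam":
            r = np.hypot(*(self.points - np.asarray(self.arena.center)).T)
            worst = float(np.max(r)) - self.arena.radius_cm
            if worst > WALL_TOLERANCE_CM:
                raise ValueError(
                    f"point {worst:.2f} cm outside the arena wall "
                    f"(tolerance {WALL_TOLERANCE_CM} cm)"
                )

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def platform_point(self) -> tuple[float, float]:
        """Platform center, from the arena or derived from the quadrant."""
        if self.arena.platform_center is not None:
            return self.arena.platform_center
        if self.platform_quadrant is not None:
            return platform_center_for_quadrant(self.platform_quadrant, self.arena)
        raise ValueError("trajectory has no platform location")

    def start(self) -> tuple[float, float]:
        return (float(self.points[0, 0]), float(self.points[0, 1]))


@dataclass
class TrialMetrics:
    """Per-trial measures; fields not applicable to a protocol stay None."""

    latency_s: Optional[float] = None
    latency_censored: Optional[bool] = None
    path_length_m: Optional[float] = None
    mean_speed_mps: Optional[float] = None
    corridor_percent: Optional[float] = None
    path_efficiency_ratio: Optional[float] = None
    quadrant_occupancy: Optional[tuple[float, float, float, float]] = None
    central_zone_path_m: Optional[float] = None
    n_stops: Optional[int] = None
    binned_speed_mps: Optional[list[float]] = field(default=None)

    def to_dict(self) -> dict:
        d: dict = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            if k == "quadrant_occupancy":
                for i, q in enumerate(v, start=1):
                    d[f"quadrant_{i}_percent"] = q
            elif k == "binned_speed_mps":
                for i, s in enumerate(v, start=1):
                    d[f"speed_bin{i}_mps"] = s
            else:
                d[k] = v
        return d


def quadrant_of(point, arena: ArenaGeometry) -> int:
    """Quadrant index 1..4 of ``point``.

    Quadrant q spans angles ``[axes + 90(q-1), axes + 90q)`` degrees
    (half-open), so boundary points belong to the sector they open;
    the arena center (angle undefined, atan2 -> 0) maps to quadrant 1
    when the axes sit at 0 degrees.
    """
    x = point[0] - arena.center[0]
    y = point[1] - arena.center[1]
    r = math.hypot(x, y)
    if r > arena.radius_cm + WALL_TOLERANCE_CM:
        raise ValueError(
            f"point at radius {r:.2f} cm lies outside the "
            f"{arena.radius_cm:.1f}-cm arena (tolerance {WALL_TOLERANCE_CM} cm)"
        )
    ang = (math.degrees(math.atan2(y, x)) - arena.quadrant_axes_deg) % 360.0
    return int(ang // 90.0) + 1


def distance_to_wall(point, arena: ArenaGeometry, return_oob: bool = False):
    """Distance (cm) from ``point`` to the circular wall, clipped at 0.

    Accepts a single point or an (n, 2) array.  With ``return_oob=True``
    also returns a flag (or boolean mask) marking points outside the wall.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    r = np.hypot(pts[:, 0] - arena.center[0], pts[:, 1] - arena.center[1])
    d = arena.radius_cm - r
    oob = d < 0
    d = np.clip(d, 0.0, None)
    if single:
        d, oob = float(d[0]), bool(oob[0])
    if return_oob:
        return d, oob
    return d


def in_corridor(point, start, platform_center, width_cm: float = 20.0) -> bool:
    """True iff ``point`` lies in the width-``width_cm`` band over the
    start->platform segment (perpendicular distance <= width/2, inclusive,
    and projection between the endpoints)."""
    sx, sy = start
    px, py = platform_center
    dx, dy = px - sx, py - sy
    length = math.hypot(dx, dy)
    if length == 0.0:
        raise ValueError("degenerate corridor: start equals platform center")
    ux, uy = dx / length, dy / length
    rx, ry = point[0] - sx, point[1] - sy
    along = rx * ux + ry * uy
    perp = abs(-rx * uy + ry * ux)
    return (0.0 <= along <= length) and (perp <= width_cm / 2.0)
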