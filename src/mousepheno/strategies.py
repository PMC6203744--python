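"""Rule-based classification of swim search strategies.

A trajectory is reduced to a small feature vector (path efficiency,
corridor adherence, time shares in the wall band, chaining annulus,
inner zone, and goal-proximity disks, plus pool coverage) and passed
through an ordered rule cascade that assigns one of the eight strategy
labels.  Spatial rules are tested before non-spatial ones so that
near-goal behavior dominates ambiguous paths, and perseverance is tested
before the wall/annulus/inner rules so focal search at the old goal is
not absorbed by scanning.

The cascade replaces manual two-rater categorization with a deterministic,
threshold-configurable procedure; the summary layer computes per-day
spatial-strategy percentages and the improvement rate (percentage-point
change between the first and last training day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import StrategyLabel, Trajectory, platform_center_for_quadrant
from .metrics import corridor_percent_path, path_efficiency_ratio

__all__ = [
    "StrategyFeatures",
    "ClassifierThresholds",
    "extract_features",
    "classify",
    "classify_trajectory",
    "spatial_percent",
    "improvement_rate",
    "summarize_cohort",
]


@dataclass
class StrategyFeatures:
    """Per-trial features feeding the strategy cascade (fractions in [0, 1])."""

    efficiency_ratio: float
    corridor_fraction: float
    wall_fraction: float
    annulus_fraction: float
    inner_fraction: float
    target_prox_fraction: float
    prev_prox_fraction: Optional[float]
    coverage: float
    target_quadrant_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable cut-offs of the rule cascade (defaults documented in docs)."""

    dsw_efficiency_max: float = 1.3
    dsw_corridor_min: float = 0.8
    dse_corridor_min: float = 0.7
    fs_prox_min: float = 0.5
    p_prox_min: float = 0.5
    t_wall_min: float = 0.65
    c_annulus_min: float = 0.7
    s_inner_min: float = 0.6
    wall_band_cm: float = 8.0
    annulus_halfwidth_cm: float = 10.0
    prox_radius_cm: float = 30.0
    coverage_grid: int = 10


def _time_weights(times: np.ndarray) -> np.ndarray:
    """Trapezoidal sample weights: each sample owns half its two intervals."""
    dt = np.diff(times)
    w = np.zeros_like(times)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    return w


def extract_features(
    traj: Trajectory,
    previous_platform: Optional[tuple[float, float]] = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> StrategyFeatures:
    """Compute the classifier features for one swim trial.

    Zone occupancies are time-weighted; efficiency, corridor adherence and
    coverage are path-based.  ``previous_platform`` defaults to the
    trajectory's recorded previous platform quadrant, when present.
    """
    arena = traj.arena
    start = traj.start()
    platform = traj.platform_point()
    if previous_platform is None and traj.previous_platform_quadrant is not None:
        previous_platform = platform_center_for_quadrant(
            traj.previous_platform_quadrant, arena
        )

    pts = traj.points - np.asarray(arena.center)
    r = np.hypot(pts[:, 0], pts[:, 1])
    w = _time_weights(traj.times)
    wt = w.sum()
    R = arena.radius_cm
    platform_r = math.dist(platform, arena.center)

    wall_fraction = float(w[(R - r) < thresholds.wall_band_cm].sum() / wt)
    annulus_fraction = float(
        w[np.abs(r - platform_r) <= thresholds.annulus_halfwidth_cm].sum() / wt
    )
    inner_fraction = float(w[r < R / 2.0].sum() / wt)
    d_target = np.hypot(*(traj.points - np.asarray(platform)).T)
    target_prox = float(w[d_target <= thresholds.prox_radius_cm].sum() / wt)
    prev_prox = None
    if previous_platform is not None:
        d_prev = np.hypot(*(traj.points - np.asarray(previous_platform)).T)
        prev_prox = float(w[d_prev <= thresholds.prox_radius_cm].sum() / wt)

    # target-quadrant time share
    th = math.radians(arena.quadrant_axes_deg)
    ang = (np.arctan2(pts[:, 1], pts[:, 0]) - th) % (2 * math.pi)
    quad = (ang // (math.pi / 2)).astype(int) + 1
    tq = traj.platform_quadrant
    if tq is None:
        tq_ang = (math.atan2(platform[1] - arena.center[1],
                             platform[0] - arena.center[0]) - th) % (2 * math.pi)
        tq = int(tq_ang // (math.pi / 2)) + 1
    target_quadrant_fraction = float(w[quad == tq].sum() / wt)

    # coverage: visited share of pool-interior cells on a g x g overlay
    g = thresholds.coverage_grid
    edges = np.linspace(-R, R, g + 1)
    ix = np.clip(np.digitize(pts[:, 0], edges) - 1, 0, g - 1)
    iy = np.clip(np.digitize(pts[:, 1], edges) - 1, 0, g - 1)
    cell_c = (edges[:-1] + edges[1:]) / 2.0
    cx, cy = np.meshgrid(cell_c, cell_c, indexing="ij")
    interior = np.hypot(cx, cy) <= R
    visited = np.zeros((g, g), dtype=bool)
    visited[ix, iy] = True
    coverage = float((visited & interior).sum() / interior.sum())

    return StrategyFeatures(
        efficiency_ratio=path_efficiency_ratio(traj, start, platform),
        corridor_fraction=corridor_percent_path(traj, start, platform) / 100.0,
        wall_fraction=wall_fraction,
        annulus_fraction=annulus_fraction,
        inner_fraction=inner_fraction,
        target_prox_fraction=target_prox,
        prev_prox_fraction=prev_prox,
        coverage=coverage,
        target_quadrant_fraction=target_quadrant_fraction,
    )


def classify(
    features: StrategyFeatures,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> StrategyLabel:
    """Assign a strategy label by the first matching rule of the cascade.

    Order: DSw, DSe, FS, P, T, C, S, with RS as the fall-through, so the
    classifier is total.  The perseverance rule is skipped when no previous
    platform is defined.
    """
    f, th = features, thresholds
    if f.efficiency_ratio <= th.dsw_efficiency_max and \
            f.corridor_fraction >= th.dsw_corridor_min:
        return StrategyLabel.DSw
    if f.corridor_fraction >= th.dse_corridor_min:
        return StrategyLabel.DSe
    if f.target_prox_fraction >= th.fs_prox_min:
        return StrategyLabel.FS
    if f.prev_prox_fraction is not None and f.prev_prox_fraction >= th.p_prox_min:
        return StrategyLabel.P
    if f.wall_fraction >= th.t_wall_min:
        return StrategyLabel.T
    if f.annulus_fraction >= th.c_annulus_min:
        return StrategyLabel.C
    if f.inner_fraction >= th.s_inner_min:
        return StrategyLabel.S
    return StrategyLabel.RS


def classify_trajectory(
    traj: Trajectory,
    previous_platform: Optional[tuple[float, float]] = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[StrategyLabel, StrategyFeatures]:
    feats = extract_features(traj, previous_platform, thresholds)
    return classify(feats, thresholds), feats


# ---------------------------------------------------------------------------
# summaries


def spatial_percent(labels: Iterable[StrategyLabel]) -> float:
    """Percentage of labels in the spatial category (DSe, FS, DSw, P)."""
    labels = [StrategyLabel(l) for l in labels]
    if not labels:
        raise ValueError("no labels")
    return 100.0 * sum(l.is_spatial for l in labels) / len(labels)


def improvement_rate(first_day_percent: float, last_day_percent: float) -> float:
    """Percentage-point change in spatial-strategy use, last day minus first.

    Positive values mean a progression toward spatial strategies; e.g.
    44% on day 1 and 87% on day 5 give an improvement rate of 43.
    """
    return last_day_percent - first_day_percent


def summarize_cohort(labels_df: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
    """Per-group, per-day strategy summary.

    ``labels_df`` needs columns ``group``, ``day`` and ``label_col``.
    Returns one row per (group, day) with per-label counts, the spatial
    percentage, and (on every row of a group) the group's improvement rate.
    """
    out = []
    for (group, day), sub in labels_df.groupby(["group", "day"]):
        labels = [StrategyLabel(l) for l in sub[label_col]]
        row = {"group": group, "day": day, "n_trials": len(labels)}
        for lab in StrategyLabel:
            row[f"n_{lab.value}"] = sum(l is lab for l in labels)
        row["spatial_percent"] = spatial_percent(labels)
        out.append(row)
    df = pd.DataFrame(out).sort_values(["group", "day"]).reset_index(drop=True)
    rates = {}
    for group, sub in df.groupby("group"):
        sub = sub.sort_values("day")
        rates[group] = improvement_rate(
            float(sub["spatial_percent"].iloc[0]),
            float(sub["spatial_percent"].iloc[-1]),
        )
    df["improvement_rate_percent"] = df["group"].map(rates)
    return df
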