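"""Readers and writers for the plain-text interchange formats.

Trajectories travel as CSV with header ``t,x,y`` (seconds, cm, cm);
arena geometry as JSON; trial collections as a manifest CSV with one row
per trial pointing at its trajectory file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import ArenaGeometry, Trajectory

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_arena_json",
    "write_arena_json",
    "read_manifest",
    "write_manifest",
]

_META_COLUMNS = [
    "subject", "group", "day", "trial", "trial_type", "start_position",
    "platform_quadrant", "previous_platform_quadrant", "true_strategy", "file",
]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("t,x,y\n")
        for t, (x, y) in zip(traj.times, traj.points):
            fh.write(f"{t:.6f},{x:.6f},{y:.6f}\n")


def read_trajectory_csv(path, arena: ArenaGeometry, **metadata) -> Trajectory:
    """Read a ``t,x,y`` CSV and validate it against ``arena``.

    Malformed rows are reported with their line number rather than a bare
    parser error.
    """
    df = pd.read_csv(path)
    expected = ["t", "x", "y"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header t,x,y, got {list(df.columns)}")
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        # +2: one for the header, one for 0-based indexing
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise ValueError(f"{path}: non-numeric or missing values at rows {rows}")
    return Trajectory(
        times=df["t"].to_numpy(float),
        points=df[["x", "y"]].to_numpy(float),
        arena=arena,
        **metadata,
    )


def write_arena_json(arena: ArenaGeometry, path) -> None:
    Path(path).write_text(json.dumps(arena.to_dict(), indent=2) + "\n")


def read_arena_json(path) -> ArenaGeometry:
    return ArenaGeometry.from_dict(json.loads(Path(path).read_text()))


def write_manifest(df: pd.DataFrame, path) -> None:
    cols = [c for c in _META_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "file" not in df.columns:
        raise ValueError(f"{path}: manifest needs a 'file' column")
    return df


def load_manifest_trajectories(
    manifest: pd.DataFrame, arena: ArenaGeometry, root: Optional[Path] = None
):
    """Yield (row, Trajectory) pairs for every trial in a manifest."""
    root = Path(root) if root is not None else Path(".")
    for _, row in manifest.iterrows():
        meta = {}
        for key in ("subject", "group", "start_position", "trial_type"):
            if key in row and not pd.isna(row[key]):
                meta[key] = row[key]
        for key in ("day", "trial", "platform_quadrant", "previous_platform_quadrant"):
            if key in row and not pd.isna(row[key]):
                meta[key] = int(row[key])
        traj = read_trajectory_csv(root / row["file"], arena, **meta)
        yield row, traj
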