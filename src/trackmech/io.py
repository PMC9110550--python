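"""CSV interchange formats.

All tables are plain CSV with physical units in the column names:
trajectories as ``frame, time_min, object_id, role, x_um, y_um``,
per-frame mechanics as ``frame, time_min, d_um, strain, force_nN``,
width profiles as ``frame, time_min, position_um, width_um, phase`` and
nucleus shapes as the morphometry table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import Trajectory

TRAJECTORY_COLUMNS = ["frame", "time_min", "object_id", "role", "x_um", "y_um"]
MECHANICS_COLUMNS = ["frame", "time_min", "d_um", "strain", "force_nN"]


def write_trajectories(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns {missing}")
    table[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: trajectory CSV missing columns {missing}")
    return table


def speckle_trajectories_table(trajs, pixel_quality: bool = True) -> pd.DataFrame:
    """Long-format table for tracked speckles (frame, position, NCC quality)."""
    rows = []
    for tr in trajs:
        for t in range(len(tr.positions)):
            if np.isnan(tr.positions[t, 0]):
                continue
            rows.append((t, t * tr.frame_interval, tr.speckle_id, "speckle",
                         tr.positions[t, 0], tr.positions[t, 1], tr.quality[t]))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS + ["quality"])


def trajectory_from_csv(path: str | Path, object_id: str, role: str,
                        frame_interval: float | None = None) -> Trajectory:
    """Load one object's trajectory from an interchange CSV."""
    table = read_trajectories(path)
    sel = table[(table.object_id.astype(str) == str(object_id)) & (table.role == role)]
    if sel.empty:
        raise ValueError(f"{path}: no rows for object {object_id!r} role {role!r}")
    sel = sel.sort_values("frame")
    if frame_interval is None:
        times = sel["time_min"].to_numpy()
        frames = sel["frame"].to_numpy()
        if len(sel) < 2:
            raise ValueError("cannot infer frame interval from a single row")
        frame_interval = float((times[-1] - times[0]) / (frames[-1] - frames[0]))
    return Trajectory(object_id=str(object_id), role=role,
                      positions=sel[["x_um", "y_um"]].to_numpy(dtype=float),
                      frame_interval=frame_interval,
                      frames=sel["frame"].to_numpy())
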