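"""Cell migration kinematics from point trajectories.

A migrating cell is tracked on three points — leading edge, nucleus
centre and cell rear.  From these we compute mean speed (total path
length over total time, so stop phases count fully toward time),
directional persistence (path length over beeline, ≥ 1 by the triangle
inequality), per-frame cell length and the relative position of the
nucleus along the rear→leading axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEADING = "leading"
NUCLEUS = "nucleus"
REAR = "rear"
CENTROID = "centroid"
ROLES = (LEADING, NUCLEUS, REAR, CENTROID)

#: Minimum beeline (µm) below which persistence is undefined (returned cell).
BEELINE_EPS = 1.0


@dataclass
class Trajectory:
    """Per-frame 2D positions (µm) of one tracked point.

    ``positions`` is ``(n, 2)`` with columns (x, y) in µm; frames are
    evenly spaced ``frame_interval`` minutes apart.
    """

    object_id: str
    role: str
    positions: np.ndarray
    frame_interval: float
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of (x, y) µm")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.frames is None:
            self.frames = np.arange(len(self.positions))
        else:
            self.frames = np.asarray(self.frames)
            if np.any(np.diff(self.frames) <= 0):
                raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def path_length(self) -> float:
        """Total path length in µm (sum of consecutive step lengths)."""
        steps = np.diff(self.positions, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    def beeline(self) -> float:
        """Start-to-end straight-line distance in µm."""
        return float(np.hypot(*(self.positions[-1] - self.positions[0])))

    def duration_min(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval)


def compute_speed(traj: Trajectory) -> float:
    """Mean migration speed in µm/min: path length / elapsed time.

    Stationary frames contribute zero path but full time, so pauses
    lower the mean speed rather than being excluded.
    """
    if len(traj) < 2:
        raise ValueError("speed is undefined for a single-frame trajectory")
    return traj.path_length() / traj.duration_min()


@dataclass
class PersistenceResult:
    """Directional persistence: path length / beeline (≥ 1 when defined).

    When the beeline is shorter than ``BEELINE_EPS`` the cell has returned
    to its start and the ratio is undefined; ``value`` is None and
    ``returned_cell`` is set instead of reporting a spurious number.
    """

    value: float | None
    returned_cell: bool = False


def compute_persistence(traj: Trajectory, beeline_eps: float = BEELINE_EPS) -> PersistenceResult:
    """Path-over-beeline persistence; 1 = perfectly straight motion."""
    if len(traj) < 2:
        raise ValueError("persistence is undefined for a single-frame trajectory")
    bee = traj.beeline()
    if bee <= beeline_eps:
        return PersistenceResult(value=None, returned_cell=True)
    return PersistenceResult(value=traj.path_length() / bee)


def _check_time_base(*trajs: Trajectory) -> None:
    n = len(trajs[0])
    for t in trajs[1:]:
        if len(t) != n or not np.array_equal(t.frames, trajs[0].frames):
            raise ValueError("trajectories do not share a time base")


def cell_length_series(leading: Trajectory, nucleus: Trajectory,
                       rear: Trajectory) -> tuple[np.ndarray, float]:
    """Per-frame cell length ‖leading − rear‖ (µm) and its mean."""
    if leading.role != LEADING or rear.role != REAR:
        raise ValueError(
            f"expected roles ({LEADING!r}, {REAR!r}), got "
            f"({leading.role!r}, {rear.role!r})")
    _check_time_base(leading, nucleus, rear)
    diff = leading.positions - rear.positions
    lengths = np.hypot(diff[:, 0], diff[:, 1])
    return lengths, float(lengths.mean())


@dataclass
class NuclearPositionResult:
    """Nucleus position as % of cell length along the rear→leading axis.

    The nucleus is projected onto the rear→leading axis, expressed as a
    percentage of cell length and clipped to [0, 100]; off-axis excursions
    do not inflate the position.  ``rear_nucleus`` flags cells whose mean
    position falls below the rear threshold.
    """

    percent: np.ndarray
    mean_percent: float
    rear_nucleus: bool
    skipped_frames: int = 0


def nuclear_position_series(leading: Trajectory, nucleus: Trajectory,
                            rear: Trajectory,
                            rear_threshold_pct: float = 30.0) -> NuclearPositionResult:
    """Relative nuclear position per frame (0 % = rear, 100 % = leading edge)."""
    if leading.role != LEADING or rear.role != REAR or nucleus.role != NUCLEUS:
        raise ValueError("expected roles (leading, nucleus, rear)")
    _check_time_base(leading, nucleus, rear)
    axis = leading.positions - rear.positions
    length2 = np.einsum("ij,ij->i", axis, axis)
    ok = length2 > 0
    skipped = int((~ok).sum())
    proj = np.einsum("ij,ij->i", nucleus.positions - rear.positions, axis)
    pct = np.clip(100.0 * proj[ok] / length2[ok], 0.0, 100.0)
    mean = float(pct.mean()) if len(pct) else float("nan")
    return NuclearPositionResult(percent=pct, mean_percent=mean,
                                 rear_nucleus=bool(mean < rear_threshold_pct),
                                 skipped_frames=skipped)


@dataclass
class CellMetrics:
    """Summary migration metrics for one cell."""

    mean_speed: float                 # µm/min
    persistence: PersistenceResult
    mean_cell_length: float           # µm
    mean_nuclear_position: float      # % of cell length
    rear_nucleus: bool


def cell_metrics(leading: Trajectory, nucleus: Trajectory, rear: Trajectory,
                 rear_threshold_pct: float = 30.0,
                 speed_point: str = NUCLEUS) -> CellMetrics:
    """Compute all migration metrics; speed/persistence use the nucleus track."""
    point = {LEADING: leading, NUCLEUS: nucleus, REAR: rear}[speed_point]
    _, mean_len = cell_length_series(leading, nucleus, rear)
    npos = nuclear_position_series(leading, nucleus, rear, rear_threshold_pct)
    return CellMetrics(
        mean_speed=compute_speed(point),
        persistence=compute_persistence(point),
        mean_cell_length=mean_len,
        mean_nuclear_position=npos.mean_percent,
        rear_nucleus=npos.rear_nucleus,
    )


def trajectories_from_table(table, frame_interval: float) -> dict[str, Trajectory]:
    """Build Trajectory objects from a long-format table.

    Expects columns ``frame, object_id, role, x_um, y_um`` (the ground
    truth / CSV interchange format); returns a dict keyed by role for the
    cell roles and by ``object_id`` for speckles and walls.
    """
    out: dict[str, Trajectory] = {}
    for (obj, role), grp in table.groupby(["object_id", "role"], sort=False):
        grp = grp.sort_values("frame")
        key = role if role in ROLES else str(obj)
        out[key] = Trajectory(
            object_id=str(obj), role=str(role),
            positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            frame_interval=frame_interval,
            frames=grp["frame"].to_numpy())
    return out
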