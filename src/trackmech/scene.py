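"""Seeded synthetic microtrack scenes.

This module renders multi-channel time-lapse stacks that emulate confocal
imaging of a cell migrating through a laser-ablated microtrack in a dense
collagen lattice: a speckled collagen reflection channel with a dark linear
track, a cytoplasm channel showing an elongated cell filling the track
cross-section, and a nucleus channel.  The cell exerts a prescribed wall
force; the collagen responds with a linear-elastic displacement field, so
every rendered stack comes with exact ground truth (wall displacement,
strain, force, speckle and cell trajectories, track width) against which
the measurement pipeline can be validated.

Mechanical model
----------------
The wall force ``F`` (nN) maps to strain through the linear relation
``F = E · s · A`` with Young's modulus ``E`` (Pa) and contact area ``A``
(µm²); since 1 Pa·µm² = 1e-3 nN, ``s = 1000·F / (E·A)``.  Strain is
realised geometrically as a perpendicular wall displacement decaying
linearly to zero at ``clamp_distance`` from the wall, so the peak wall
displacement is ``d_peak = s · clamp_distance`` and true strain is exactly
``d / clamp_distance`` at every time point.  Along the track axis the
displacement is modulated by a raised-cosine envelope of support
``contact_length`` centred on the cell, and in time by a linear ramp over
``ramp_frames`` frames.  A plasticity fraction of the locally attained peak
displacement may persist after the cell has passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stack import CYTOPLASM, NUCLEUS, REFLECTION, TimelapseStack

# Rendered intensity levels (arbitrary units, dynamic range ~[0, 1]).
REFLECTION_BASE = 0.30
TRACK_FLOOR = 0.02
SPECKLE_AMP = 0.70
CYTO_AMP = 0.80
NUC_AMP = 0.90
FLUOR_FLOOR = 0.02
EDGE_SOFT_UM = 0.16  # half a pixel at 0.32 µm/px: subpixel wall edges

PUSH = "push"
PULL = "pull"

#: Margin (µm) between the undeformed wall and the nearest speckle centre.
SPECKLE_WALL_MARGIN = 0.5


@dataclass
class Scene:
    """Parametric description of a synthetic microtrack world.

    Distances are µm, times minutes, forces nN, elastic modulus Pa.
    Defaults describe a wide track being pulled inward by a single
    migrating cell imaged at 0.32 µm/px every 4 minutes.
    """

    image_shape: tuple[int, int] = (384, 256)  # (Y, X) pixels
    pixel_size: float = 0.32
    frame_interval: float = 4.0
    n_frames: int = 30
    track_axis_y: float | None = None  # µm; default: image centre
    track_width0: float = 22.0
    speckle_density: float = 5.0  # per 100 µm² of collagen
    speckle_sigma: float = 0.6
    cell_speed: float = 0.5  # µm/min
    cell_length: float = 40.0
    nucleus_axes: tuple[float, float] = (15.0, 8.0)  # (major, minor) µm
    nucleus_offset_frac: float = 0.5  # nucleus position as fraction rear→leading
    cell_start_x: float | None = None  # µm; default: cell_length/2 + 2
    pause_at_x: float | None = None  # µm; cell dwells when its centroid reaches this
    pause_frames: int = 0  # duration of the stop phase, frames
    wall_force_peak: float = 20.0
    contact_length: float = 20.0
    clamp_distance: float = 40.0
    youngs_modulus: float = 340.0
    contact_area: float = 400.0
    deformation_sign: str = PULL
    plasticity: float = 0.0  # residual fraction of peak displacement
    ramp_frames: int | None = None  # frames to reach peak force; default 2/3 of movie
    noise_sd: float = 0.05
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dy, dx) px/frame
    seed: int = 0

    # -- derived quantities ---------------------------------------------
    @property
    def axis_y(self) -> float:
        if self.track_axis_y is not None:
            return float(self.track_axis_y)
        return self.image_shape[0] * self.pixel_size / 2.0

    @property
    def start_x(self) -> float:
        if self.cell_start_x is not None:
            return float(self.cell_start_x)
        return self.cell_length / 2.0 + 2.0

    @property
    def n_ramp(self) -> int:
        if self.ramp_frames is not None:
            return int(self.ramp_frames)
        return max(1, round(2 * (self.n_frames - 1) / 3))

    @property
    def peak_strain(self) -> float:
        """Dimensionless strain at peak force: 1000·F/(E·A)."""
        return 1000.0 * self.wall_force_peak / (self.youngs_modulus * self.contact_area)

    @property
    def d_peak(self) -> float:
        """Peak wall displacement (µm) from the closed form F/(E·A)·clamp."""
        return self.peak_strain * self.clamp_distance

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("pixel_size", "frame_interval", "track_width0", "speckle_sigma",
                     "cell_length", "contact_length", "clamp_distance",
                     "youngs_modulus", "contact_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.speckle_density < 0:
            raise ValueError("speckle_density must be >= 0")
        if min(self.nucleus_axes) <= 0:
            raise ValueError("nucleus_axes must be positive")
        if self.wall_force_peak < 0:
            raise ValueError("wall_force_peak must be >= 0")
        if self.deformation_sign not in (PUSH, PULL):
            raise ValueError(f"deformation_sign must be 'push' or 'pull', got {self.deformation_sign!r}")
        if not 0.0 <= self.plasticity <= 1.0:
            raise ValueError("plasticity must lie in [0, 1]")
        if self.pause_frames < 0:
            raise ValueError("pause_frames must be >= 0")
        if self.pause_at_x is not None and not \
                0 < self.pause_at_x < self.image_shape[1] * self.pixel_size:
            raise ValueError("pause_at_x must lie inside the image")
        if self.d_peak >= self.clamp_distance:
            raise ValueError(
                f"fold-over: peak wall displacement {self.d_peak:.2f} µm reaches the "
                f"clamped boundary at {self.clamp_distance:.2f} µm; lower wall_force_peak "
                f"({self.wall_force_peak} nN) or raise stiffness/contact area"
            )
        if self.deformation_sign == PULL and 2 * self.d_peak >= self.track_width0:
            raise ValueError(
                f"track collapse: pulling both walls in by {self.d_peak:.2f} µm closes a "
                f"{self.track_width0:.2f} µm track; lower wall_force_peak or widen the track"
            )

    # -- kinematic prescription -----------------------------------------
    def cell_x(self, frame: int | np.ndarray) -> np.ndarray:
        """Cell centroid axial position (µm) at a frame index.

        The cell advances at ``cell_speed``; if a stop phase is configured
        (``pause_at_x``/``pause_frames``) it dwells there before resuming,
        emulating the stop-and-go character of single-cell migration.
        """
        t = np.asarray(frame, dtype=float)
        if self.pause_at_x is None or self.pause_frames <= 0:
            return self.start_x + self.cell_speed * self.frame_interval * t
        per_frame = self.cell_speed * self.frame_interval
        t_reach = max(0.0, (self.pause_at_x - self.start_x) / per_frame)
        t_eff = np.where(t < t_reach, t,
                         np.where(t < t_reach + self.pause_frames, t_reach,
                                  t - self.pause_frames))
        return self.start_x + per_frame * t_eff

    def grip_start_frame(self) -> float:
        """Frame at which the force ramp begins.

        Without a stop phase the cell loads the wall from frame 0; with one
        the ramp starts when the cell arrives at the grip site, matching the
        build-up of traction over tens of minutes at a stationary contact.
        """
        if self.pause_at_x is None or self.pause_frames <= 0:
            return 0.0
        per_frame = self.cell_speed * self.frame_interval
        return max(0.0, (self.pause_at_x - self.start_x) / per_frame)

    def force_amplitude(self, frame: int | np.ndarray) -> np.ndarray:
        """Wall force (nN) at a frame: linear ramp to the peak over ramp_frames."""
        t = np.asarray(frame, dtype=float) - self.grip_start_frame()
        f = np.clip(t / self.n_ramp, 0.0, 1.0)
        return self.wall_force_peak * f

    def displacement_amplitude(self, frame: int | np.ndarray) -> np.ndarray:
        """Peak-of-envelope wall displacement d(t) in µm."""
        return self.force_amplitude(frame) / self.wall_force_peak * self.d_peak \
            if self.wall_force_peak > 0 else np.zeros_like(np.asarray(frame, dtype=float))

    def envelope(self, u: np.ndarray) -> np.ndarray:
        """Raised-cosine axial envelope with support ``contact_length``."""
        u = np.asarray(u, dtype=float)
        half = self.contact_length / 2.0
        out = np.zeros_like(u)
        inside = np.abs(u) < half
        out[inside] = np.cos(np.pi * u[inside] / self.contact_length) ** 2
        return out

    # -- serialisation ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scene":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("image_shape", "nucleus_axes", "drift_per_frame"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact per-frame state of a rendered scene.

    mechanics
        ``frame, time_min, d_um, strain, force_nN`` — wall displacement at
        the cell position, true strain ``d/clamp_distance`` and force
        ``E·s·A`` in nN.
    trajectories
        Long-format table ``frame, time_min, object_id, role, x_um, y_um``
        with roles ``leading``/``nucleus``/``rear`` (cell), ``speckle`` and
        ``wall``.  Coordinates are drift-free (stabilised frame).
    width_um
        ``(T, X)`` rendered track width at every axial pixel column.
    x_um
        Axial coordinate (µm) of each width column.
    """

    mechanics: pd.DataFrame
    trajectories: pd.DataFrame
    width_um: np.ndarray
    x_um: np.ndarray
    scene: Scene

    def speckle_positions(self, frame: int = 0) -> pd.DataFrame:
        t = self.trajectories
        return t[(t.role == "speckle") & (t.frame == frame)].reset_index(drop=True)

    def role_positions(self, role: str) -> pd.DataFrame:
        return self.trajectories[self.trajectories.role == role].reset_index(drop=True)

    def width_at(self, x_um: float, frame: int) -> float:
        col = int(round(x_um / self.scene.pixel_size))
        col = min(max(col, 0), self.width_um.shape[1] - 1)
        return float(self.width_um[frame, col])


def _soft_step(edge_distance: np.ndarray, soft_um: float = EDGE_SOFT_UM) -> np.ndarray:
    """0→1 linear ramp over ±soft_um around an edge (subpixel localisation)."""
    return np.clip(edge_distance / (2.0 * soft_um) + 0.5, 0.0, 1.0)


def _sample_speckles(scene: Scene, rng: np.random.Generator) -> np.ndarray:
    """Initial speckle positions (n, 2) = (x, y) µm, outside the track."""
    ny, nx = scene.image_shape
    y_max = ny * scene.pixel_size
    x_max = nx * scene.pixel_size
    lo_wall = scene.axis_y - scene.track_width0 / 2.0
    hi_wall = scene.axis_y + scene.track_width0 / 2.0
    band_lo = max(lo_wall - SPECKLE_WALL_MARGIN, 0.0)
    band_hi = y_max - min(hi_wall + SPECKLE_WALL_MARGIN, y_max)
    area = (band_lo + band_hi) * x_max  # µm² of collagen
    n = rng.poisson(scene.speckle_density / 100.0 * area)
    if n == 0:
        return np.empty((0, 2))
    x = rng.uniform(0.0, x_max, size=n)
    pick_hi = rng.uniform(0.0, band_lo + band_hi, size=n) >= band_lo
    y = np.where(
        pick_hi,
        hi_wall + SPECKLE_WALL_MARGIN + rng.uniform(0.0, 1.0, size=n) * band_hi,
        rng.uniform(0.0, 1.0, size=n) * band_lo,
    )
    return np.column_stack([x, y])


def _render_gaussians(img: np.ndarray, xy_um: np.ndarray, sigma_um: float,
                      amp: float, pixel_size: float) -> None:
    """Add Gaussian spots at subpixel positions, in place, via local patches."""
    if len(xy_um) == 0:
        return
    ny, nx = img.shape
    sigma_px = sigma_um / pixel_size
    half = max(2, int(np.ceil(4 * sigma_px)))
    for x_um, y_um in xy_um:
        cx = x_um / pixel_size
        cy = y_um / pixel_size
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, nx)
        y0c, y1c = max(y0, 0), min(y1, ny)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) - cx
        ys = np.arange(y0c, y1c) - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
        img[y0c:y1c, x0c:x1c] += amp * g


def _soft_ellipse(ys_um: np.ndarray, xs_um: np.ndarray, cx: float, cy: float,
                  a: float, b: float, soft_frac: float = 0.06) -> np.ndarray:
    """Soft-edged filled ellipse with semi-axes a (x) and b (y), in µm grid."""
    q = np.sqrt(((xs_um[None, :] - cx) / a) ** 2 + ((ys_um[:, None] - cy) / b) ** 2)
    return np.clip((1.0 - q) / soft_frac + 0.5, 0.0, 1.0)


def generate_stack(scene: Scene) -> tuple[TimelapseStack, GroundTruth]:
    """Render a scene into a (T, 3, Y, X) stack with exact ground truth.

    Channels are ``(reflection, cytoplasm, nucleus)``.  The same
    :class:`Scene` (including its seed) always yields byte-identical
    output.  Raises ``ValueError`` if the prescribed force would fold the
    collagen over the clamped boundary or collapse a pulled track.
    """
    scene.validate()
    rng = np.random.default_rng(scene.seed)
    ny, nx = scene.image_shape
    T = scene.n_frames
    ps = scene.pixel_size
    xs_um = np.arange(nx) * ps
    ys_um = np.arange(ny) * ps
    axis = scene.axis_y
    half0 = scene.track_width0 / 2.0
    sign = +1.0 if scene.deformation_sign == PUSH else -1.0

    speckles0 = _sample_speckles(scene, rng)
    n_spk = len(speckles0)
    spk_r = np.abs(speckles0[:, 1] - axis) - half0  # distance from undeformed wall
    spk_side = np.sign(speckles0[:, 1] - axis)
    spk_decay = np.clip(1.0 - spk_r / scene.clamp_distance, 0.0, None)

    # Running per-location peaks for the plasticity (residual deformation) term.
    col_peak = np.zeros(nx)       # per axial pixel column
    spk_peak = np.zeros(n_spk)    # per speckle
    wall_x = scene.cell_x(np.arange(T)).mean()  # wall marker at mid-path
    wall_peak = 0.0

    data = np.zeros((T, 3, ny, nx), dtype=np.float32)
    mech_rows = []
    traj_rows = []
    width_um = np.zeros((T, nx))

    dy_px, dx_px = 0.0, 0.0
    for t in range(T):
        time_min = t * scene.frame_interval
        amp = float(scene.displacement_amplitude(t))
        xc = float(scene.cell_x(t))
        # drift offsets content by +cumulative px; render world at p - offset
        off_y = scene.drift_per_frame[0] * t * ps
        off_x = scene.drift_per_frame[1] * t * ps

        # wall displacement per axial column (world coordinates)
        d_now = amp * scene.envelope(xs_um - off_x - xc)
        col_peak = np.maximum(col_peak, amp * scene.envelope(xs_um - xc))
        d_cols = np.maximum(d_now, scene.plasticity * np.interp(
            xs_um - off_x, xs_um, col_peak))
        halfw = np.clip(half0 + sign * d_cols, 0.0, None)
        # ground-truth width uses the drift-free field
        d_cols_world = np.maximum(amp * scene.envelope(xs_um - xc),
                                  scene.plasticity * col_peak)
        width_um[t] = np.clip(scene.track_width0 + 2.0 * sign * d_cols_world, 0.0, None)

        # reflection channel: plateau outside walls, floor inside, speckles
        edge_dist = np.abs(ys_um[:, None] - (axis + off_y)) - halfw[None, :]
        refl = TRACK_FLOOR + (REFLECTION_BASE - TRACK_FLOOR) * _soft_step(edge_dist)

        spk_d = np.maximum(amp * scene.envelope(speckles0[:, 0] - xc),
                           scene.plasticity * spk_peak)
        spk_peak = np.maximum(spk_peak, amp * scene.envelope(speckles0[:, 0] - xc))
        spk_u = spk_d * spk_decay
        spk_y = speckles0[:, 1] + sign * spk_side * spk_u
        spk_x = speckles0[:, 0]
        _render_gaussians(refl, np.column_stack([spk_x + off_x, spk_y + off_y]),
                          scene.speckle_sigma, SPECKLE_AMP, ps)

        # cell: soft ellipse spanning the local track cross-section
        col_c = min(max(int(round(xc / ps)), 0), nx - 1)
        b_cell = max(float(halfw[min(max(int(round((xc + off_x) / ps)), 0), nx - 1)]), 0.5)
        cyto = FLUOR_FLOOR + CYTO_AMP * _soft_ellipse(
            ys_um, xs_um, xc + off_x, axis + off_y, scene.cell_length / 2.0, b_cell)

        # nucleus at a fixed fraction of the rear→leading axis
        lead_x = xc + scene.cell_length / 2.0
        rear_x = xc - scene.cell_length / 2.0
        nuc_x = rear_x + scene.nucleus_offset_frac * (lead_x - rear_x)
        b_nuc = min(scene.nucleus_axes[1] / 2.0, b_cell)
        nuc = FLUOR_FLOOR + NUC_AMP * _soft_ellipse(
            ys_um, xs_um, nuc_x + off_x, axis + off_y, scene.nucleus_axes[0] / 2.0, b_nuc)

        frame = np.stack([refl, cyto, nuc])
        if scene.noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.noise_sd, size=frame.shape)
        data[t] = frame.astype(np.float32)

        # ground truth (drift-free world coordinates)
        strain = amp / scene.clamp_distance
        force = scene.youngs_modulus * strain * scene.contact_area * 1e-3
        mech_rows.append((t, time_min, amp, strain, force))
        traj_rows.extend([
            (t, time_min, "cell", "leading", lead_x, axis),
            (t, time_min, "cell", "nucleus", nuc_x, axis),
            (t, time_min, "cell", "rear", rear_x, axis),
        ])
        wall_d = max(amp * float(scene.envelope(np.array([wall_x - xc]))[0]),
                     scene.plasticity * wall_peak)
        wall_peak = max(wall_peak, amp * float(scene.envelope(np.array([wall_x - xc]))[0]))
        traj_rows.append((t, time_min, "wall_top", "wall", wall_x,
                          axis + half0 + sign * wall_d))
        traj_rows.append((t, time_min, "wall_bottom", "wall", wall_x,
                          axis - half0 - sign * wall_d))
        for i in range(n_spk):
            traj_rows.append((t, time_min, f"speckle_{i}", "speckle",
                              float(spk_x[i]), float(speckles0[i, 1] + sign * spk_side[i] * spk_u[i])))

    mechanics = pd.DataFrame(mech_rows, columns=["frame", "time_min", "d_um", "strain", "force_nN"])
    trajectories = pd.DataFrame(
        traj_rows, columns=["frame", "time_min", "object_id", "role", "x_um", "y_um"])
    stack = TimelapseStack(
        data=data, pixel_size=ps, frame_interval=scene.frame_interval,
        channel_roles=(REFLECTION, CYTOPLASM, NUCLEUS))
    truth = GroundTruth(mechanics=mechanics, trajectories=trajectories,
                        width_um=width_um, x_um=xs_um, scene=replace(scene))
    return stack, truth


def realized_speckle_count(stack: TimelapseStack, frame: int = 0) -> int:
    """Count detected speckle maxima in the reflection channel of one frame.

    Local maxima are detected above a robust threshold (median + 6 MAD-based
    sigma) so that pure noise yields zero detections; the dark track region
    contains no speckles and contributes none.
    """
    from skimage.feature import peak_local_max

    if not 0 <= frame < stack.n_frames:
        raise IndexError(f"frame {frame} out of range for {stack.n_frames}-frame stack")
    img = np.asarray(stack.channel(REFLECTION)[frame], dtype=float)
    med = float(np.median(img))
    mad_sigma = 1.4826 * float(np.median(np.abs(img - med)))
    thr = med + 6.0 * max(mad_sigma, 1e-12)
    peaks = peak_local_max(img, min_distance=1, threshold_abs=thr)
    return int(len(peaks))
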