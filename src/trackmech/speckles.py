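"""Collagen speckle tracking and linear-elastic traction force estimation.

Speckles in the reflection channel are followed over time by normalized
cross-correlation against their frame-0 template.  The distance change of
a speckle pair spanning the deforming region yields the matrix strain
relative to time point 0, and the simplified linear elastic relation
``E = stress / strain`` converts strain to traction force::

    F(t) [nN] = E [Pa] · |s(t)| · A [µm²] · 1e-3

with collagen Young's modulus ``E`` (340 Pa for a 6 mg/ml rat-tail
lattice) and an assumed cell–collagen contact area ``A`` (a 20 µm × 20 µm
square, 400 µm²).  The absolute force scale inherits the gauge-length
ambiguity of "relative deformation": it depends on the chosen speckle
pair, which should span the wall-to-clamp region being deformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.feature import match_template

from .stack import REFLECTION, TimelapseStack

#: NCC peak below which a speckle is considered lost to noise.
LOST_CORRELATION = 0.3


@dataclass
class ElasticModel:
    """Linear elastic parameters of the collagen lattice."""

    youngs_modulus: float = 340.0  # Pa
    contact_area: float = 400.0    # µm²

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0 or self.contact_area <= 0:
            raise ValueError("youngs_modulus and contact_area must be positive")


@dataclass
class SpeckleTrajectory:
    """Tracked path of one collagen speckle.

    ``positions`` is ``(T, 2)`` in µm (NaN after loss); ``quality[t]`` is
    the NCC peak value at frame t (1.0 at the seed frame).  ``lost_from``
    is the first frame at which the template could no longer be matched,
    or None if the speckle was followed to the end.
    """

    speckle_id: str
    positions: np.ndarray
    quality: np.ndarray
    frame_interval: float
    lost_from: int | None = None

    @property
    def n_valid(self) -> int:
        return len(self.positions) if self.lost_from is None else self.lost_from

    def displacement(self, frame: int) -> np.ndarray:
        """Displacement vector (µm) of this speckle at ``frame`` vs frame 0."""
        return self.positions[frame] - self.positions[0]


def _quadratic_peak(c: np.ndarray, ij: tuple[int, int]) -> tuple[float, float]:
    """Subpixel peak by 1D quadratic fits around an integer argmax."""
    i, j = ij

    def refine(m1, m0, p1):
        den = m1 - 2 * m0 + p1
        if den >= 0:  # not a maximum; keep integer location
            return 0.0
        off = 0.5 * (m1 - p1) / den
        return float(np.clip(off, -0.5, 0.5))

    di = refine(c[i - 1, j], c[i, j], c[i + 1, j]) if 0 < i < c.shape[0] - 1 else 0.0
    dj = refine(c[i, j - 1], c[i, j], c[i, j + 1]) if 0 < j < c.shape[1] - 1 else 0.0
    return i + di, j + dj


def track_speckles(stack: TimelapseStack, seeds_um: np.ndarray,
                   template_px: int = 7, search_px: int = 10,
                   min_correlation: float = LOST_CORRELATION,
                   ) -> list[SpeckleTrajectory]:
    """Track speckles by NCC against their frame-0 templates.

    For each seed an odd-sized square template is cut from the reflection
    channel of frame 0.  In every later frame the template is matched by
    normalized cross-correlation within a window of radius ``search_px``
    centred on the speckle's previous position; the correlation peak is
    refined to subpixel precision by quadratic interpolation.  A peak below
    ``min_correlation`` marks the trajectory lost from that frame onward.
    The stack should be stabilized and preprocessed first.
    """
    if template_px % 2 == 0:
        raise ValueError("template_px must be odd")
    refl = np.asarray(stack.channel(REFLECTION), dtype=float)
    T, ny, nx = refl.shape
    ps = stack.pixel_size
    half = template_px // 2
    seeds_um = np.atleast_2d(np.asarray(seeds_um, dtype=float))
    trajs: list[SpeckleTrajectory] = []
    for s_idx, (sx_um, sy_um) in enumerate(seeds_um):
        col0, row0 = sx_um / ps, sy_um / ps
        ic, ir = int(round(col0)), int(round(row0))
        if not (half <= ic < nx - half and half <= ir < ny - half):
            raise ValueError(f"seed {s_idx} at ({sx_um:.1f}, {sy_um:.1f}) µm too close to the border")
        template = refl[0, ir - half:ir + half + 1, ic - half:ic + half + 1]
        # fractional offset between the seed and the template's integer centre
        frac = np.array([row0 - ir, col0 - ic])
        pos = np.full((T, 2), np.nan)
        quality = np.full(T, np.nan)
        pos[0] = sx_um, sy_um
        quality[0] = 1.0
        prev = np.array([row0, col0])  # px (row, col)
        lost_from = None
        for t in range(1, T):
            pr, pc = int(round(prev[0])), int(round(prev[1]))
            r0 = max(pr - search_px - half, 0)
            r1 = min(pr + search_px + half + 1, ny)
            c0 = max(pc - search_px - half, 0)
            c1 = min(pc + search_px + half + 1, nx)
            window = refl[t, r0:r1, c0:c1]
            if window.shape[0] < template_px or window.shape[1] < template_px:
                lost_from = t
                break
            ncc = match_template(window, template)
            ij = np.unravel_index(np.argmax(ncc), ncc.shape)
            peak = float(ncc[ij])
            if peak < min_correlation:
                lost_from = t
                break
            ri, cj = _quadratic_peak(ncc, ij)
            # match position of template centre within the full frame
            row = r0 + ri + half + frac[0]
            col = c0 + cj + half + frac[1]
            pos[t] = col * ps, row * ps
            quality[t] = peak
            prev = np.array([row, col])
        trajs.append(SpeckleTrajectory(
            speckle_id=f"speckle_{s_idx}", positions=pos, quality=quality,
            frame_interval=stack.frame_interval, lost_from=lost_from))
    return trajs


@dataclass
class StrainSeries:
    """Pairwise speckle-distance strain relative to time point 0.

    ``strain[t] = (‖p_a(t) − p_b(t)‖ − L0) / L0`` with ``L0`` the frame-0
    separation; positive when the separation increased.  ``strain[0]`` is
    0 by construction.  The series is truncated at the first frame either
    trajectory was lost.
    """

    strain: np.ndarray
    frames: np.ndarray
    frame_interval: float
    baseline_um: float
    pair: tuple[str, str] = ("a", "b")

    def times_min(self) -> np.ndarray:
        return self.frames * self.frame_interval


def compute_strain(traj_a: SpeckleTrajectory, traj_b: SpeckleTrajectory,
                   min_baseline_um: float = 2.0) -> StrainSeries:
    """Strain from the distance change of a speckle pair."""
    n = min(len(traj_a.positions), len(traj_b.positions),
            traj_a.n_valid, traj_b.n_valid)
    if n < 1:
        raise ValueError("trajectories have no valid common frames")
    d = traj_a.positions[:n] - traj_b.positions[:n]
    sep = np.hypot(d[:, 0], d[:, 1])
    L0 = float(sep[0])
    if L0 <= min_baseline_um:
        raise ValueError(
            f"initial separation {L0:.2f} µm is below the {min_baseline_um} µm minimum")
    return StrainSeries(strain=(sep - L0) / L0, frames=np.arange(n),
                        frame_interval=traj_a.frame_interval, baseline_um=L0,
                        pair=(traj_a.speckle_id, traj_b.speckle_id))


@dataclass
class ForceSeries:
    """Traction force over time from strain and the elastic model.

    ``force_nN[t] = E · |s(t)| · A · 1e-3`` (1 Pa·µm² = 1e-3 nN); the
    deformation direction is carried separately as the sign of the strain
    (negative = separation decreased).
    """

    force_nN: np.ndarray
    stress_Pa: np.ndarray
    strain: StrainSeries
    model: ElasticModel

    @property
    def direction(self) -> np.ndarray:
        return np.sign(self.strain.strain)

    @property
    def peak_nN(self) -> float:
        return float(np.nanmax(self.force_nN))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.strain.frames,
            "time_min": self.strain.times_min(),
            "strain": self.strain.strain,
            "stress_Pa": self.stress_Pa,
            "force_nN": self.force_nN,
        })


def compute_force(strain: StrainSeries, model: ElasticModel | None = None) -> ForceSeries:
    """Apply the linear elastic relation F = E·|s|·A (reported in nN)."""
    model = model or ElasticModel()
    stress = model.youngs_modulus * np.abs(strain.strain)
    return ForceSeries(force_nN=stress * model.contact_area * 1e-3,
                       stress_Pa=stress, strain=strain, model=model)


@dataclass
class DisplacementField:
    """Per-speckle displacement vectors at one frame, relative to frame 0."""

    table: pd.DataFrame  # speckle_id, x0_um, y0_um, dx_um, dy_um, magnitude_um
    frame: int

    @property
    def max_magnitude_um(self) -> float:
        return float(self.table["magnitude_um"].max())

    def max_location(self) -> tuple[float, float]:
        row = self.table.loc[self.table["magnitude_um"].idxmax()]
        return float(row.x0_um), float(row.y0_um)

    def monotone_decay(self, wall_y_um: float) -> tuple[float, float]:
        """Spearman correlation of |u| vs distance from the track wall.

        A strongly negative correlation confirms the expected decay of
        collagen displacement away from the track edge.
        """
        r = np.abs(self.table["y0_um"] - wall_y_um)
        rho, p = sps.spearmanr(r, self.table["magnitude_um"])
        return float(rho), float(p)


@dataclass
class TrackGeometry:
    """Geometry of the deforming track region used for force inversion.

    ``axis_y_um``/``half_width_um`` locate the undeformed walls (measurable
    from the reflection channel at frame 0, e.g. via track-width edge
    detection); ``contact_x_um`` is the axial position of the cell-wall
    contact being analysed; ``clamp_distance_um`` is the distance from the
    wall at which the collagen is effectively held fixed, and
    ``contact_length_um`` the axial support of the contact envelope.
    """

    axis_y_um: float
    half_width_um: float
    contact_x_um: float
    clamp_distance_um: float = 40.0
    contact_length_um: float = 20.0

    def envelope(self, u: np.ndarray) -> np.ndarray:
        L = self.contact_length_um
        u = np.clip(np.asarray(u, dtype=float), -L / 2, L / 2)
        return np.cos(np.pi * u / L) ** 2 * (np.abs(u) < L / 2)

    def wall_distance(self, y_um: float, side: int) -> float:
        """Distance of a point from the undeformed wall on one side (µm)."""
        return side * (y_um - self.axis_y_um) - self.half_width_um


@dataclass
class TractionEstimate:
    """Consensus wall-displacement and force series from many speckle pairs."""

    wall_displacement_um: np.ndarray  # per-frame consensus d(t), NaN if < min pairs
    force_nN: np.ndarray
    model: ElasticModel
    n_pairs: int
    n_valid: np.ndarray  # pairs contributing per frame after outlier rejection

    @property
    def peak_nN(self) -> float:
        return float(np.nanmax(self.force_nN))


def estimate_traction_force(stack: TimelapseStack, speckle_xy_um: np.ndarray,
                            geometry: TrackGeometry,
                            model: ElasticModel | None = None,
                            end_frame: int | None = None,
                            template_px: int = 13,
                            near_band_um: tuple[float, float] = (4.0, 18.0),
                            far_band_um: tuple[float, float] = (30.0, 46.0),
                            max_axial_offset_um: float = 6.0,
                            min_pairs: int = 3) -> TractionEstimate:
    """Peak-robust traction force from the collagen speckle field.

    Speckle pairs spanning the deforming wall-to-clamp region are formed on
    both sides of the track: each wall-adjacent speckle (distance from the
    wall within ``near_band_um``, close to the contact axially) is paired
    with the axially nearest far speckle (``far_band_um``).  Each pair's
    distance strain is inverted to a wall-displacement estimate through the
    linear-decay / contact-envelope model using the pair's frame-0
    geometry, which removes the bias a raw pairwise strain carries when
    the pair is off the contact axis or not perfectly transverse.  A
    per-frame median across pairs with MAD outlier rejection suppresses
    speckles the tracker lost to a look-alike neighbour.  Larger
    "constellation" templates (default 13 px) make the match identity-
    specific; quality gating is deliberately not applied because high
    strain legitimately deforms the constellation and lowers the NCC peak
    of correctly tracked speckles.

    The stack must already be stabilized and preprocessed.  ``end_frame``
    restricts the analysis to the grip phase (while the contact stays at
    ``contact_x_um``); frames after it are ignored.
    """
    model = model or ElasticModel()
    geo = geometry
    clamp = geo.clamp_distance_um
    xy = np.atleast_2d(np.asarray(speckle_xy_um, dtype=float))
    # drop speckles whose template would clip the image border
    ny, nx = stack.frame_shape
    margin = (template_px // 2 + 2) * stack.pixel_size
    inside = ((xy[:, 0] > margin) & (xy[:, 0] < nx * stack.pixel_size - margin)
              & (xy[:, 1] > margin) & (xy[:, 1] < ny * stack.pixel_size - margin))
    xy = xy[inside]
    pairs: list[tuple[np.ndarray, np.ndarray, int]] = []
    for side in (+1, -1):
        r = np.array([geo.wall_distance(y, side) for y in xy[:, 1]])
        dx = np.abs(xy[:, 0] - geo.contact_x_um)
        near = np.where((r >= near_band_um[0]) & (r <= near_band_um[1])
                        & (dx <= max_axial_offset_um))[0]
        far = np.where((r >= far_band_um[0]) & (r <= far_band_um[1])
                       & (dx <= max_axial_offset_um + 4.0))[0]
        if len(near) == 0 or len(far) == 0:
            continue
        near = near[np.argsort(dx[near])][:5]
        for i in near:
            j = far[np.argmin(np.abs(xy[far, 0] - xy[i, 0]))]
            pairs.append((xy[i], xy[j], side))
    if not pairs:
        raise ValueError("no usable speckle pairs around the contact region")
    tra = track_speckles(stack, np.array([p[0] for p in pairs]),
                         template_px=template_px, search_px=6)
    trb = track_speckles(stack, np.array([p[1] for p in pairs]),
                         template_px=template_px, search_px=4)
    T = stack.n_frames
    dmat = np.full((len(pairs), T), np.nan)
    for k, ((a, b, side), ta, tb) in enumerate(zip(pairs, tra, trb)):
        try:
            s = compute_strain(ta, tb)
        except ValueError:
            continue
        ra = geo.wall_distance(a[1], side)
        rb = geo.wall_distance(b[1], side)
        gain = (geo.envelope(a[0] - geo.contact_x_um) * (1 - min(ra, clamp) / clamp)
                - geo.envelope(b[0] - geo.contact_x_um) * (1 - min(rb, clamp) / clamp))
        dy = abs(a[1] - b[1])
        if gain < 0.25 or dy < 5.0:
            continue
        n = len(s.strain)
        dmat[k, :n] = np.abs(s.strain) * s.baseline_um**2 / (dy * gain)
    if end_frame is not None:
        dmat[:, end_frame + 1:] = np.nan
    import warnings as _warnings
    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        med0 = np.nanmedian(dmat, axis=0)
        mad = np.nanmedian(np.abs(dmat - med0), axis=0)
        dmat[np.abs(dmat - med0) > np.maximum(3 * 1.4826 * mad, 0.3)] = np.nan
        n_valid = np.sum(~np.isnan(dmat), axis=0)
        med = np.nanmedian(dmat, axis=0)
    med[n_valid < min_pairs] = np.nan
    if np.all(np.isnan(med)):
        raise ValueError("consensus failed: no frame with enough valid pairs")
    force = model.youngs_modulus * (med / clamp) * model.contact_area * 1e-3
    return TractionEstimate(wall_displacement_um=med, force_nN=force,
                            model=model, n_pairs=len(pairs), n_valid=n_valid)


def displacement_field(trajs: list[SpeckleTrajectory], frame: int) -> DisplacementField:
    """Displacement vectors vs frame 0 for all trajectories valid at ``frame``."""
    rows = []
    for tr in trajs:
        if tr.lost_from is not None and frame >= tr.lost_from:
            continue
        u = tr.displacement(frame)
        rows.append((tr.speckle_id, tr.positions[0, 0], tr.positions[0, 1],
                     u[0], u[1], float(np.hypot(*u))))
    if not rows:
        raise ValueError(f"no trajectory is still tracked at frame {frame}")
    table = pd.DataFrame(rows, columns=["speckle_id", "x0_um", "y0_um",
                                        "dx_um", "dy_um", "magnitude_um"])
    return DisplacementField(table=table, frame=frame)
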