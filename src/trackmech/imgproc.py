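"""Stack stabilization, channel filtering, kymographs and track width.

The processing recipe mirrors a standard confocal reflection workflow:
translation-only drift correction by phase correlation on the collagen
reflection channel, disc-median filtering of fluorescence channels,
spatiotemporal mean filtering of the reflection channel, kymograph
sampling along polylines, and automated measurement of the dark track's
transverse width with subpixel edge localisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import median as sk_median
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .kinematics import Trajectory
from .stack import REFLECTION, TimelapseStack


# ---------------------------------------------------------------------------
# stabilization
# ---------------------------------------------------------------------------

@dataclass
class StabilizationResult:
    """Corrected stack plus the per-frame correction shifts applied.

    ``shifts[t]`` is the (dy, dx) translation in pixels applied to frame t
    to align it with the reference frame, i.e. the negative of the drift
    the frame had accumulated.  ``flat_frames`` lists zero-variance frames
    for which no shift could be estimated (shift 0 is applied).
    """

    stack: TimelapseStack
    shifts: np.ndarray  # (T, 2) pixels, (dy, dx)
    flat_frames: list[int] = field(default_factory=list)


def stabilize(stack: TimelapseStack, reference_frame: int = 0,
              upsample_factor: int = 50) -> StabilizationResult:
    """Remove translational drift using the reflection channel.

    Each frame's shift relative to ``reference_frame`` is estimated by
    subpixel phase correlation on the reflection channel and the negated
    shift is applied to all channels (one rigid translation per frame).
    """
    if not 0 <= reference_frame < stack.n_frames:
        raise IndexError(f"reference_frame {reference_frame} out of range")
    refl = stack.channel(REFLECTION)
    ref = np.asarray(refl[reference_frame], dtype=float)
    out = np.array(stack.data, dtype=np.float32, copy=True)
    shifts = np.zeros((stack.n_frames, 2))
    flat = []
    for t in range(stack.n_frames):
        frame = np.asarray(refl[t], dtype=float)
        if frame.std() == 0 or ref.std() == 0:
            flat.append(t)
            continue
        if t == reference_frame:
            continue
        drift, _, _ = phase_cross_correlation(ref, frame,
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        shifts[t] = drift  # translation that maps frame onto ref
        if np.any(drift != 0):
            for c in range(stack.n_channels):
                out[t, c] = ndimage.shift(stack.data[t, c].astype(float), drift,
                                          order=1, mode="nearest")
    return StabilizationResult(stack=stack.with_data(out), shifts=shifts,
                               flat_frames=flat)


# ---------------------------------------------------------------------------
# filtering recipe
# ---------------------------------------------------------------------------

def preprocess(stack: TimelapseStack, fluor_median_radius: int = 2,
               reflection_xy_halfwin: int = 1,
               reflection_t_halfwin: int = 2) -> TimelapseStack:
    """Apply the channel filtering recipe.

    Fluorescence channels (every non-reflection channel) are median
    filtered per frame with a disc of the given radius.  The reflection
    channel is mean filtered over a ±1 px spatial, ±2 frame temporal
    window; at stack edges the window is truncated (the mean is taken over
    the available samples only), so constant images are preserved exactly.
    """
    out = np.array(stack.data, dtype=np.float32, copy=True)
    footprint = disk(fluor_median_radius)
    for c, role in enumerate(stack.channel_roles):
        if role == REFLECTION:
            vol = np.asarray(stack.data[:, c], dtype=float)  # (T, Y, X)
            kernel = np.ones((2 * reflection_t_halfwin + 1,
                              2 * reflection_xy_halfwin + 1,
                              2 * reflection_xy_halfwin + 1))
            num = ndimage.convolve(vol, kernel, mode="constant", cval=0.0)
            den = ndimage.convolve(np.ones_like(vol), kernel, mode="constant", cval=0.0)
            out[:, c] = (num / den).astype(np.float32)
        else:
            for t in range(stack.n_frames):
                out[t, c] = sk_median(np.asarray(stack.data[t, c], dtype=np.float32),
                                      footprint=footprint)
    return stack.with_data(out)


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """Position × time intensity image sampled along a polyline.

    ``data[i, t]`` is the intensity at polyline sample ``i`` in frame
    ``t``; samples are spaced one pixel apart along the line.
    """

    data: np.ndarray                # (n_samples, T)
    line_um: np.ndarray             # (n_samples, 2) sampled (x, y) µm
    source_channel: str
    pixel_size: float
    frame_interval: float

    def positions_um(self) -> np.ndarray:
        """Arc-length coordinate (µm) of each sample."""
        d = np.diff(self.line_um, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])


def _sample_polyline(vertices_um: np.ndarray, spacing_um: float) -> np.ndarray:
    """Resample a polyline at ~one-pixel spacing, keeping the vertices' path."""
    verts = np.asarray(vertices_um, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("polyline must be an (n, 2) array of (x, y) µm")
    if len(verts) == 1:
        return verts.copy()
    pts = [verts[0]]
    for a, b in zip(verts[:-1], verts[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        n = max(1, int(np.ceil(length / spacing_um)))
        for k in range(1, n + 1):
            pts.append(a + seg * (k / n))
    return np.asarray(pts)


def kymograph(stack: TimelapseStack, line_um: np.ndarray, channel: str,
              prefilter_radius: int = 4) -> Kymograph:
    """Sample one channel along a polyline over all frames.

    The reflection channel is median filtered (disc of ``prefilter_radius``
    pixels) per frame before sampling; other channels are sampled as-is.
    Sampling is bilinear at one-pixel spacing along the line.  Polylines
    falling outside the image bounds are rejected.
    """
    ps = stack.pixel_size
    samples = _sample_polyline(np.asarray(line_um, dtype=float), spacing_um=ps)
    ny, nx = stack.frame_shape
    cols = samples[:, 0] / ps
    rows = samples[:, 1] / ps
    if (cols.min() < 0 or rows.min() < 0 or cols.max() > nx - 1 or rows.max() > ny - 1):
        raise ValueError("polyline extends outside image bounds")
    chan = stack.channel(channel)
    data = np.zeros((len(samples), stack.n_frames))
    footprint = disk(prefilter_radius) if channel == REFLECTION else None
    for t in range(stack.n_frames):
        img = np.asarray(chan[t], dtype=float)
        if footprint is not None:
            img = sk_median(img.astype(np.float32), footprint=footprint).astype(float)
        data[:, t] = ndimage.map_coordinates(img, [rows, cols], order=1)
    return Kymograph(data=data, line_um=samples, source_channel=channel,
                     pixel_size=ps, frame_interval=stack.frame_interval)


# ---------------------------------------------------------------------------
# track width
# ---------------------------------------------------------------------------

NO_TRACK = "no_track"
OK = "ok"


@dataclass
class WidthMeasurement:
    """Width of the dark track at one axial position and frame.

    ``status`` is ``"ok"`` with a width in µm, or ``"no_track"`` (with
    ``width_um`` = NaN) when the transverse profile shows no contiguous
    low-intensity run — distinct from a zero width.
    """

    width_um: float
    status: str
    y_edges_um: tuple[float, float] | None = None

    @property
    def found(self) -> bool:
        return self.status == OK


def measure_track_width(stack: TimelapseStack, axial_position_um: float,
                        frame: int, axial_halfwin_um: float = 1.6,
                        min_run_um: float = 1.0) -> WidthMeasurement:
    """Measure the transverse width of the dark track at one axial position.

    The transverse reflection profile (averaged over a small axial window
    to suppress speckle texture) is thresholded halfway between a robust
    track floor (profile minimum) and the collagen plateau (profile
    median — the median sits on the collagen base level rather than on
    speckle peaks); the width is the contiguous below-threshold run
    containing the minimum, with edges located by linear interpolation
    (subpixel).  The criterion is relative, so the measurement is
    invariant to global intensity scaling.
    """
    ps = stack.pixel_size
    ny, nx = stack.frame_shape
    col = axial_position_um / ps
    if not 0 <= col <= nx - 1:
        raise ValueError(f"axial position {axial_position_um} µm outside image")
    halfwin = max(1, int(round(axial_halfwin_um / ps)))
    c0 = max(int(round(col)) - halfwin, 0)
    c1 = min(int(round(col)) + halfwin + 1, nx)
    img = np.asarray(stack.channel(REFLECTION)[frame], dtype=float)
    profile = img[:, c0:c1].mean(axis=1)
    floor = float(profile.min())
    plateau = float(np.median(profile))
    if plateau <= 0 or floor >= 0.5 * plateau:
        return WidthMeasurement(width_um=float("nan"), status=NO_TRACK)
    thr = floor + 0.5 * (plateau - floor)
    below = profile < thr
    if not below.any():
        return WidthMeasurement(width_um=float("nan"), status=NO_TRACK)
    # contiguous below-threshold run containing the profile minimum
    edges = np.diff(below.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)  # exclusive
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(below))
    i_min = int(np.argmin(profile))
    runs = [(s, e) for s, e in zip(starts, ends)]
    s, e = next((r for r in runs if r[0] <= i_min < r[1]),
                max(runs, key=lambda r: r[1] - r[0]))
    if (e - s) * ps < min_run_um:
        return WidthMeasurement(width_um=float("nan"), status=NO_TRACK)

    def _cross(i_out, i_in):
        """Subpixel y (px) where the profile crosses thr between two samples."""
        a, b = profile[i_out], profile[i_in]
        if a == b:
            return float(i_in)
        return i_out + (thr - a) / (b - a) * (i_in - i_out)

    y_top = _cross(s - 1, s) if s > 0 else float(s)
    y_bot = _cross(e, e - 1) if e < len(below) else float(e - 1)
    width = (y_bot - y_top) * ps
    return WidthMeasurement(width_um=float(width), status=OK,
                            y_edges_um=(y_top * ps, y_bot * ps))


# ---------------------------------------------------------------------------
# width-versus-time profiles and passage phases
# ---------------------------------------------------------------------------

BEFORE = "before"
DURING_SINGLE = "during_single"
DURING_COLLECTIVE = "during_collective"
AFTER = "after"


@dataclass
class TrackWidthProfile:
    """Track width as a function of axial position and frame.

    ``table`` has columns ``frame, time_min, position_um, width_um`` and,
    after phase labelling, ``phase``.
    """

    table: pd.DataFrame

    @classmethod
    def measure(cls, stack: TimelapseStack, positions_um, frames=None,
                **kwargs) -> "TrackWidthProfile":
        """Measure widths on a grid of axial positions × frames."""
        frames = range(stack.n_frames) if frames is None else frames
        rows = []
        for t in frames:
            for pos in np.atleast_1d(positions_um):
                m = measure_track_width(stack, float(pos), int(t), **kwargs)
                rows.append((int(t), t * stack.frame_interval, float(pos),
                             m.width_um, m.status))
        return cls(pd.DataFrame(
            rows, columns=["frame", "time_min", "position_um", "width_um", "status"]))


def width_phase_summary(profile: TrackWidthProfile,
                        cell_trajs: list[dict[str, Trajectory]] | dict[str, Trajectory],
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label width measurements by cell-passage phase and summarise.

    Each measurement is labelled per frame by whether any cell body (the
    rear→leading axial interval of its trajectory) overlaps the measured
    axial position: ``before`` while every cell is still short of the
    position, ``during_single``/``during_collective`` while one/several
    cell bodies overlap it, and ``after`` once the cells have passed.
    Returns the labelled table and a per-phase summary (mean, SD, n).
    Cells are assumed to traverse in their net direction of motion.
    """
    if isinstance(cell_trajs, dict):
        cell_trajs = [cell_trajs]
    cells = []
    for trajs in cell_trajs:
        lead, rear = trajs["leading"], trajs["rear"]
        if len(lead.positions) != len(rear.positions):
            raise ValueError("leading and rear trajectories must share a time base")
        forward = lead.positions[-1, 0] >= lead.positions[0, 0]
        cells.append((lead.positions[:, 0], rear.positions[:, 0], forward))

    labels = []
    for _, row in profile.table.iterrows():
        t = int(row.frame)
        pos = row.position_um
        n_overlap = 0
        any_after = False
        all_before = True
        for lead_x, rear_x, forward in cells:
            ti = min(t, len(lead_x) - 1)
            lo, hi = sorted((lead_x[ti], rear_x[ti]))
            if lo <= pos <= hi:
                n_overlap += 1
                all_before = False
            elif (forward and rear_x[ti] > pos) or (not forward and rear_x[ti] < pos):
                any_after = True
                all_before = False
        if n_overlap >= 2:
            labels.append(DURING_COLLECTIVE)
        elif n_overlap == 1:
            labels.append(DURING_SINGLE)
        elif any_after:
            labels.append(AFTER)
        else:
            labels.append(BEFORE)
    table = profile.table.copy()
    table["phase"] = labels
    valid = table[table["status"] == OK] if "status" in table else table
    summary = (valid.groupby("phase")["width_um"]
               .agg(mean="mean", sd="std", n="count").reset_index())
    return table, summary
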