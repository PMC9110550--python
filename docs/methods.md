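# Methods

This note documents the models, conventions and design choices behind
`trackmech`: what the synthetic scenes emulate, how each measurement is
defined, which parameters matter, and where the known limitations are.

## The synthetic microtrack scene

`trackmech.scene` renders a three-channel time-lapse (collagen
reflection speckle, cytoplasm, nucleus) of a single cell migrating
through a linear track in a dense collagen lattice.  Defaults describe
the imaging conditions the package targets: 0.32 µm/px isotropic pixels,
4-minute frame intervals, tracks of 2.6–22 µm initial width inside a
field large enough to hold a full clamp distance of collagen on both
sides.  All randomness (speckle placement, Poisson speckle count,
Gaussian intensity noise) flows from one seed; identical scene + seed
produces byte-identical stacks.

### Geometry and rendering

* The track is a horizontal dark band (floor intensity 0.02) in a
  collagen background (base 0.30) carrying Gaussian speckles (amplitude
  0.70, σ = 0.6 µm, density 5 per 100 µm² of collagen — the speckle
  texture of confocal reflection images).  Wall edges are rendered with
  a half-pixel soft ramp so edge positions are meaningful at subpixel
  scale.
* The cell is a soft-edged ellipse filling the local track cross
  section, with an elliptical nucleus (default 15 × 8 µm) at a
  configurable fraction of the rear→leading axis (default 0.5).
* Additive Gaussian noise, default σ = 0.05 of the [0, 1] dynamic range
  (5 %), is applied per channel and frame.
* Optional uniform drift (px/frame) translates the rendered content
  analytically; ground-truth tables are always in drift-free
  coordinates, i.e. they describe the stabilized stack.

### Mechanics

The wall force `F` maps to strain via the linear relation
`F = E·s·A` (`E` = 340 Pa, `A` = 400 µm² by default; 1 Pa·µm² = 10⁻³
nN).  Strain is realised geometrically: each wall displaces
perpendicular to the track by `d(x, t) = d_peak·ramp(t)·env(x − x_cell)`
with

* `d_peak = s_peak · clamp_distance` — displacement decays linearly to
  zero at the clamped boundary (default 40 µm from the wall), making
  true strain exactly `d/clamp_distance`;
* `env` a raised-cosine envelope of support `contact_length` (20 µm,
  the side of the assumed contact square), centred on the cell;
* `ramp` a linear force build-up over `ramp_frames` (default two thirds
  of the movie; in grip scenarios 10 frames = 40 min).

Pull moves both walls toward the centerline (width `w0 − 2d`), push
moves them apart (`w0 + 2d`).  Speckles displace with the same field;
they are never created or destroyed.  A plasticity fraction ρ ∈ [0, 1]
of the locally attained peak displacement can persist after the cell has
passed (ρ = 0 models contractility-inhibited cells whose tracks relax
fully; ρ ≈ 0.5 models the partial persistence seen with untreated
cells).

Two generator safeguards reject unphysical scenes: fold-over
(`d_peak ≥ clamp_distance`) and pull collapse (`2·d_peak ≥ w0`).

### Stop phases and the force time course

Cells migrating in tracks move in a stop-and-go fashion, and traction
builds over tens of minutes while a cell grips a fixed wall site, not
while it crawls.  The generator therefore supports a stop phase
(`pause_at_x`, `pause_frames`); when one is configured the force ramp
starts at arrival (`grip_start_frame`).  This matters quantitatively:
with a 4-min frame interval, a full-amplitude deformation envelope
traveling at crawl speed would move wall speckles by several µm per
frame — faster than any tracker (or human) can follow on
temporally mean-filtered data, and faster than real wall deformation
develops.  The standard scenarios used in tests and in the acceptance
script (`grip_scene`) let the cell crawl in at 0.5 µm/min, stop for
16 frames at the grip site, and ramp the force over 10 frames.

## Image processing

* **Stabilization**: translation-only, subpixel phase correlation
  (plain cross-correlation normalization; upsampling ×50) of each
  reflection frame against a reference frame; one rigid shift per frame
  is applied to all channels.  Zero-variance frames are flagged and
  left unshifted.  Injected drifts up to 10 px are recovered within
  0.1 px/frame.
* **Channel filtering**: fluorescence channels are median-filtered with
  a 2 px-radius disc; the reflection channel is mean-filtered over a
  ±1 px spatial, ±2 frame temporal window with truncated windows at the
  stack edges (constants are preserved exactly).  Radii follow the
  Fiji convention for filter sizes.
* **Kymographs**: bilinear sampling at 1 px spacing along a polyline;
  the reflection channel is median-prefiltered (4 px radius) first.
* **Track width**: the transverse reflection profile, averaged over a
  ±1.6 µm axial window to suppress speckle texture, is thresholded
  halfway between the profile minimum (track floor) and the profile
  median (collagen base).  The width is the contiguous below-threshold
  run containing the minimum, with subpixel edges by linear
  interpolation.  The median is used for the plateau rather than a high
  percentile because high percentiles sit on speckle peaks and inflate
  the threshold.  A relative no-track criterion (floor ≥ 50 % of the
  plateau) distinguishes "no track" from zero width and makes the
  measurement invariant to global intensity scaling.
* **Passage phases**: each width measurement is labelled per frame by
  whether any cell body (rear→leading interval) overlaps the measured
  position: `before`, `during_single`, `during_collective` (≥ 2 cells),
  `after`.  The labelling is per-frame by overlap; binned
  before/during/after windows chosen by eye would differ slightly.

## Speckle tracking and force estimation

`track_speckles` follows each seed by normalized cross-correlation of
its frame-0 template inside a search window centred on the previous
position, with quadratic subpixel peak refinement; the NCC peak value is
the per-frame quality, and a peak below 0.3 marks the trajectory lost.
Defaults (template 7 px, search 10 px) suit sparse, slowly moving
speckles.

Two facts shape the force estimator built on top:

1. **Speckles are look-alikes.**  A 7 px single-speckle template can
   match a neighbouring speckle with NCC > 0.95, so a single pair is not
   robust.  `estimate_traction_force` uses 13 px "constellation"
   templates (locally unique), tighter search radii, and a consensus
   over ~10 pairs on both walls: per-frame median of the per-pair
   wall-displacement estimates with 3-MAD outlier rejection.  NCC
   quality is deliberately *not* used to gate frames: at high strain the
   constellation legitimately deforms and lowers the peak correlation of
   correctly tracked speckles.
2. **Pair strain needs geometric inversion.**  The raw pair strain
   `(‖p_a − p_b‖ − L0)/L0` equals the wall-gauge strain `d/clamp` only
   for a perfectly transverse pair on the contact axis.  Each pair's
   estimate is therefore corrected by its frame-0 geometry — the axial
   envelope factor at each speckle and the projection of the
   displacement difference on the pair direction — before entering the
   consensus.  The correction uses the same documented displacement
   model the generator implements; on real data the equivalent step is
   the experimenter's choice of a wall-perpendicular pair at the
   contact, and the absolute force scale inherits the gauge-length
   ambiguity of "relative deformation" (it depends on the assumed clamp
   distance).

With this estimator the full pipeline (stabilize → preprocess → track →
pair strain → elastic inversion) recovers prescribed peak forces of 10,
20 and 40 nN within a few percent across seeds; the acceptance tolerance
is 15 %.

**Limitation**: during the fastest ramp phases of a 40 nN grip,
wall-adjacent speckles move ~1 µm per frame and the ±2-frame temporal
mean smears them into streaks; individual trajectories can then lock
onto a neighbour for a few frames (excursions of 2–3 µm) before the
frame-0 template recaptures them.  The consensus median absorbs these
excursions, and the peak itself is quasi-static and unaffected, but
single-pair strain traces from high-force scenes should not be trusted
frame-by-frame.  Sub-half-pixel RMS tracking accuracy holds for speckle
velocities up to ~0.5 µm/frame (verified at 10 nN).

## Kinematics

Speed is total path length over total elapsed time — stationary frames
contribute zero path but full time, so stop phases lower the mean, by
convention.  Persistence is path length over the start-to-end beeline
(≥ 1; undefined and flagged as a "returned cell" when the beeline is
below 1 µm).  Cell length is ‖leading − rear‖ per frame; nuclear
position is the projection of the nucleus onto the rear→leading axis as
a percentage of cell length, clipped to [0, 100] so off-axis excursions
do not inflate it.  The rear-nucleus flag uses a configurable threshold,
default 30 % of cell length — the published figures show the rear-zone
box without a number, so the default is explicit and adjustable.
Metrics are computed over the full supplied trajectory; windowing is
left to the caller.

## Nuclear morphometry

Nuclei are segmented by Otsu thresholding plus a distance-transform
watershed (seed maxima ≥ 5 µm apart; raise `min_separation_um` for
strongly elongated nuclei, which the watershed otherwise splits).
Rule-based exclusion replaces manual curation: area < 10 µm², border
contact, or solidity < 0.5, each recorded with a reason code.

Shape descriptors are computed from the binary mask: minor/major
diameters from the inertia-tensor ellipse fit (binary moments; whether
the original workflow weighted by intensity is unknown, so the simpler
binary convention is used and stated), and

```
NII = (1 − circularity) + (1 − solidity),  circularity = 4πA/P²
```

— zero for an ideal disc, increasing with elongation and with contour
concavity.  The published work cites an NII definition without
reproducing the formula; this package's NII is its own documented
operationalisation with the same qualitative behaviour, not a
bit-compatible reimplementation.  Perimeter, area and solidity are
measured on the marching-squares contour smoothed with a 5-point
circular moving average; this keeps a digitised disc's circularity
within ~1 % of 1 (pixel-count perimeters err by 2–6 % and are
orientation-sensitive).  A digitised disc scores NII ≤ 0.02, and NII is
monotone in ellipse aspect ratio over 1–4 at fixed area.

The proteolysis index is (mean collagen-cleavage signal − background) /
nuclei count, clipped at zero with a flag; it is undefined without
nuclei.

## Statistics

Kruskal–Wallis (tie-corrected H, χ² p) with Dunn's pairwise z tests on
pooled ranks, tie-corrected, Bonferroni-adjusted by default (Holm and
Šidák available); the implementation is in-package and verified against
direct rank arithmetic.  If all observations are identical, H = 0 and
p = 1 by definition.  Two groups are rejected with a pointer to the
Mann–Whitney test, which uses the exact null distribution when the
smaller sample has n ≤ 8 and there are no ties (verified equal to full
permutation enumeration for all n₁+n₂ ≤ 10) and the tie-corrected
normal approximation otherwise.  Summaries report medians with 25/75th
and 5/95th percentiles using linear interpolation (type 7); plotting
software using a different percentile convention will differ in the
last digit.

## What the synthetic tests do and do not show

The generator reproduces the *geometry and mechanics* of microtrack
deformation under an idealised linear elastic, locally clamped model
with a smooth contact envelope, plus realistic pixel size, frame rate,
speckle texture and noise.  It does not model fibre-network
nonlinearity or strain stiffening, collagen remodelling/densification,
3D out-of-plane motion, photobleaching, or uneven illumination.
Passing the round-trip tests therefore demonstrates that the
measurement chain is unbiased and robust under the stated model — not
that the linear elastic force conversion is an accurate constitutive
description of any particular collagen preparation, for which the
Young's modulus and contact-area assumptions remain rough estimates.

## Problem sizes

Test and acceptance scenarios use 400 × 320 px fields (128 × 102 µm),
30–36 frames (2–2.4 h), ~500 speckles, and ~10 tracked pairs per force
estimate — a single region-of-interest analysis at full experimental
resolution, sized so the whole suite runs in about a minute.
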