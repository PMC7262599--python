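# Methods

## Scope and model

The package quantifies the motion of the two centrosomes of a flat
adherent cell relative to its nucleus from multi-channel time-lapse
stacks.  The geometry is treated as two-dimensional throughout: in these
"fried egg" cells the centrosomes travel essentially under or beside the
disk-shaped nuclear surface, so all angles, distances and speeds are
computed in (x, y) μm.  A z column is carried through the track tables
unchanged for consumers that have one.

Coordinate convention: image arrays are `(row, col) = (y, x)`, 0-based;
physical coordinates are `(x, y)` in μm = `(col, row) ×` pixel size.
Times are minutes, lengths μm in everything downstream of detection;
pixel-space coordinates are carried alongside in the spot and track
tables.

## Detection

The centrosome channel is band-passed with a difference of Gaussians,
sigmas 1.5 and 4.5 px — just below and above the expected ~3 px spot
size.  The background is defined by Otsu's threshold computed on the
filtered image over a 256-bin histogram, implemented as an explicit
exhaustive maximization of the between-class variance (and cross-checked
against an independent brute-force oracle in the tests).  Each connected
set of above-background pixels is claimed by one local maximum; touching
regions are split at their highest saddle (watershed on the inverted
filtered image).  Regions smaller than 15 px are removed after the split
— the splitting-order question is open in the original recipe; applying
the size rule afterwards means two merged spots are not jointly rejected.

Two filters follow:

- **Prominence.** A region's peak must exceed the background threshold by
  at least 10× the standard deviation of the sub-threshold filtered
  pixels.  Otsu always produces a threshold, even on a structureless
  frame; this rule is what makes an all-noise frame yield zero spots.
  (Measured: pure-noise frames yield maxima at ≤ ~8.5σ; true spots at
  peak SNR 5 sit at ≥ ~20σ.)
- **Circularity.** 4π·area/perimeter², clipped to 1, must reach 0.7.
  The perimeter is the length of the marching-squares sub-pixel boundary
  after one 3-point moving-average smoothing pass; plain chain-code
  counting collapses on 1-px-thin shapes, and unsmoothed contours
  overestimate digitized smooth boundaries (a radius-10 disk would score
  0.84).  Inside `detect_spots` the shape is judged on the region's
  half-maximum mask rather than its full above-background support: at low
  SNR the support is noise-ragged while the FWHM contour reflects the
  feature itself — a 3:1 streak remains 3:1 there and is still rejected.

Sub-pixel positions are intensity-weighted centroids of the
background-subtracted filtered signal.  EB3 comets use
Laplacian-of-Gaussian blob detection at the comet scale with no
circularity filter (comets are elongated by nature), refined by a local
intensity-weighted centroid.

## Segmentation

DNA channel: Otsu threshold → morphological close then open (disk,
radius 2 px) → Euclidean distance transform → Gaussian blur (σ = 2 px) →
watershed seeded at distance maxima, which cuts touching nuclei; objects
below a minimum area (default 100 px) are dropped.  A contrast guard
(foreground mean must exceed the background mean by 4 background sigmas)
keeps thresholding from inventing nuclei on empty frames.  Cell outline:
summed Gabor magnitude over 4 orientations × 2 frequencies (0.10,
0.25 cycles/px), smoothed, Otsu-thresholded, hole-filled; the connected
component containing the nucleus is kept, and a manually drawn polygon
can override the automatic result.  Per-frame failures set a flag and
exclude the frame from metrics rather than raising.  Because adherent
cells barely move between 5-min frames, the (expensive) Gabor outline is
recomputed every 5th frame by default and reused in between
(`SegmentationParams.cell_stride`).

## Tracking

Spots are linked frame-to-frame with one of three motion models: nearest
(predict = last position), drift (predict = last position + last
displacement — the EB3 regime), or a constant-velocity Kalman filter.
Candidate links are gated at the search radius (scaled by the gap length
when bridging up to `max_gap` missing frames) and resolved greedily by
ascending distance, ties toward the lower spot id; on instances whose
displacements stay below half the inter-spot spacing this reproduces the
optimal minimum-total-distance assignment (verified against a Hungarian
oracle).  Gap-closed positions are never interpolated; downstream
statistics use actual time lags.

Default centrosome search radius: **10 px** (2 μm/frame).  At the stated
imaging regime — 0.2 μm/px, 5-min frames, speeds up to ~0.5 μm/min — a
centrosome moves up to ~2.5 μm per frame; a 3–5 px radius would cut every
active-phase track into fragments.  The 3-px radius is the EB3 comet
default, where frame intervals are much shorter.

The two centrosome tracks of a cell are the two longest tracks lying
(majority of points) inside the cell mask; C1/C2 labels follow
first-frame intensity, then track id.

## Metrics

- **Distance and events.** d(t) is the Euclidean distance at common
  frames.  Separation onset: first frame d > 2.5 μm sustained 2 frames
  (the threshold sits above the engaged-pair regime; configurable).
  Contact: first frame d < 1.5 μm sustained 2 frames — 1.5 μm is roughly
  where two spots become an unresolvable merged detection at this pixel
  size.  When congressing centrosomes merge, one track ends next to the
  survivor just above the threshold; the pipeline recognizes this merge
  (the surviving spot lies within a tolerance plus the recent approach
  step of the ended track's last position) and records d = 0 from the
  merge frame on.  Without this closure the distance series would stop
  before ever crossing the contact threshold at high approach speeds.
- **Phases and speeds.** The active phase runs from onset until d first
  comes within 0.5 μm of its plateau maximum (noise in the plateau must
  not stretch the phase).  Speeds are path length over elapsed time
  within the phase window; the window starts *at* onset because the
  engaged pair may detect as a single midpoint spot one frame earlier,
  which would add phantom path.  "Approach velocity" (|Δd|/Δt of the
  pair distance) and individual path speed are both provided.
- **MSD.** Time-averaged over all overlapping pairs per lag, lags up to
  ⅓ of the track span — the usual bias/variance compromise.  High/low
  displacement grouping compares the two centrosomes at the largest lag
  common to both curves; exact ties go to C1.
- **Nuclear-envelope phases.** NE contact is the first frame within 1 μm
  of the nucleus boundary polygon (shapely point-to-ring distance);
  speeds are reported for outside, pause (0–20 min after contact) and
  after-pause windows.
- **Position classes.** Deterministic rules with inclusive tolerances:
  both beyond 5 μm from the NE and outside the nucleus → detached;
  angle ≥ 150° with both under the nuclear projection →
  diametric-under-nucleus; both within 1 μm of the NE → NE-border;
  otherwise side-of-nucleus.
- **Axis rotation.** Acute angle between undirected axes, [0°, 90°].

## Line profiles and ring score

Profiles crossing the nuclear envelope are sampled by bilinear
interpolation, normalized so the brightest sample is exactly 100%,
registered at their recorded NE crossing and aggregated pointwise
(mean ± SD on a 101-sample grid).  Perinuclear ring prominence = mean
intensity within ±1 μm of the nucleus boundary / mean intensity in a
cytoplasmic band 2–4 μm outside; the ratio is invariant to overall
scaling, ≈1 without a ring, and the present/absent cutoff is 1.5 —
halfway between the no-ring score (≈1) and a clearly visible ring at 3×
cytoplasmic intensity (≈3).

## Synthetic data: what it emulates and what it does not

The generator renders a single elliptical nucleus (default semi-axes
9 × 6 μm) inside an elliptical cell (22 × 18 μm) on a 256² px field at
0.2 μm/px and 5-min frames; channels: Gaussian centrosome spots
(σ = 1.5 px, amplitude 300 over background 100 → peak SNR ≈ 15; SNR 5
corresponds to amplitude 70), a flat DNA nucleus fill, band-pass random
texture for tubulin, anisotropic comets for EB3 (0.25 μm/min radial,
5 per centrosome per frame, 6-frame lifetime), and a ±1 μm perinuclear
annulus for actin.  Noise is Poisson shot noise plus Gaussian read noise
(σ = 5), deterministic under a seed.

Trajectory programs: separation (engaged pair 1 μm apart near the nuclear
centroid moving to endpoints placed at radius r = D/√(2(1 − cos θ)) so
that both the target distance D and the target angle θ at the centroid
hold), congression (separated pair moving straight to the nuclear
centroid), stall_at_NE (approach from 5 μm outside, 20-min dwell at the
boundary, continue inward), stationary, and detach.  Phase labels
(pre/active/post, outside/pause/inside), contact times and a
target-reached flag are emitted as ground truth.

Not emulated: forces and motors (trajectories are kinematic),
photobleaching, 3D PSFs, multiple cells per field, nuclear deformation.
A green test therefore establishes that the *measurement chain* recovers
programmed kinematics under realistic noise — not that any biological
model is correct.

## Numerical choices and limitations

- Otsu uses 256 bins; thresholds inside an empty histogram gap are
  accepted as equivalent maxima (the variance, not the bin index, is the
  invariant).
- The ellipse rasterizer works in pixel units so symmetric scenes give
  exactly symmetric masks (μm-space arithmetic breaks ties by floating
  point).
- Normalized profiles reach 100 exactly (`(v / max) × 100`); aggregation
  SD of identical profiles is zero to numerical precision (~1e-16).
- Kalman noise parameters (process 0.05, measurement 0.25 in
  units²/frame) are fixed, tuned only for smoothness, and matter little
  at the default frame intervals; `nearest` is the default model.
- The merge-closure rule cannot distinguish a true merge from one
  centrosome vanishing right next to the other within one frame; at the
  simulated regimes this ambiguity does not arise.
- `segment_cell` assumes one cell per field (the component containing
  the nucleus); multi-cell fields need per-nucleus calls with
  `track_masks` identities.
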