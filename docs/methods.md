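# Methods

This note documents the quantitative procedures implemented in `migmode`,
the assumptions behind them, the parameters that matter, and the design
choices made where the method was genuinely open.

## Scope and data model

The package analyses *segmented* single-cell time-lapse imaging.  Its inputs
are per-frame integer label masks (multi-page TIFF) for two layers — whole
cells and cell–matrix adhesion complexes (CMACs, demarcated by paxillin
fluorescence) — together with the matching intensity stacks (paxillin for
CMACs, LifeAct for F-actin) and acquisition metadata.  Defaults assume
confocal imaging at 0.21 µm/pixel and 5-min frame intervals.  Segmentation of
raw microscope images is out of scope: upstream tools produce the masks.
Migration-mode labels (Continuous / Discontinuous / null) are manual
annotations supplied as a CSV table; `null` marks dead cells or cells in
sustained contact and is excluded from every analysis.  Blinding support
(`io.blind_randomize`) produces a seed-deterministic bijection from sequence
ids to anonymous codes plus a randomized presentation order so that manual
classification can be performed blind to condition.

Pixel indices are 0-based `(row, col)`; physical coordinates are
`index × pixel_size_um` at pixel centers.

## Tracking and trajectory smoothing

Objects are linked frame-to-frame by *mutual nearest centroids* with a
distance gate: a link forms only when each object is the other's nearest
neighbour and their distance is inside the gate (3 equivalent cell radii for
cells, 2 µm for CMACs; both configurable).  Distance ties break toward the
lower label id.  There is no gap closing: an object must be present in
consecutive frames, so tracks never contain frame gaps.  Mutual-nearest
linking is symmetric, so tracking a time-reversed movie yields the same
links.

Cells touching the image border in a frame are removed from that frame
before tracking.  Cell trajectories are smoothed with cubic smoothing
splines; the smoothing parameter follows the csaps convention on [0, 1]
(1 = interpolation, 0 = least-squares line) and defaults to generalized
cross-validation.  Smoothing is applied to cell trajectories only.

CMAC filters: observations with area ≤ 0.05 µm² are discarded; surviving
runs shorter than three consecutive frames are discarded (runs split by the
area filter become separate tracks); lifetime = n_frames × frame interval
and is *undefined* — not zero — for tracks present in the first or last
frame of the sequence, which still contribute to all other statistics.

## Organizational features

One observation = one (cell, frame).  Built-in features: cell area
(pixel count × pixel area); cell compactness 4πA/P² with the perimeter
estimated by the 4-direction Crofton formula (clipped into (0, 1] against
digital-boundary overshoot); CMAC count, median and total CMAC area; median
CMAC distance to the cell border (Euclidean distance transform sampled at
the CMAC centroid); median background-corrected paxillin and LifeAct
intensity over the CMACs.  Additional features plug in through a registry
(name → function of a per-observation context), since the full catalogue of
organizational features is open-ended.

CMAC intensity correction subtracts the mean intensity in a 1-µm annulus
around the CMAC, excluding pixels of any other segmented CMAC; an annulus
fully occupied by neighbours yields an undefined (flagged) value.
Intensities are then standardized per experimental repeat by dividing by the
median corrected intensity of reference-sized CMACs (area 0.15–0.2 µm²) of a
reference condition, making values invariant to global linear intensity
scaling within a repeat.  Aggregates over zero CMACs are always missing
values, never zeros; downstream multivariate routines apply their own
missing-data policy.

## Membrane protrusion/retraction dynamics

Between two masks of the same cell, protrusion = pixels gained and
retraction = pixels lost, converted to µm².  Window sizes of 1–15 frames
(5–75 min) compare raw masks at t and t+w with no intermediate accumulation,
probing net shape/position changes per timescale.  Event-size probability
distributions use fixed-width 1-µm² bins from 0 to the 99.5th percentile of
the pooled events with open end bins; distributions are subtracted bin-wise
(the difference sums to zero).

Temporal coupling is quantified per cell by a lagged cross-correlation
between the protrusion and retraction series at lags −12..+12 frames
(±60 min); negative lags mean protrusion leads retraction.  Missing values
are imputed by the trajectory mean first.  Each lag is normalized on the
overlapping segments (per-lag correlation coefficient), bounding values by
1 in magnitude and making a pure one-frame-delayed copy correlate exactly
1.0 at lag −1; this per-lag normalization is this package's choice where the
historical routine is ambiguous about scaling.  Per-mode summaries average
|xcov| over all 25 lags per cell and window, then over cells with equal cell
weights and a t-based 95% CI.  Modes are compared by a Friedman test with
the 15 window sizes as blocks and the modes as treatments, implemented with
the tie-corrected chi-square statistic so that the two-treatment layout is
supported (generic implementations often require three).

## Motion analysis

Instantaneous speed is the frame-to-frame displacement of the smoothed
centroid divided by the frame interval (µm/min).  MSD profiles are computed
in a moving window (default 24 frames = 2 h), averaging squared
displacements over all in-window pairs at each lag; the window is centered
on the reported frame and truncated windows are dropped.  The first 12 lags
are fitted by nonlinear least squares to the Furth persistent-random-walk
model

    MSD(t) = 4 M (t − t_p (1 − e^{−t/t_p})),    M, t_p ≥ 0,

giving the migration coefficient M (µm²/min) and persistence time t_p (min).
Initialization uses the terminal slope (M₀ = slope/4, t_p₀ = 2 frame
intervals) with two further starts on failure; non-convergent fits are
flagged, never silently zeroed.  When the caller supplies the length n of
the averaged segment, lags are weighted by the standard sampling variance of
a time-averaged MSD (var ∝ MSD²·(2k²+1)/(3k(n−k+1)) at lag k); without
weighting, the noisy and strongly correlated long-lag values dominate the
fit and bias t_p low when t_p is below the frame interval.  Quantile binning
(quintiles/tertiles, linear-interpolation quantile edges) summarizes a
companion variable per bin by median and notch interval.

## Multivariate statistics

CVA (canonical variates analysis): features are z-scored, rows with missing
selected features dropped (features >20% missing are excluded with a
warning), and the canonical vectors solve the generalized eigenproblem
B v = λ W v with B the between-group and W the pooled within-group
covariance, W ridge-regularized by λ = 1e-6·trace(W)/p.  min(g−1, p)
vectors are retained; per-CV variance fraction is λᵢ/Σλ.  For two groups CV1
is the Fisher LDA direction (verified against a closed-form oracle).
Features are ranked by |CV1 coefficient|; group centers of mass are mean
scores per group; separation is the fraction of observations nearest their
own center.

PCA is SVD of the z-scored matrix.  Spearman matrices are pairwise-complete
with average-rank ties.  Correlation differences between two groups are
judged against a permutation null that shuffles which feature-pair identity
each off-diagonal value of one matrix carries while holding the other matrix
fixed, pooled over 100 permutations (seed-controlled).  KDE probability
surfaces use a Gaussian kernel with Silverman bandwidth × 0.5 (deliberately
smaller than the group spread) on a regular grid normalized to total mass 1.
Univariate comparisons use the two-sided Wilcoxon rank-sum test (exact for
small tie-free samples) and notched medians, median ± 1.57·IQR/√n with
linear-interpolation quantiles.

The per-mode speed-correlation catalogue computes Spearman rs between each
feature and speed *within* each cell trajectory (≥8 complete time points),
takes the median over cells per mode, and calls a coupling non-significant
when 0 lies inside the notch interval of the per-cell rs values; feature
classes compare the two modes (both-positive, both-negative, one-mode-only,
inverted).  Aggregation per cell (rather than per repeat) is this package's
choice.

## Synthetic data

The generator produces every input with known ground truth, at defaults
representing the study conditions (96 frames = 8 h at 5-min intervals,
0.21 µm pixels, 50 cells per mode):

* **Trajectories** — the velocity is a stationary Ornstein–Uhlenbeck process
  with relaxation time t_p and per-component variance M/t_p; position and
  velocity advance jointly by the exact Gaussian transition, so the ensemble
  MSD equals the Furth formula at every lag (unit-tested against the closed
  form).  t_p = 0 reduces to independent Gaussian steps.
* **Membrane events** — Continuous: protrusion follows a positive AR(1)
  fluctuation and retraction repeats it one frame later plus noise (tightly
  coupled, protrusion-led).  Discontinuous: sparse large retraction events
  (rate 0.10/frame, ≈40 µm²) on a small noisy baseline, each followed 5
  frames later by a protrusion burst (retraction-led, decoupled), plus weak
  one-frame coupling — yielding a bimodal retraction-size distribution, a
  cross-correlation peak near the generated delay, and lower overall
  coordination than the Continuous mode.
* **Feature tables** — two Gaussian populations over 20 features with a 4-sd
  shift on 3 features between modes, and a latent per-observation speed
  coupled to chosen features with mode-specific signs (default: one feature
  at +0.6/−0.6, an inverted coupling).
* **Rendered movies** — a deformable disk whose boundary is edited per frame
  by angle-contiguous pixel removal/addition so each transition realizes the
  prescribed protrusion/retraction pixel counts exactly (for integer-
  stationary tracks); CMAC blobs ride at fixed offsets with known intensity
  on a known background.  Pixel-level boundary editing was chosen over a
  parametric polar-perturbation shape because it guarantees the prescribed
  event areas to the pixel, which the round-trip validation depends on; no
  biomechanical realism is claimed.

What the generator does *not* emulate: segmentation errors, uneven
illumination, cell–cell contact, division/death, intensity photobleaching
and realistic cell morphology.  Passing round-trip tests therefore
demonstrate the correctness of the measurement code, not robustness to
segmentation noise.

## Numerical choices and limitations

* Validation problem sizes: 200 tracks × 96 frames per parameter set for
  Furth recovery; 50 cells × 96 frames per mode for coupling structure;
  1000 observations for CVA separation; 30-frame movies for the rendered
  round trip.
* Compactness can exceed 1 on digital shapes by discretization; it is
  clipped.  Distance-to-border uses the rounded CMAC centroid pixel.
* Constant series, empty annuli, zero-CMAC observations and degenerate KDE
  inputs are flagged (NaN) rather than coerced to 0.
* Whole-track MSD fits identify t_p below the frame interval only in the
  median over many tracks; single-window (24-frame) fits of such short
  persistence times are unreliable and should be interpreted as population
  summaries.
* The tracker is mutual-nearest with a gate: it does not handle merging,
  splitting, or objects that swap positions within one frame interval at
  distances comparable to their spacing.
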