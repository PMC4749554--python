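# migmode

Quantitative analysis of mesenchymal cell migration *modes* from segmented
single-cell time-lapse microscopy.

Migrating adherent cells alternate between two recurring behavioral modes:
**Continuous** migration — smooth translocation with stable morphology, where
membrane protrusion tightly leads retraction — and **Discontinuous**
migration — stepwise movement cycling through lateral protrusion,
polarization and tail retraction, with temporally decoupled membrane
dynamics.  `migmode` takes per-frame label masks of cells and of their
cell–matrix adhesion complexes (CMACs, marked by paxillin), plus matching
fluorescence stacks, and quantifies:

* **Motion** — instantaneous speed; moving-window mean squared displacement
  fitted to the Furth persistent-random-walk model
  `MSD(t) = 4M(t − t_p(1 − e^{−t/t_p}))`, yielding a migration coefficient
  *M* (µm²/min) and persistence time *t_p* (min) per window;
* **Membrane dynamics** — protrusion/retraction areas over 1–15-frame
  windows, event-size probability distributions and their differences, and
  the lagged (±12 frames) protrusion–retraction cross-correlation whose sign
  convention makes negative lags mean "protrusion leads retraction";
* **Organization** — per-(cell, frame) features: cell area and compactness,
  CMAC count/areas/lifetimes, distance to the cell border, and
  background-corrected, per-repeat-standardized paxillin and LifeAct (F-actin)
  intensities, with a registry for user-defined features;
* **Multivariate structure** — canonical variates analysis (CVA) separating
  mode populations and ranking features by |CV1 coefficient|, PCA, Spearman
  correlation networks with permutation-null difference testing, Gaussian-KDE
  probability surfaces over component space, Wilcoxon rank-sum tests and
  notched medians (median ± 1.57·IQR/√n);
* **Synthetic ground truth** — generators for persistent-random-walk
  trajectories (exact Ornstein–Uhlenbeck discretization matching the Furth
  MSD), mode-specific membrane event series, two-mode feature tables, and
  rendered label-mask movies realizing prescribed event areas exactly, so the
  whole pipeline is testable without microscope data.

Raw-image segmentation and automated mode classification are out of scope:
masks and mode labels are inputs (the package provides seed-deterministic
blinding/randomization support for manual classification).

## Worked example

```python
import numpy as np
from migmode import synthetic, motion, membrane, mvstats

# trajectories -> Furth fit
rng = np.random.default_rng(7)
track = synthetic.simulate_trajectory(m=2.0, t_p=10.0, frames=96, dt=5.0, rng=rng)
_, msd = motion.msd_moving_window(track[:, 0], track[:, 1], window=96, max_lag=12)
fit = motion.fit_furth(np.arange(1, 13) * 5.0, msd[0], n_frames=96)
print(f"M = {fit.m:.2f} um^2/min, t_p = {fit.t_p:.1f} min")

# membrane coupling per mode
for mode in ("Continuous", "Discontinuous"):
    pop = synthetic.simulate_membrane_population(mode, n_cells=50, frames=96, seed=7)
    profs = [membrane.protrusion_retraction_xcov(p, r, 12) for p, r in pop]
    mean_prof = np.nanmean([pr.values for pr in profs], axis=0)
    peak = profs[0].lags[np.argmax(mean_prof)]
    print(f"{mode}: peak lag {peak}, mean |xcov| {np.mean([p.mean_abs() for p in profs]):.3f}")

# two-mode feature table -> CVA
table = synthetic.simulate_feature_table(seed=7)
model = mvstats.cva_fit(table, [f"f{i:02d}" for i in range(20)])
print(f"CVA separation: {100 * mvstats.cva_separation(model):.1f}%; "
      f"CV1 variance fraction: {model.variance_fractions[0]:.2f}")
print("top features:", list(model.cv1_ranking()["feature"].head(3)))
```

Output:

```
M = 2.05 um^2/min, t_p = 11.5 min
Continuous: peak lag -1, mean |xcov| 0.249
Discontinuous: peak lag 5, mean |xcov| 0.126
CVA separation: 100.0%; CV1 variance fraction: 1.00
top features: ['f01', 'f02', 'f00']
```

Reading the numbers: a single simulated cell with true (M, t_p) = (2.0, 10)
fits to (2.05, 11.5) — single-track estimates scatter around the truth, and
the package's validation checks that the *median over 200 tracks* lands
within 15%.  The synthetic Continuous population peaks at lag −1 (protrusion
leads retraction by one frame, tightly coupled), while the Discontinuous
population's correlation peaks at the generated +5-frame delay
(retraction-led) and is overall less coordinated (lower mean |xcov|).  The
two-mode feature table (4-sd shift on features f00–f02) separates perfectly
in canonical-variates space, CV1 carries all the between-group variance, and
the three shifted features rank on top.

## Command line

```
migmode --seed 7 --out run/ simulate --mode both --n-cells 50 --frames 96
migmode --out run/ track --cells cells.tif --cmacs cmacs.tif
migmode --out run/ features --tracks run/cell_tracks.csv --cells cells.tif \
        --cmacs cmacs.tif --paxillin pax.tif --lifeact act.tif
migmode --out run/ dynamics --cells cells.tif --tracks run/cell_tracks.csv
migmode --out run/ msd --tracks run/cell_tracks.csv --window 24 --lags 12
migmode --out run/ cluster --method cva --features run/features.csv
migmode --out run/ correlate --features run/features.csv --by mode
migmode --out run/ frequencies --modes modes.csv
```

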