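# cellmotility

Persistent-random-walk analysis of cell migration trajectories.

Immune cells such as tissue-resident T cells search their environment by
undirected random walks. Two competing explanations exist for the broad range
of displacements such populations show: a scale-free walk (Lévy flight)
performed identically by every cell, or a population of ordinary persistent
random walkers that differ from one another. Distinguishing the two — and
characterizing the structure of the heterogeneity — requires a battery of
trajectory statistics applied to large sets of tracked cells. This package
implements that battery for anyone with tracked 2-D cell centroids (from
light-sheet or two-photon imaging, in vitro assays, etc.), together with a
stochastic simulator so every estimator can be validated end to end on
populations with known ground truth.

## The model

Each cell's velocity follows a 2-D Ornstein–Uhlenbeck process

```
dv_i/dt = -(1/P) v_i + (S/√P) η_i ,
```

with characteristic speed `S` (root-mean-square 2-D speed at stationarity,
µm/min) and persistence time `P` (min). Under this normalization the
per-component velocity autocovariance is `(S²/2)·e^(−τ/P)`, the ensemble mean
squared displacement is

```
MSD(τ) = 2 S² P τ (1 + (P/τ)(e^(−τ/P) − 1)) ,
```

and the long-lag effective diffusion constant is `D_eff = MSD/(4τ) = S²P/2`.

Heterogeneous populations draw a per-cell `S` from a speed law; the
persistence time is either uniform (UPT: `P = P0`) or coupled to speed
(SPC: `P = S/α + β`, with `α` an acceleration and `β` a time), so that faster
cells are also straighter. The observation model decimates positions to the
imaging interval and adds Gaussian mislocation noise — the two measurement
artifacts that bias secant-based speed and turning statistics.

## What the package computes

- **trajectory I/O** (`cellmotility.io`): delimited track tables
  (`track_id, sample_id, time_s, x_um, y_um`), inclusion filtering
  (≥ 30 consecutive steps), single-gap interpolation, splitting at longer
  gaps, temporal subsampling.
- **kinematics** (`cellmotility.kinematics`): secant velocities, folded turn
  angles, local speed–turn coupling, threshold-crossing persistence time,
  bout lengths (runs of same-sign x-displacement), per-track summaries.
- **ensemble statistics** (`cellmotility.ensemble`): time-averaged MSD with
  bootstrap bands and model fit; the velocity power spectrum (zero-padded,
  Parseval-normalized) with a piecewise log-log fit; bout-length
  distributions with stretched-exponential fits; per-track KS heterogeneity
  tests against the pooled distribution; speed classes (quintiles) with
  conditioned turning; speed-rank switching curves with permutation nulls;
  variance decompositions (speed vs stochasticity; between-sample R²).
- **diffusion scaling** (`cellmotility.diffusion`): persistence-vs-speed
  decile fit of `P = S/α + β`; `D_eff(τ)` by 5% speed bins; one-constant
  UPT (`D_eff ∝ S²`) vs SPC (`D_eff ∝ S²(S/α + β)`) scaling fits.
- **simulator** (`cellmotility.simulate`): Euler–Maruyama integration of
  UPT/SPC populations with optional speed switching and the observation
  model; ground-truth tables for parameter-recovery tests.
- **pipeline & CLI** (`cellmotility.pipeline`, `cellmotility` command):
  config-driven one-command runs, two-condition comparisons, JSON manifests.

## Worked example

```python
import cellmotility as cm
from cellmotility import ensemble, diffusion

# simulate a coupled (SPC) population and analyze it end to end
pop = cm.PopulationParams(n_cells=200, coupling=cm.SPC(alpha=4.0, beta=0.5),
                          duration=150.0, dt=9.0, sample_interval=45.0, seed=0)
tracks, truth = cm.simulate_observed(pop)
tracks = cm.preprocess(tracks)

summaries = cm.summarize_set(tracks)
print(summaries[["track_id", "mean_speed", "mean_cos", "persistence_time"]].head(3).round(3))

curve = ensemble.msd_curve(tracks, max_lag=20.0, seed=1)
fit = ensemble.fit_msd(curve)
print(f"MSD fit: S = {fit.S:.2f} um/min, P = {fit.P:.2f} min, sigma2 = {fit.sigma2:.2f} um2")

coupling = diffusion.persistence_vs_speed(summaries, seed=2)
print(f"coupling: alpha = {coupling.alpha:.2f} um/min2, beta = {coupling.beta:.2f} min "
      f"(UPT-consistent: {coupling.upt_consistent})")

deff = diffusion.deff_table(tracks, taus=[15.0, 19.5], bin_frac=0.1, seed=3)
upt, spc = diffusion.fit_scaling(deff, coupling)
print(f"D_eff scaling residuals (log space): UPT {upt.rss_log:.2f} vs SPC {spc.rss_log:.2f}; "
      f"SPC fold-variation {spc.fold_variation:.0f}x")
```

Output:

```
   track_id  mean_speed  mean_cos  persistence_time
0  cell0000       4.841     0.705             3.815
1  cell0001       3.751     0.591             3.227
2  cell0002       6.385     0.709             4.171
MSD fit: S = 6.45 um/min, P = 2.57 min, sigma2 = 0.51 um2
coupling: alpha = 2.57 um/min2, beta = 2.19 min (UPT-consistent: False)
D_eff scaling residuals (log space): UPT 1.50 vs SPC 0.08; SPC fold-variation 89x
```

Reading the numbers: the per-track table gives each cell's position on the
behavioral manifold (mean speed in µm/min, mean turn cosine, persistence time
in minutes). The ensemble MSD fit recovers a population-scale speed and
persistence time. The coupling fit confirms a positive speed–persistence
relationship (`UPT-consistent: False`); note its `alpha`/`beta` are the *raw*
fit to the threshold-crossing persistence estimator at 45 s sampling, which
overestimates `P` by a sampling-dependent offset — recovering the generative
constants requires the calibration map (`diffusion.persistence_calibration`,
see `docs/methods.md`). The scaling comparison strongly favors the coupled
model: the SPC shape fits the measured `D_eff` with ~20× smaller log-space
residual, and the predicted spread of diffusivities across the population is
~89-fold, i.e. the coupling amplifies the range of length scales cells
explore.

The same pipeline runs from the shell:

```
cellmotility reproduce-synthetic --out-dir out/ --seed 0
cellmotility analyze --tracks my_tracks.csv --out-dir out/
cellmotility compare --tracks-a control.csv --tracks-b treated.csv --out-dir cmp/
```

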