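# Methods

## Model and conventions

The walker model is the 2-D Ornstein–Uhlenbeck (OU) velocity process,
`dv_i/dt = −v_i/P + (S/√P) η_i` per component, with `η` unit white noise.
Conventions in the literature differ by constant factors in how `S` enters
the noise amplitude; this package fixes one convention everywhere:

- `S²` is the **stationary mean-square 2-D speed** (so the per-component
  velocity variance is `S²/2` and the mean 2-D speed is `S·√π/2 ≈ 0.886 S`);
- the per-component velocity autocovariance is `(S²/2)·e^(−τ/P)`;
- `MSD(τ) = 2 S² P τ (1 + (P/τ)(e^(−τ/P) − 1))`, hence ballistic `S²τ²` at
  `τ ≪ P` and diffusive `4 D_eff τ` with `D_eff = S²P/2` at `τ ≫ P`.

Fitted `S` values are convention-dependent and must not be compared across
conventions; all shape conclusions (exponents, ratios, fold-variations) are
convention-free.

Under speed–persistence coupling (SPC) the persistence time is linear in
speed, `P(S) = S/α + β`, with `α` an acceleration (µm/min²) and `β` a time
(min); the uniform-persistence-time (UPT) null sets `P = P0` for every cell.

Units: µm and seconds on disk and in `Trajectory` objects; µm/min for all
user-facing speeds; minutes for persistence times and MSD lags; radians for
angles (folded to `[0, π]`).

## Simulator

Integration is Euler–Maruyama per velocity component,
`v ← v(1 − dt/P) + (S/√P)·√dt·ξ`, positions `x ← x + v·dt`, with velocities
initialized from the stationary Gaussian to avoid transients in short
tracks. The step `dt` defaults to a few seconds; halving it changes ensemble
MSD estimates by less than the bootstrap bands (the first-order weak error
is `O(dt/P)`, about 1–4% in second moments at the defaults, absorbed by
fitted amplitudes and irrelevant to shape statistics).

Population defaults emulate a heterogeneous tissue population: per-cell `S`
log-normal with median 5 µm/min and log-sd 0.545 (5th–95th percentile
roughly 2–12 µm/min, an order-of-magnitude spread), coupling SPC with
`α = 4 µm/min²`, `β = 0.5 min` (persistence times of order 1–3.5 min),
45 s sampling, zero mislocation noise. Everything is configurable.

Speed switching is a Poisson redraw: at rate `switching_rate` per minute
(implemented as a per-step Bernoulli with probability `rate·dt`, the
discrete-time limit of exponential waiting times), a cell redraws `S` from
the speed law, updates `P` from the coupling, and rescales its velocity to
the new stationary scale. Ground-truth tables record the initial `(S, P)`
and every switching event.

The observation model decimates positions to the imaging interval (which
must be an integer multiple of `dt`) and then adds independent
`N(0, σ_loc²)` noise per coordinate — in that order, since mislocation noise
acts on the measured frames only.

What the generator does **not** emulate: boundaries or confinement, drift,
track fragmentation and segmentation errors, the excess of near-`π`
turn-backs seen in real amoeboid cells, 3-D motion, or any mechanistic
(actin-flow) model. Tests passing on synthetic data therefore validate the
estimators under the model's assumptions; they do not certify behavior on
artifacts the generator omits.

## Preprocessing rules

Tracks need at least 30 consecutive steps. A single missing frame is
linearly interpolated (midpoint of the neighbors); gaps of two or more
missing frames are never interpolated — the track is split into gap-free
child tracks (ids suffixed `.0`, `.1`, …), each re-filtered by the minimum
length, with reduction to the longest segment available as an option.
Preprocessing is idempotent. Interpolated steps are retained in all
downstream statistics (they exist precisely to keep the step series
consecutive).

## Estimators and numerical choices

**Secant kinematics.** Velocities are displacements over one sampling
interval divided by the interval. Turn angles between consecutive secant
steps are computed via `atan2(|cross|, dot)` (numerically stable, folded to
`[0, π]` automatically — the unfolded distribution is symmetric about 0).
Turns adjacent to a zero-length (or below-threshold) step are excluded, not
assigned angle 0, because their direction is undefined; exclusion counts are
logged. The local speed at a turn is the mean of the two adjacent step
speeds; the per-track `local_corr` is the Pearson correlation of local
speed and turn angle, undefined below 3 turns or at zero variance.

**Persistence time.** For each base step `s`, the elapsed time until the
first later step `m` whose displacement satisfies `x(s)·x(m) < 0` (for the
default π/2 threshold; the general test is angle > threshold), averaged over
base steps that terminate within the track; straight tracks yield NaN. The
search loops over lags with early exit, so cost is `O(n·⟨lag⟩)` rather than
`O(n²)` for typical tracks. The estimator is monotone in the threshold and
rank-preserving in the true `P`, but **biased**: relative to the OU
parameter `P` it carries a multiplicative factor and a positive offset that
grow with the sampling interval, plus a censoring component that depends on
track duration. `diffusion.persistence_calibration` measures the affine map
`P̃ ≈ cP + d` on noiseless ensembles matched in sampling interval,
duration *and* integration step, over a grid of `P` spanning the population
(in the noiseless model the turning test is invariant to speed rescaling, so
one map serves all speeds). The headline persistence-vs-speed curve uses the
raw `P̃` (as measured curves should); ground-truth recovery of `(α, β)`
inverts the calibration and regresses on the **RMS** track speed, which
estimates the model's `S` directly (the mean 2-D speed is `0.886 S` and
would bias `α` by ~11%).

**Bouts.** Consecutive same-sign x-displacements are summed into bouts;
zero displacements carry the previous sign (a reversal requires an actual
sign flip). Bout lengths are normalized by the per-track mean, so pooled
values average to 1 per track. The pooled distribution is binned on
percentile edges with density normalization and bin x-locations at the mean
of member points; the stretched exponential `A·e^(−γx^β)` is fit by least
squares in log-density space. The top percentile bin is excluded from the
fit (kept in the table): its width runs to the sample maximum, so its
width-averaged density understates the density at the bin's mean point by
roughly a factor `e`, which alone inflates the fitted `β` by ~0.2 on
exponential test data.

**MSD.** Per-track time-averaged MSD over all start points at every integer
lag (computed by the FFT autocorrelation identity, verified against brute
force), averaged across tracks; 95% bands from a 1000-resample bootstrap
over trajectories — the resampling unit for every interval estimate in the
package. The model `MSD(τ) = 2S²Pτ(1+(P/τ)(e^(−τ/P)−1)) + σ²` (the offset
`σ² = 4σ_loc²` absorbs mislocation noise) is fit in log space weighted by
the log-scale CI half-widths, with data-driven initialization (`S` from the
shortest lag, `P` from the long-lag diffusivity).

**Velocity power spectrum.** Per-track secant velocities are zero-padded to
400 timesteps (longer tracks truncated with a warning) and the spectrum
normalized so that the values at `k = 0…N/2` sum exactly to the track's
mean squared speed — a Parseval identity asserted to 1e-9 in the tests,
which pins the normalization. Spectra are averaged with equal weight per
trajectory. The two-segment log-log fit solves the continuous hinge model
exactly for each candidate breakpoint on the observed frequency grid and
keeps the least-squares winner; boundary breakpoints or equal slopes are
flagged degenerate. On a smoothly curved Lorentzian this piecewise estimator
has a known systematic: the low-frequency segment absorbs curvature below
the knee, giving a low-side slope near −0.25 rather than 0 and a knee
10–20% above `1/(2πP)`; both are properties of the fit, not the spectrum.

**KS heterogeneity.** The pooled CDF of secant speeds (or turn angles) is
estimated as linear interpolation of the cumulative frequency across 25
percentile bins and treated as fixed; each track is tested against it with a
two-sided one-sample KS test and the fraction below `alpha = 0.01` reported
(Benjamini–Hochberg available as an option). Two documented approximations:
the pooled CDF is estimated from the same data (negligible at hundreds of
tracks), and — more importantly — **the KS test assumes independent
samples**. Secant speeds of a persistent walker are serially correlated
(adjacent-interval correlation ≈ 0.6 at `P = 2 min` sampled at 45 s), which
makes the per-track test anti-conservative: on a *homogeneous* simulated
population with those parameters roughly 10% of tracks are flagged at
`alpha = 0.01`, versus the nominal ~1% that the same procedure delivers on
independent samples (both measured by the test suite and acceptance
script). Heterogeneity fractions from this procedure on strongly persistent
data are therefore upper bounds; fractions far above the inflated null
(e.g. the >80% flagged for a two-speed mixture) remain unambiguous.

**Speed classes and conditioned turning.** Tracks are ranked by mean speed
and split into equal-count quintiles (stable tie-breaking). Per class:
pooled folded turn-angle histograms, and mean turn cosine against
percentile-binned local speed with bin x-locations at the member mean.
Bootstrap bands resample tracks within the class; conditioned-turning bin
edges are frozen at the point estimate's percentiles so resamples are
comparable.

**Speed switching.** Per-track speeds are averaged on non-overlapping
19.5-min blocks (the default; `auto_block` scans multiples of the sampling
interval between 5 and 40 min and keeps the one maximizing adjacent-block
correlation). For each pair of block columns the Spearman correlation across
tracks is computed and averaged within equal start-time differences.
Bands bootstrap over tracks; the null envelope permutes speeds among tracks
independently within each block (1000 permutations by default).

**Variance decompositions.** A univariate smoothing spline `f` of per-track
mean turn cosine on mean speed gives the speed-explained share
`Vs = Var(f(S_m))`; the stochastic share is the mean squared standard error
of each track's mean cosine, `Vst = mean_m[Var_j(cos θ_jm)/(k_m − 1)]`; the
remainder is "other" (clamped at 0 with a warning when estimation noise
overshoots). Smoothing uses the library default factor (exact duplicate
speeds are averaged first); the factor is exposed as a parameter, and
scanning it over a ±4× range is the recommended sensitivity check since no
principled automatic selector is available for this spline. Between-sample
structure is summarized as the R² of mean speed on sample-identity
indicators (equivalently the between-sample share of speed variance).

**Effective diffusion and scaling laws.** `D_eff(τ) = MSD(τ)/4τ` per track
at user-chosen long lags (defaulting to five lags in the upper half of the
available range), averaged within 5% speed-quantile bins with
bootstrap-over-track bands and per-lag qualifying counts. Note the exact OU
value at finite lag is `(S²P/2)·(1 − (P/τ)(1 − e^(−τ/P)))`, a deterministic
deficit of `P/τ` (10% at `τ = 10P`) relative to the asymptote — comparisons
against theory use the exact finite-lag form. The UPT (`c·S²`) and SPC
(`c·S²(S/α + β)`) scaling models each have a single multiplicative constant
fit in log space weighted by the CIs, with `α, β` taken from the
persistence-vs-speed fit and never refit; reported per model are the
log-space residual sum of squares and the fold-variation of predicted
`D_eff` between the extreme speed bins (their ratio between the two models
equals the persistence ratio of the extreme bins, an identity the tests
verify numerically).

A related caveat: even for an uncoupled (UPT) population the raw
persistence-vs-speed fit has a slightly positive slope expectation
(z ≈ 1 at 300 tracks), because binning on *measured* mean speed selects
within-track fluctuations and high-speed OU episodes are also straighter.
It is two orders of magnitude below the coupled slope at the default
parameters, and vanishes as track length grows.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at the
sizes the validation design calls for: 1000 tracks × 60 min (dense 1.5 s
integration, 15 s observation) for the simulator-theory MSD/D_eff lock and
spectrum shape; 300 tracks × 180 min (3 s integration, 6 s observation) for
coupling-constant recovery; 300 tracks × 135–180 min at 45 s for the
KS, noise-bias and perturbation studies. Smaller unit-test ensembles
(≤ 400 tracks) share a session-scoped fixture. Bootstrap and permutation
counts default to 1000 in the library; tests use fewer where the assertion
tolerates it.

## Known limitations

- The persistence estimator's calibration map is model-based (noiseless OU);
  with mislocation noise the map is speed-dependent and no correction is
  attempted — instead the bias is characterized (slow-end spurious coupling)
  by the simulation study.
- KS heterogeneity fractions are anti-conservative on persistent tracks
  (above); no dependence-robust alternative is provided.
- The SPC model does not reproduce the excess of complete turn-backs
  (angles near π) of real cells; it targets diffusive-scale behavior.
- All analysis is 2-D; z-coordinates, if present in input tables, are
  ignored with a warning.
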