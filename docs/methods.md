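# Methods

## Scope and model overview

`avidex` implements the quantitative analysis behind an avidity-based
platform for capturing PD-L1⁺ exosomes: AFM force-distance (FD) rupture
scoring of functionalized capture surfaces, the surface-comparison and
clinical biomarker statistics, and the ellipsometric dose-response/LOD
calibration. Because the underlying raw data are not public, every analysis
is driven by a synthetic-data generator whose presets are calibrated so the
scored summaries match the published per-surface statistics; the pipeline
itself is agnostic to whether curves are simulated or read from disk.

## Rupture-event scoring

A retraction trace F(z) (force in pN, negative = attractive; separation z in
nm) is scored as follows.

1. **Baseline.** A straight line is fitted by OLS on the farthest
   `baseline_fraction` of the retract samples and subtracted from the whole
   trace. The default fraction is 0.45: the fitted line is extrapolated
   back to z = 0, and the extrapolation error there scales roughly as
   σ·(window fraction)^(-3/2)/√z_max. With σ = 30 pN, 160 nm traces and a
   45% window, the baseline error at the surface is ~13 pN (SD) —
   comfortably below the noise band; with a 20% window it would be ~70 pN,
   large enough to push whole noise stretches past the adhesion gates.
2. **Noise.** Robust SD of the far-field window: MAD × 1.4826.
3. **Contact point.** Scanning outward, the separation of the last in-band
   sample before |F| first exceeds `noise_k·σ` (default k = 2); `None`
   ("no contact") if the trace never leaves the band, in which case the
   adhesion energy is zero.
4. **Events.** A rupture is a local force minimum followed by a recovery
   toward baseline of at least the threshold (default 300 pN) within
   `within_window` (2 nm) of separation; events closer than
   `min_event_gap` (1 nm) are merged keeping the larger magnitude. The
   threshold applies to the *jump*, not the absolute force, so a second
   rupture riding on a deep adhesion well still counts. Curves with ≥ 2
   events are "multiple binding" (multivalent), 1 event "single", 0
   "no binding". Detection operates on the unsmoothed trace by default:
   at σ = 30 pN the 300 pN criterion sits at 10σ (measured-jump noise
   ~42 pN), so smoothing buys nothing and would blunt genuine jumps.
   Savitzky-Golay smoothing (window 11, order 2) is available per config.
5. **Maximum adhesion force.** F_max = max(−F) over the whole retract
   trace, so sub-threshold nonspecific adhesion yields a nonzero F_max
   (the scrambled control's mean sits near, not at, zero).
6. **Adhesion energy.** E_adh = ∫|F| dz by the trapezoid rule over
   adhesive runs: maximal contiguous stretches with F < −noise_k·σ whose
   peak depth also exceeds 4σ, with run edges extended to the linearly
   interpolated band crossings. The depth condition is essential under
   noise: plain per-sample gating at 2σ admits ~2.3% of noise samples and
   would accumulate σ·φ(2) ≈ 1.6 pN·nm of spurious energy per nm of trace,
   more than the smallest surface's published mean; with the 4σ depth
   condition the expected noise-only contribution is below 1 pN·nm per
   curve. On noise-free piecewise-linear traces the integral is exact.

Grid summaries report binding-class prevalences, mean ± SD (n−1) of F_max
and E_adh, class-stratified F_max statistics, and F_max/E_adh heatmaps in
acquisition order with missing raster positions as NaN.

## Synthetic FD curves

Each simulated curve is a piecewise-linear retraction trace:

* m specific bonds drawn from a per-surface PMF over {0, 1, 2, 3, 4};
  curves with m ≥ 2 are the multivalent population.
* Ordered rupture separations uniform on (5, 60) nm with a 3 nm minimum
  gap (so distinct events are never merged by the 1 nm merge window).
* Per-bond rupture magnitudes lognormal, truncated from below at 450 pN
  (threshold + ~3.5× the measured-jump noise SD), so every generated bond
  is detected with probability ≈ 1 and the scored class equals the
  generated one. Sub-450 pN contacts are treated as part of the
  nonspecific background rather than as marginal events. Single-bond
  curves and the bonds of multivalent curves may follow different
  lognormal laws so the class-stratified force statistics can be matched
  independently.
* Before each rupture the force loads along a steep linear ramp
  (`loading_stiffness`, pN/nm), giving an energy contribution of
  F²/(2k) per bond; the rupture itself is an instantaneous recovery,
  represented by a node pair 10⁻⁶ nm apart. Samples are placed on a
  uniform 0.5 nm grid *plus* the geometry nodes, so the polyline (and
  hence the trapezoidal energy) is exact at any grid spacing.
* A shallow nonspecific dip near z = 0 (lognormal depth, default mean
  50 pN) recovers gradually (slope ≤ 80 pN/nm, i.e. at most 160 pN over
  the detector's 2 nm window), so it raises F_max without ever counting
  as an abrupt rupture.
* I.i.d. Gaussian force noise (default σ = 30 pN) on every sample;
  traces run to z_max = 160 nm so the baseline window is long and clean.

Determinism: a curve is a pure function of (profile, seed); grids derive
per-curve streams from (seed, row, col) and are order-independent.

### Calibration and presets

`calibrate_profile` moment-matches a profile to a target summary: the PMF
is assigned the target prevalences exactly by construction, then a
fixed-point loop (common random numbers, ≤ 20 iterations) shifts the
lognormal log-means by the log-ratio of target to achieved force means
(stratified by class when stratified targets are given) and rescales the
loading stiffness by the achieved/target energy ratio, re-simulating and
re-scoring until all targeted moments are within tolerance.

The four shipped presets were produced by this routine at n = 4000 curves,
seed 7, 1% tolerance, against the published per-surface summaries:

| preset | P(multiple) | P(single) | targets |
|---|---|---|---|
| G7-pPDL1 | 0.890 | 0.110 | stratified F_max 654.9 / 1558.3 pN, E_adh 106.4 pN·nm |
| aPD-L1 | 0.710 | 0.200 | F_max 790.5 pN, E_adh 66.8 pN·nm |
| pPDL1 | 0.360 | 0.340 | F_max 594.0 pN, E_adh 51.5 pN·nm |
| G7-pPDL1-scr | 0.075 | 0.225 | F_max 350.9 pN |

Only the multiple-binding prevalence is published for each surface; the
single-binding prevalences of aPD-L1, pPDL1 and the scrambled control are
free parameters chosen to be plausible for an antibody, a monovalent
peptide and a nonspecific surface respectively. For G7-pPDL1 the published
stratified means force the choice: with P(multiple) = 0.89, the implied
overall mean 0.11·654.9 + 0.89·1558.3 = 1458.9 pN differs from the
published overall 1470.8 pN by 0.8% — an inconsistency inherited from the
source numbers and well inside the acceptance bands. The scrambled
surface's adhesion energy is not published and is left uncalibrated.

### What the generator does and does not emulate

It reproduces the *pipeline-level* statistics (class prevalences, force
and energy moments, their heavy right tails via lognormal magnitudes) and
the sequential discrete-jump morphology of multivalent retraction curves.
It does not model polymer elasticity (WLC/FJC stretching), loading-rate
dependence (Bell-Evans kinetics), parallel-bond load sharing, baseline
drift, or instrument artifacts. Rupture ramps are much steeper than real
tether stretching because the published adhesion energies (~10² pN·nm) are
tiny relative to the published forces (~10³ pN); with triangle-shaped
wells, matching both simultaneously forces narrow wells (F²/2k with
k ~ 10⁴ pN/nm). Passing closed-loop tests therefore demonstrates that the
scoring pipeline correctly recovers known generating parameters under
realistic noise — not that it is robust to every artifact of real AFM
data.

## Biomarker statistics

* **Gated comparison:** each group is screened with a one-sample KS test
  against a normal with the sample's own mean/SD (the published analysis
  protocol); if both pass at α the comparison is Welch's t (unequal
  variances — group SDs here differ by orders of magnitude), else a
  two-sided Mann-Whitney U. Scipy computes the exact U null for small
  tie-free samples and the tie-corrected normal approximation otherwise.
  Groups smaller than 5 cannot be screened and default to Mann-Whitney.
* **ROC AUC:** midrank Mann-Whitney identity, ties counted ½.
* **Kaplan-Meier:** product-limit estimator; censored times reduce the
  risk set without a step; events precede censorings at tied times.
* **Log-rank:** observed-minus-expected chi-square, 1 df, with the
  hypergeometric variance.
* **Cox:** univariate, Breslow ties, Newton-Raphson on an internally
  standardized covariate (≤ 50 iterations, gradient tolerance 1e-8, step
  clip 2), Wald p-value. Covariate = raw marker ("non-categorical") or
  above-median indicator ("binary"; marker equal to the median goes to
  the high group — a fixed tie rule). |β| ≥ 10 is reported as a monotone
  likelihood: non-converged, capped at ±20. Breslow was chosen so the
  score test at β = 0 coincides with the log-rank statistic on tie-free
  data (verified to 1e-6 in tests).
* **Schoenfeld power:** Φ(√(d·p(1−p))·|ln HR| − z₁₋α/₂) with d total
  events. The published 68%/76% powers correspond to d = 5 and d = 6
  events at the published binary-model HR 8.861, p = 0.5, α = 0.05 — the
  event counts are a reconstruction (they reproduce the printed powers to
  2 dp) since they are not published.
* No multiple-testing correction anywhere, matching the published
  analysis.

## Sensor calibration

Plateau levels are trailing-window means of each concentration step of the
staircase sensorgram; the dose-response is an OLS fit of dΨ on
log₁₀(concentration) (slope per decade, R²); the LOD inverts the fitted
line at baseline mean + 3·baseline SD, with the baseline taken from the
pre-injection running-buffer segment. The published LOD values depend on
an unpublished baseline-window convention and are treated as context, not
reproduction targets; the fold-change between systems is reported from
unrounded fitted slopes.

## Numerical choices and degenerate inputs

* Sample SDs use n−1; single-member strata report SD 0.
* Zero-variance samples are rejected by the KS gate and comparisons.
* An all-flat FD curve yields "no contact" and zero energy rather than an
  error.
* Curve IO uses fixed decimal formats (9 dp separations, 6 dp forces) so
  write→read→write is byte-identical.
* All randomness flows from explicit integer seeds; there is no
  wall-clock seeding anywhere.

## Problem sizes

Closed-loop acceptance checks use 20×20 grids (400 curves) per surface,
the acquisition size of the study; the false-event property uses 1000
pure-noise curves; sensor closed-loop recovery uses 100 seeds. A full
four-surface closed loop runs in a few seconds on one CPU.

## Known limitations

* The detector's defaults (2 nm recovery window, 1 nm merge) are exact on
  the simulator's geometry; real curves with slow rupture cascades inside
  1 nm would be merged.
* The Cox implementation is univariate only, by design.
* `read_fd_curves` supports the long-format TSV dialect only; proprietary
  AFM instrument formats are out of scope.
* KS-gating at small n has essentially no power, so small samples are
  compared nonparametrically regardless of their true distribution.
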