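# Methods

## Robustness score

For one strain over a perturbation space (a named set of cultivation
conditions), all non-missing phenotype values across conditions *and*
replicates are pooled as individual observations, and

    R = −(σ² / x̄) · (1 / m)

with `x̄` the strain mean, `σ²` the strain variance and `m` the grand
mean over every observation of every strain in the space. Properties
relied on throughout (and enforced by tests): `R ≤ 0` for non-negative
data with positive mean; `R = 0` iff `σ² = 0`; invariance under global
rescaling; strict monotonicity in `σ²` at fixed `x̄`, `m`.

Conventions:

* **Variance estimator.** Sample variance (`ddof=1`) by default — the
  unbiased choice at the small condition counts (≈14) these screens use;
  `ddof=0` is exposed for population-variance parity with other
  toolchains.
* **Grand mean.** Mean over all pooled observations, not the mean of
  strain means; the two coincide for balanced screens.
* **Degenerate strains.** A strain with `x̄ = 0` (no growth anywhere)
  has an undefined Fano factor; it is flagged `zero_mean` with missing
  `R`, never reported as 0 (which would read as maximal robustness).
  Zero-growth *observations*, by contrast, are ordinary data retained in
  `x̄`, `σ²` and `m`. Fewer than `min_obs` (default 2) usable values →
  `too_few_obs`.
* **Combined space.** When several subsets are declared, the pipeline
  also scores the union (`COMBINED`), with its own grand mean, as just
  another named subset.

## µmax estimation

The maximum specific growth rate is the largest slope of ln(signal)
versus time. The estimator fits a natural cubic smoothing spline to
ln(signal) with the penalty chosen by generalized cross-validation
(GCV), and takes the maximum of the spline's first derivative over the
observed interval (no extrapolation); a fixed penalty can be supplied
for exact reproducibility.

Because instrument noise is approximately additive on the linear scale,
log-transformed data are heteroscedastic (Var[ln y] ≈ σ²/y²). The
default therefore applies variance-stabilising weights `w ∝ ŷ²`, with
`ŷ` a pilot GCV smooth of the linear-scale signal; weights are
normalised so estimates are invariant to signal rescaling.
`weighting="none"` gives the plain unweighted log-scale fit. Exploration
during design (fixed penalties, discrepancy-principle penalty selection,
isotonic prefiltering, window-averaged derivatives, twicing,
stationary-tail truncation) did not improve on pilot weights.

Decision rules per well:

* **No growth:** `max(signal) < 1.2 ×` initial signal (mean of the first
  three points, robust to one noisy reading) → status `no_growth`,
  µmax = 0.
* **Fit quality:** R² is computed on the log scale — the scale of the
  residuals being minimised — between fitted and observed ln(signal);
  R² < 0.99 → `poor_fit`, µmax missing.
* **Validity:** < 5 points, non-increasing times, or non-positive raw
  signals → `invalid_input`. After optional blank subtraction, signals
  are floored at `1e-6 × max` before the log.

Known limitation: for logistic-like curves the true maximum of the log
derivative sits at the *start* of the record, where a spline derivative
is hardest to estimate. With additive noise at 1 % of the carrying
capacity, the median absolute µmax error across a 96-well plate is
0.010–0.016 1/h (systematically low for fast growers, whose short
exponential phase is smoothed into the stationary knee); at 0.1 % noise
it drops below 0.005 1/h. Errors in this regime are a property of
global-penalty spline estimators generally, not of this implementation —
the same data fitted with the classical unweighted GCV spline show
roughly tenfold larger medians.

## Classification and overlap

Percentile thresholds are type-7 (linear-interpolation) quantiles over
non-missing metric values; set membership is inclusive (`≤ q_low`,
`≥ q_high`), so a tie block sitting exactly on a threshold — typically
the strains at `R = 0` — is kept whole. Strains missing a metric are
excluded from that metric's sets; a metric whose low and high thresholds
coincide is flagged degenerate with a warning.

Venn categories are the eight mutually exclusive membership patterns of
(HF | LF | neither) × (HR | LR | neither); HF∩LF and HR∩LR are empty by
construction. Percentages use the union of the four sets as denominator
and sum to 100 up to rounding.

## Region deviation test

Each annotation region (label per strain; "unknown" is a real label,
not a missing marker) is compared against the distribution of **all**
annotated strains — deliberately *including* the region itself, the
framing used when a region is judged against "the overall distribution".
This overlap makes the test mildly conservative (the null variance is
overstated by a factor ≈ N/(N−n)); a conventional region-vs-complement
variant is available via `include_region=False`. The statistic is the
two-sided Wilcoxon rank-sum / Mann–Whitney U: exact null distribution
when both samples have n < 25 and no ties, tie-corrected normal
approximation otherwise (overridable). Regions below `min_region_size`
(default 3) are skipped with a log line. Benjamini–Hochberg adjusted
p-values are reported next to the raw ones, never silently substituted.

## Synthetic data

`simulate_screen` draws, per strain `s` and condition `c`,

    value(s, c, rep) = mean_s · g_c · h_{s,c} + ε,   clipped at 0

with log-normal strain means `mean_s` (median 1.0, log-sd 0.2),
log-normal shared condition effects `g_c` (log-sd 0.1), strain-specific
condition interaction `h_{s,c}` whose across-condition coefficient of
variation is drawn per strain from Gamma(2, 0.05) (mean CV 0.1), and
additive replicate noise ε (sd 0.02). A fraction of cells
(`zero_growth_fraction`, 0.5 %) is set to exact zero, mirroring
no-growth calls. A `robust_fraction` (1.5 %) of strains is emulated as
exactly invariant — identical values in every condition — reproducing
the tie block of maximal-robustness strains that real discretised
colony-size screens show and that the inclusive-threshold rule exists
for. Default dimensions, 4429 strains × 14 conditions × 1 observation,
follow the reference screen scale this pipeline targets.

Ground truth (`true_mean`, `true_dispersion`, `true_robustness`) is
computed from the noise-free expected values across the realized
conditions, with the same `ddof=1` convention as the estimator, so at
zero noise and one replicate the estimate equals the truth exactly;
with noise, parameter-recovery tests honestly include estimator error.

`simulate_plate` draws logistic trajectories
`y(t) = K / (1 + (K/y0 − 1)e^{−rt})` over 48 h at 0.5 h intervals with
additive Gaussian noise (sd = 1 % of K by default) floored at a small
positive value; the true µmax is the analytic `r(1 − y0/K)`. Start
signals default to 5–15 % of K — an inoculum resolvable above the noise
floor, as a competently run experiment is designed — and rates to
0.05–0.3 1/h, the span budding yeast covers in rich or
inhibitor-supplemented media. No-growth wells are flat at `y0` plus
noise. What the simulator does *not* emulate: lag phases, diauxie,
signal drift, evaporation, well-to-well cross-talk, or saturating
camera calibration; passing recovery tests therefore bound estimator
error under clean logistic kinetics, not under every real curve shape.

`simulate_annotation` assigns strains to regions uniformly or by
weights and can plant per-region multiplicative fitness shifts (used by
the power checks of the deviation test). All generators are
deterministic given config + seed.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen as the package's
own verification budget: 100×14 matrices for score-vs-oracle agreement
(tolerance 1e-12 relative), 96-well plates for µmax recovery, 300–500
null/power replicates for the deviation test (KS at α = 0.01; planted
2-pooled-sd shift, n_region = 30, N = 1000), and a 300×14 screen run
twice for byte-identical pipeline output. Floats are written with 6
significant digits; rows are sorted on every writer, so outputs are
reproducible byte-for-byte given config + seed. The derivative of the
growth spline is maximised on a 2001-point grid over the observed
interval; negative zero is normalised so `R = 0` prints as `0`.
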