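# Methods

This note documents the models, numerical choices, and known limitations
of the package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design emulated by the generator

Each synthetic participant completes two scanner tasks (identify, compare)
of 160 trials each: 4 numerosities {2, 4, 6, 8} x 2 formats (nonsymbolic
dot arrays, symbolic digits) x 20 trials per cell at defaults.  Trial
order is pseudorandom with no more than 3 consecutive trials of the same
numerosity-and-format, enforced by rejection sampling with a retry cap of
10^5 shuffles (a `DesignError` is raised beyond the cap rather than
looping).  Interstimulus intervals take the five values 3300-7300 ms in
1000 ms steps, balanced exactly within every (numerosity, format) cell, so
the task-level mean is exactly 5300 ms whenever the per-cell trial count
is a multiple of five; otherwise remainders are spread by per-cell random
rotation.  Whether the original counterbalancing was exact or approximate
within every sub-condition is not stated anywhere; exact balance is
generated because it makes the design-count contracts testable.

Out-of-scanner behavior is a 70-trial number-comparison session: 7 ratio
pairs x 10 repetitions, endpoints (5 vs 15, ratio 0.33) and (9 vs 10,
ratio 0.9).  The five middle pairs — (5,12), (6,12), (7,12), (8,12),
(9,12) — are the package's own choice from the same 5-15 dot range, spaced
roughly evenly in ratio; only the endpoints and the trial count are pinned
by the design being emulated.

## Neural generative model

The pattern generator is the package's own construction (the analysis it
feeds is format-agnostic about where patterns come from).  It follows the
field-standard account of numerosity coding:

- A fraction `active_fraction` (default 0.5) of each region's voxels
  responds to the stimuli; the rest carry pure noise.  This gives
  activation-based voxel selection a real target, as in real regions of
  interest where the t-contrast separates responsive from unresponsive
  voxels.
- Each responsive voxel has a preferred numerosity drawn uniformly in log
  space on [log 2, log 8] and a log-Gaussian tuning curve with SD
  `tuning_width` (default 0.4 log-units, wide enough that adjacent
  numerosities overlap and confusions show a distance effect).
- Nine independent tuning maps are drawn per participant/region: one
  shared, one per format, one per task, one per format x task cell.  The
  noiseless pattern for cell (n, f, t) is the convex mixture
  `af*at*S + (1-af)*at*F_f + af*(1-at)*T_t + (1-af)*(1-at)*X_ft`,
  centered and rescaled to unit SD across responsive voxels so that `snr`
  means the same thing at every sharing level.
- Trial betas are `snr * pattern + N(0, 1)` per voxel.  `snr` defaults to
  0.5: single-trial beta estimates are noisy, and 0.5 puts default
  within-format decoding clearly above chance without saturating.

**Orthogonalized maps.** Independent tuning maps drawn over finitely many
voxels overlap by O(1/sqrt(V)), and because the tuning family is
low-dimensional a high-snr linear classifier can exploit that overlap,
leaving residual cross-condition decodability even at zero sharing.  Each
map's 4-class block is therefore projected off the span of all previously
drawn maps (leaving its internal class geometry intact), so "zero sharing"
means exactly zero linear cross-decodability of the noiseless patterns.
The projection needs more responsive voxels than the 36 class-pattern
rows; below that the maps are left raw and the guarantee is approximate.
Even with exact orthogonality, the accuracy of cross-decoding on any one
cohort couples with the training-set noise in the estimated class means,
so per-cohort cross-decoding accuracy at zero sharing is chance only in
expectation, with per-cohort spread that grows with snr.  Tests of the
zero-sharing contract therefore average over cohorts.

**Activation t-statistics.** Real pipelines select voxels on an
all-conditions-vs-baseline t-map from a GLM, which is out of scope here;
the generator emits a condition-blind signal-energy surrogate instead
(snr times the RMS of a voxel's noiseless cell patterns, plus measurement
noise shrinking with trial count).  Selection is therefore unbiased with
respect to numerosity, as in the emulated design.

**Individual differences.** Per-participant format-sharing values are
`clip(alpha_format + alpha_sd * z, 0.02, 0.98)` with `alpha_sd = 0.15`;
math standard scores are mean 100, SD 15, with a Gaussian latent
correlated at `brain_behavior_r` with the standardized sharing values.
Behavioral Weber fractions are drawn from N(0.23, 0.05) clipped to
[0.05, 0.60], matching the reported range of adult samples on this task
family (mean about 0.23, typical population mean about 0.25).

## Behavioral models

`P = RT(1 + 2 ER)`: the error rate uses all trials; the mean RT uses
correct trials only, after a single pass removing trials beyond ±3 sample
standard deviations of the participant's mean correct RT.  Whether the
original trimming iterated, and whether its SD included error trials, is
unstated; single-pass on correct trials is implemented and documented.

The Weber model predicts comparison error
`½ erfc(|n1−n2| / (√2 · w · √(n1² + n2²)))`.  Some sources print the
denominator as `√(n1² + n1²)`; the canonical form with both operands is
the default and a `printed_form` flag reproduces the variant for
comparison.  The fit minimizes squared error of observed proportion
correct against `1 − error` over w in [0.01, 2] (coarse 200-point grid,
then bounded scalar minimization to 10^-4), weighting pairs by trial
count.  All-perfect accuracy pins w at the lower bound with an
`at_boundary` flag rather than erroring.  A Bernoulli maximum-likelihood
objective is available as an option; least squares on percent correct is
the default because it is the form the emulated literature fits.

Math standard scores are squared before correlational analyses; the
transform report carries adjusted Fisher-Pearson skewness and Shapiro-Wilk
statistics for raw and squared scores.  Squaring is a variance-raising
transform that counteracts the negative skew typical of achievement
standard scores in unselected samples.

## Classification and inference

**LDA.** Pooled within-class covariance (denominator n − c) shrunk toward
its scaled identity, `(1−λ)S + λ(tr S/d)I`, with λ = 0.01 by default.  The
exact regularization constant used by the MVPA toolboxes this emulates is
unreported; 0.01 keeps the covariance positive-definite in the
more-voxels-than-trials regime while perturbing well-conditioned problems
minimally, and is configurable everywhere.  Priors are equal by default
(the design is balanced); training sets with unequal class counts are
rejected rather than reweighted.  Exact discriminant ties break toward
the lowest class label.

**Cross-validation.** Trials are grouped into chunks of one trial per
numerosity by within-class presentation order (the original chunk
assignment rule is unstated; presentation order is deterministic and
reproducible).  Leave-three-out over chunks uses all C(m, 3) combinations
when that is at most `max_folds` (default 2000), otherwise a seeded
uniform subsample without replacement; at the study's 40 chunks the
exhaustive count is 9880, so the default cap keeps desk-scale runs
tractable while `max_folds=None` preserves full fidelity.

**Permutation null.** Training labels are scrambled uniformly within the
training partition at each of 1000 iterations (the stratification of the
original scrambling is unstated); test labels stay intact for scoring.
The null mean's deviation from 25% is the bias summary.

**Group statistics.** One-sample t against 25% chance, two-tailed, with
Bonferroni multiplication by the 8 regions capped at 1, and Cohen's
d = (mean − 25%)/SD; paired t with d = mean(diff)/SD(diff).

**Distance/button model.** The mixed model with random intercepts and
slopes is approximated by per-participant ordinary least squares of
off-diagonal prediction rates (targets 4 and 6, compare-task button map
{2,4} vs {6,8}) on numerical distance and a shared-button indicator,
followed by a group one-sample t on each coefficient with df = n − 1,
matching the df the emulated analysis reports.  Note a generator-specific
caveat: tuning is log-spaced, so confusions fall with log distance; a
linear-distance regressor then leaves a residual that partially loads on
the button indicator (2-4 confusions exceed 6-8 confusions at equal
linear distance) even though the generator contains no motor component.

**Default correlation Bayes factors.** The two-sided BF10 integrates the
exact sampling density of the Pearson r (hypergeometric form) against a
stretched beta prior of width κ (default 1: uniform on (−1, 1)) via
adaptive quadrature; constant factors cancel in the likelihood ratio, and
the result depends on the data only through (r, n).  One-sided factors
truncate and renormalize the prior (truncation, not posterior-mass
correction — the alternative convention is noted as an open choice in the
emulated analysis).  An independent 200k-point trapezoid oracle bounds the
quadrature error at 10^-3 in the tests.  The Kendall-tau factor uses
parametric yoking: a normal approximation to tau-b's sampling distribution
with null variance 2(2n+5)/(9n(n−1)) and a prior induced from the
stretched beta through tau = (2/π) arcsin(ρ).  It is flagged approximate
and is not used for any printed-value check.  Spearman p-values use the
t approximation; one-sided p-values halve the two-sided value on the
observed side.

## Problem sizes

The default test suite and the acceptance script run at reduced sizes
chosen once as the package's desk-scale conditions: cohorts of 1-8
participants, regions of 60-200 voxels (half responsive), 3-20 trials per
cell, fold caps of 10-200, and 60-1000 permutation iterations; the Weber
and brain-behavior recovery studies use 500 replicates.  Reduced sizes
raise Monte-Carlo error, which the affected checks absorb by averaging
over seeds and testing medians; they do not change the generative
conditions (snr, sharing levels, Weber parameters) those checks assume.

## Limitations

- The generator emulates design-level structure only: no hemodynamics, no
  GLM estimation, no spatial autocorrelation between voxels, no dot-image
  visual-property congruency.  Passing tests demonstrate that the analysis
  chain is correct and calibrated under the stated generative model, not
  that any particular real dataset would yield the same group results.
- Voxel noise is white and unit-variance; real beta-series noise is
  heteroscedastic and spatially structured, which would lower decoding
  accuracy at a given nominal snr.
- The RT model (shifted lognormal with ratio-linear location) is a
  convenience; only positivity and difficulty-monotonicity are relied on.
- The distance/button group test is a fixed-effects approximation of the
  random-slope mixed model; with strong per-participant heteroscedasticity
  the two can diverge.
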