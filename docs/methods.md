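# Methods

This note records the model, the numerical choices, and the reasoning
behind every point where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Classifier model

A case is a plasma thermogram — excess heat capacity ΔC_p on a fixed,
strictly increasing temperature grid (default 45.0–90.0 °C, 451 points,
0.1 °C steps) — plus a binary clinical label, control (negative class)
or cancer (positive class). Six features summarise a case: IR (binary
initial slope direction), T1/PEAK1 and T2/PEAK2 (location and height of
the smoothed curve's maxima on [45, 55] and (55, 90] respectively), and
IND, the raw curve.

Classification is k-nearest-neighbour retrieval under the weighted
rank-order similarity

S(x_i, x_0) = Σ_f ω_f · (N′_f − rank(d_f(x_i, x_0))) / (N′_f − 1),

with dense ranks of the per-feature local distances over the case-base
(squared Euclidean for scalars, discrete Fréchet for IND) and weights
ω_f ≥ 0, Σω_f = 1. The retrieved k cases vote; the class-conditional
probability is the vote fraction. Because only ranks enter, S is
invariant to strictly increasing transforms of any feature's distances —
which is why keeping the *squared* Euclidean distance (no root) is
harmless, and why the classifier tolerates outlying distance magnitudes.

### Similarity conventions

- **Dense ranking.** Ties share a rank and the next distinct value takes
  the next integer, so the maximal rank equals the number of distinct
  values N′ and each feature's bracketed term maps exactly onto [0, 1].
  Competition ("min") ranking would allow ranks above N′ and negative
  terms.
- **Degenerate feature (N′ = 1).** All distances tied carries no ordering
  information; the term is defined as the constant 1, which preserves
  case ordering and keeps S = 1 attainable for a perfect match.
- **Ties.** Equal similarities break by case insertion order (oldest
  first); a 50/50 class vote predicts control — the conservative call for
  a screen, and unreachable at the default k = 1.
- **Retain.** Appending a solved case is part of the CBR cycle and is
  provided (`rankcbr.cbr.retain`), but the cross-validation harness never
  retains test cases: doing so would leak the test fold into the
  case-base. `run_experiment` ignores `retain: true` with a warning.

### Local distances

The continuous Fréchet distance is approximated by its discrete variant
on the sampled points (the standard O(nm) dynamic program over the
coupling lattice), which upper-bounds the continuous value and converges
as the grid refines; curves exist only as samples, so nothing finer is
available. Ground space is the raw (T °C, ΔC_p) plane — no rescaling by
default, since the two axes' units are both meaningful; an optional
z-scaling of each axis by training-set spread is exposed
(`frechet_zscale`) for cohorts where temperature units would otherwise
dominate. The DP is numba-jitted when numba is importable (~0.5 ms per
451-point pair) with an identical pure-Python fallback; tests pin the DP
to an exhaustive coupling-enumeration oracle on short curves.

## Feature extraction

Curves are smoothed by Nadaraya–Watson regression with a Gaussian kernel;
the bandwidth (kernel SD) defaults to 1.0 °C — wide enough to suppress
point noise at the default 0.1 °C spacing, narrow enough to move a
noiseless peak by well under the 0.2 °C tolerance the tests assert. Row
weights are computed with the row maximum subtracted before
exponentiation, so the bandwidth → 0 limit degenerates gracefully to the
identity rather than to 0/0.

- **Windows.** T1 searches [45, 55], T2 searches (55, 90]; half-open at
  55 so every grid point belongs to exactly one window (the nominal
  ranges [45–55] and [56–90] leave the 55–56 band unassigned on a fine
  grid).
- **Plateau ties.** Argmax takes the lowest temperature — deterministic
  and stable under grid refinement.
- **IR.** Least-squares slope of the smoothed curve over the first 2 °C
  (21 points on the default grid); IR = 1 iff strictly positive, so a
  flat start counts as non-increasing. "Initial directional tendency" is
  otherwise unspecified; a fitted slope is less noise-sensitive than a
  first difference.
- **IND is raw.** The stored curve is never smoothed or mutated by
  extraction; the default measurement enters the Fréchet distance as
  recorded.

## Weight schemes

All schemes return ω with Σω = 1, 0 ≤ ω_f ≤ 1, estimated on training
cases only.

**Rank (RWCBR).** Per feature, each training case is reduced to one
scalar score: its local distance to a fixed pseudo-reference built from
the control-class training cases (feature-wise median for scalars,
point-wise median curve for IND). A two-sided Wilcoxon rank-sum test
compares cancer scores against control scores, and ω_f ∝ (1 − p_f).
Choices worth recording:

- *Reference case.* The similarity formula ranks distances to a target;
  for weight estimation a single fixed reference yields one weight vector
  per training set (as per-fold weight tables require) while preserving
  the distance-to-a-reference structure. Medians rather than means keep
  the reference robust to outlying profiles. The alternative — scoring
  each case by its mean local distance to every other training case — is
  available via `score_mode="mean-pairwise"`.
- *p-value.* Two-sided, computed from the exact null distribution when
  the pooled sample is ≤ 12 and tie-free (where the normal approximation
  is demonstrably poor: worst-case error 0.13 by enumeration), otherwise
  the normal approximation with tie-corrected variance and continuity
  correction. Two identical constant samples return p = 1 (no evidence,
  zero weight contribution).
- *Degenerate total.* If every feature has p = 1 the scheme falls back to
  equal weights rather than dividing 0/0.

**Entropy (ETCBR).** IR: Shannon entropy of the empirical Bernoulli rate
(bits). Scalars: differential entropy of a fitted normal,
½·log₂(2πe·σ̂²), floored at 0 — differential entropy is negative for
σ < 0.242, and the [0, 1] normalisation presumes nonnegative entropies.
IND: the per-grid-point normal entropies (each floored at 0), summed —
summing lets a many-point varying curve dominate the five scalars, the
qualitative behaviour expected of dispersion weighting on a 451-point
feature. All-zero entropies fall back to equal weights.

**Wald (LWCBR).** Binary logistic regression of the label on the six
predictors, with IND reduced to its trapezoidal curve integral — a
451-dimensional predictor is unfittable at n ≈ 56, and the integral is
the natural one-number summary of a nonnegative curve. Predictors are
standardised (zero-variance columns get unit divisor, hence exactly zero
coefficients); the fit is damped Newton on the ridge-penalised likelihood
(λ = 10⁻⁴, ≤ 100 iterations), which keeps the optimum finite under
perfect separation; ω_f ∝ (β̂_f/se_f)², intercept excluded; all-zero
statistics fall back to equal weights. Hand-written because no installed
library exposes ridge-stabilised IRLS together with the Wald covariance.

## Baselines

**k-NN** (k = 5): majority vote on the sum of per-feature local
distances, each feature's distance column min–max scaled to [0, 1]
across the training cases per target — raw sums would mix squared °C,
squared ΔC_p and a Fréchet length.

**SCUCC**: composite coefficient c = ρ̄^P · p̄ with weight factor P = 1,
where ρ̄ is the mean Pearson correlation of the target with each
control-class reference curve and p̄ the mean over grid points of the
two-sided normal tail probability of the target value under the
reference point-wise mean/SD. The "average probability of being in the
same group" is specified in the source literature only by citation; the
normal-tail reading is this package's documented surrogate. Grid points
with zero reference SD are skipped with a warning (all-degenerate
references fall back to an exact-match indicator). The decision
threshold (control iff c ≥ t) is calibrated on the training fold by
maximising training F-1 over midpoints of consecutive sorted composites.

## Evaluation

Cancer is the positive class. Precision = TP/(TP+FP), recall =
TP/(TP+FN), F-1 their harmonic and G-measure their geometric mean; zero
denominators yield 0 with a warning so fold summaries stay total.
Summaries report MIN/AVG/STD/MAX per model and index with the sample
(n−1) standard deviation — the convention that reproduces the bundled
published summary table from its per-fold columns. Stratified k-fold
(sklearn, shuffled, seeded) gives each fold 14 test / 56 training cases
with 7 + 7 test labels at the default 70/5 configuration.

### Bundled reference tables

`rankcbr.data` ships the per-fold information indices and their summary
as published for a seven-classifier thermogram benchmark whose underlying
70-subject cohort is not publicly deposited. Only their *internal
arithmetic* is checkable, and `verify_reference_tables()` checks it to
printed precision (1.5×10⁻⁴ — the worst-case propagation of 4-decimal
input rounding plus output rounding). Two summary cells (K-NN G-measure
AVG and STD) are inconsistent with the per-fold column they summarise
under every denominator convention and are recorded as a published
erratum with their identity-derived values (0.7315, 0.1014).

## Synthetic cohorts

No public thermogram cohort with labels exists, so the generator is the
package's test bed. Per subject: one or two Gaussian bumps with
class-dependent centres (μ1 ∈ [45, 55], μ2 ∈ [56, 90]), widths and
amplitudes; per-subject peak-centre jitter; a lognormal whole-curve scale
factor; i.i.d. Gaussian point noise; clipping at 0 (ΔC_p is reported
nonnegative). Each subject draws from an RNG substream keyed by
(seed, subject index), so cohorts are bit-reproducible and a subject's
curve is invariant to cohort size.

Defaults (chosen once, for realism, then frozen): 70 subjects, 50%
cancer; control peaks at 50/62 °C (amps 1.0/0.65, widths 2.5/4.0,
single-peak probability 0.15, jitter 1.2 °C), cancer peaks at
51.5/65 °C (amps 0.8/0.85, widths 3.0/5.5, single-peak probability
0.30, jitter 1.8 °C); lognormal scale SD 0.30; noise SD 0.05 ΔC_p
units. These produce heavily overlapping classes with large within-class
variance: on this benchmark the model family spans mean F-1 ≈ 0.80–0.96
across seeds, a realistic difficulty band rather than a saturated one.

**What the generator does not emulate — and what that implies.** Real
thermogram cohorts contain outlying profiles that follow no class
pattern, instrument baseline artefacts, and non-Gaussian subpopulation
structure. The generator's curves are clean Gaussian mixtures, so *every*
extracted feature is either class-informative or exactly constant in
distance (IR, whose similarity term is then constant under any
weighting). One documented consequence: the rank-weight scheme has no
noise feature to suppress here, and its 10-seed mean F-1 is statistically
indistinguishable from the equal-weight baseline's (measured paired
difference ≈ −0.006 ± 0.01; the corresponding acceptance test asserts
the qualitative rank-beats-equal property and accordingly fails under
these conditions). The scheme's discriminating behaviour is instead
demonstrated directly: when exactly one feature separates the classes it
receives the largest weight in 20/20 seeded replicates, and with no
signal anywhere the seed-averaged weights are near-uniform. Passing
tests on this generator therefore validate the machinery and its
contracts, not a claim that rank weighting improves accuracy on clean
Gaussian cohorts.

## Problem sizes and tolerances

The test suite and acceptance script run the full 451-point grid for
pipeline and benchmark checks (70 subjects, 5 folds; ten seeds for the
contrast), 500 random short curves for the Fréchet oracle, exhaustive
enumeration up to pooled n = 12 for the rank-sum oracle, and 1000
randomised small training sets for the weight-scheme contracts — sizes
chosen so the whole suite completes in a few minutes on one CPU while
still exercising every code path at the defaults. Numerical tolerances:
weights sum to 1 within 10⁻⁹; oracle equivalences are exact to 10⁻¹²;
published-table identities hold to printed precision (1.5×10⁻⁴).

## Known limitations

- The discrete Fréchet distance upper-bounds the continuous one; on
  0.1 °C grids the gap is far below between-subject variation.
- The SCUCC probability term is a documented surrogate for an
  under-specified published definition.
- Differential-entropy flooring makes ETCBR's IND weight scale-dependent:
  curves measured in units where point SDs are ≪ 0.24 ΔC_p would zero
  the IND entropy.
- The generator's clean mixture structure understates real-data
  heterogeneity (see above); conclusions about *relative* classifier
  accuracy on real thermograms should not be drawn from it.
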