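# Methods and numerical conventions

This note records the statistical model, the conventions the package
commits to where the underlying methods admit variants, and the known
limitations. Everything here is implemented in `src/equilat/` and
exercised by the test suite.

## Data model

A *focal record* is a horse with an ordered sequence of gallop lead
observations (L/R), one per race start; starts are treated as exchangeable
Bernoulli trials with a horse-specific right-lead probability θ. A *race
start table* is one observation per (race, horse): course direction
(clockwise C / anti-clockwise AC), stall position, age, sex, finish
position and the lead at a fixed observation point. Integrity checks
reject duplicate stalls within a race and mixed directions within a race.

## Laterality index and per-horse tests

`LI = 100 (nR − nL) / (nR + nL)`. The per-horse null is θ = 0.5, tested
two-sided at α = 0.05 (significance at p ≤ α inclusive).

**Method rule.** Exact binomial when n ≤ 25, normal approximation
otherwise. The exact two-sided p is the doubled smaller tail,
`min(1, 2·min(P[X ≤ k], P[X ≥ k]))` — the convention that matches the
published per-horse values; it is verified against brute-force tail
enumeration for all n ≤ 30. The z statistic is always reported from the
normal formula `(p̂ − 0.5)/√(0.25/n)` even for exact-test rows, because
that is what the source tables print. The normal test's 95% interval is
Wald, `p̂ ± 1.96 √(p̂(1−p̂)/n)`, without continuity correction.

**Classification.** S(R)/S(L) when significant, R/L trends otherwise,
AMBI when nR = nL exactly. Group medians of LI use the standard midpoint
convention and exclude ambilateral horses from both sign groups.

## Population tests and associations

One-proportion z tests of the right-lead count against p₀ = 0.5 over any
filtered subset of starts (per direction, winners only, ...), plus the
descriptive L:R ratio. Associations of lead with categorical covariates
use binary logistic regression (statsmodels `Logit`, Newton, tol 1e-8)
with dummy coding against a reference level; the test statistic is the
likelihood-ratio chi-square against the intercept-only model, which for a
single two-level predictor coincides with the 2×2 G statistic (tested to
1e-6). Predictor levels with fewer than two observations are dropped with
a logged warning; perfect separation raises `SeparationError` rather than
returning divergent coefficients. One-way ANOVA of LI on sex groupings
uses the standard between/within decomposition; with two groups F equals
the pooled t squared (tested).

## Bimodality of the LI distribution

The right-biased (LI > 0) and left-biased (LI < 0) horses are treated as
the two components of an equal-weight two-normal mixture with moments
(μ1, σ1) and (μ2, σ2). The distribution is declared bimodal when

    S(σ1/σ2) · (σ1 + σ2) < μ1 − μ2

where S(r) is the smallest mean separation, in units of σ1 + σ2, at which
an equal-weight two-normal mixture with σ-ratio r acquires a second mode;
S(1) = 1 recovers the classical two-standard-deviations threshold.

The factor table is **digitized from the defining computation**, not
copied: for each σ-ratio on the grid 0.05–1.00 (step 0.05) the critical
separation is found by bisection on the number of modes of the mixture
density. S is scale-symmetric (S(r) = S(1/r)), so ratios above 1 are
inverted before lookup, and intermediate ratios are linearly interpolated.
Ratios below 0.05 raise rather than extrapolate. The test suite checks
each tabulated factor against an independent mode-counting oracle. Equal
mixture weights are an approximation for near-equal group sizes (22 vs 21
in the shipped cohort).

## Strength comparisons (|LI|)

Two-sample comparisons of |LI| (degree, not direction, of laterality) use
a variance-pretested t test:

- **Pretest.** Bonett's robust log-variance test with a pooled kurtosis
  estimate about trimmed means (trim proportion `1/(2√(n−4))`), omitting
  the small-sample c(α) interval correction so the p-value is closed-form.
  With both samples ≥ 20 the Bonett p is used alone; below that, the
  smaller of the Bonett p and the median-centered Levene
  (Brown–Forsythe) p — a conservative small-sample compromise.
- **Test.** Pooled t when the pretest p ≥ 0.05, Welch otherwise. The
  Welch–Satterthwaite df is *truncated* to an integer and the p-value is
  evaluated at that integer df, matching how the comparisons this package
  reproduces were reported.

## Normality, Johnson transformation, one-sample t

Anderson–Darling with estimated mean and variance (case 3): raw A² is
reported (affine invariant, agrees with scipy to 1e-8); the p-value uses
the modification `A* = A²(1 + 0.75/n + 2.25/n²)` and the standard
piecewise approximation formulas.

When LI fails normality, a Johnson transformation is selected by the
percentile method: for each selection constant z on the grid 0.25–1.25
(step 0.01), the four sample quantiles at Φ(±z), Φ(±3z) (Weibull
plotting positions) determine the family by the quantile ratio mn/p²
(SU above 1, SB below, SL within 1e-4 of 1) and the closed-form
parameters; the candidate whose transformed sample attains the highest
Anderson–Darling p wins, and the identity is returned if the raw sample
already scores at least as well. All fitted transformations are strictly
increasing, so ranks are preserved. The population-level hypothesis
"mean transformed LI = 0" then uses an ordinary one-sample t.

## Design numbers

Two-sided one-proportion z-test sample size, no continuity correction:

    n = ⌈(z_{1−α/2}√(p₀q₀) + z_{power}√(p₁q₁))² / (p₁ − p₀)²⌉

(1225 for p₀ = 0.5, p₁ = 0.54, α = 0.05, power 0.8). The companion power
function includes both rejection tails, so power at p₁ = p₀ equals α and
is inverse-consistent with the sample-size formula.

Inter-observer reliability uses Cronbach's alpha over an items × raters
matrix, `α = k/(k−1)·(1 − Σ rater variances / var of rater sums)` with
n−1 denominators; binary L/R scores are coded 0/1.

## Synthetic cohorts

Each simulated horse draws a latent class (left-biased, right-biased,
ambilateral with probabilities π_L, π_R, π_A) and, for biased horses, a
bias magnitude B ~ Beta(a, b), giving θ = 0.5 ± 0.5B; ambilateral horses
have θ = 0.5 exactly. `bias_shape_b = 0` denotes the degenerate limit
B = 1 (fully lateralized). Leads are conditionally independent
Bernoulli(θ) draws — exactly the exchangeability assumption the analysis
makes, so the generator is the matched null/alternative for calibrating
it. Race-start tables add alternating course directions, stall layouts,
ages, sexes, one winner per race and an optional log-odds shift of θ on
clockwise starts.

Randomness flows from a single seed through per-horse spawned streams
(`SeedSequence((seed, index))`; race-level streams occupy a disjoint
index block), so enlarging a cohort never perturbs already-drawn horses
and every run is reproducible from its config, which serializes to YAML.

## Known limitations and documented source discrepancies

- The shipped anti-clockwise start counts cannot be recovered: the
  published pooled and clockwise counts imply an AC split that contradicts
  the published AC ratio and z. The AC-direction test and the published
  logistic-regression outputs are therefore documented as irreproducible
  rather than matched.
- A handful of per-horse printed values are misprints (one z digit
  transposition, one p off by 0.01, one 0.01 LI rounding slip); the
  package computes from the raw sequences and the reproduction run flags
  the differences.
- Printed per-sex bimodality rows are internally inconsistent with their
  own σ-ratios; only the all-horses row is numerically matched.
- The mixture-bimodality criterion assumes within-group normality and
  equal weights; it is a screening heuristic, not a formal test.
- No multiple-testing correction is applied anywhere, matching the
  original analysis; interpret the many per-horse tests accordingly.
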