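# Methods

## The inferential chain

The package answers "what fraction of the population experiences this
within-subject effect?" in three stages: per-subject counting, per-subject
exact testing, and population-level Bayesian aggregation. Each stage
operates only on the outputs of the previous one, so the chain can be
entered at any point (e.g. directly from a published significance count).

### Per-subject summaries and tests

A subject's evidence is the pair (k, n): two-target reports out of
experimental trials, overall or within a condition level. The null is
that two-target reports arise only from task error, at the group's pooled
error rate p₀:

- **commission baseline** (designs with catch trials): p₀ = total
  reports of ≥1 target on catch trials / total catch trials, pooled over
  subjects. Counting any non-zero report as a commission follows the
  logic that reporting *a* dot where none was flashed is the relevant
  error process; a stricter two-target-only variant is available
  (`commission_counts="two_only"`).
- **omission baseline** (designs without catch trials): p₀ = total
  zero-reports on experimental trials / total experimental trials.

Pooling is trial-weighted (total errors over total trials) rather than a
mean of subject rates; the two coincide for balanced designs, and the
unweighted variant is exposed (`rate_method="mean_of_rates"`). The test
is the exact upper tail P(X ≥ k) for X ~ Binomial(n, p₀); subjects with
p < α (default 0.05) are flagged. Per-level tests reuse the overall
pooled baseline, under the assumption that the error process does not
depend on the condition. If p₀ = 0 (no errors observed anywhere), the
p-value is taken at its limit — 0 for k > 0, with a warning, since the
baseline was evidently not estimable — and 1 for k = 0.

**Calibration caveat.** The exact binomial test is conservative by
discreteness: its attained size is below the nominal α. Under the
package's own null simulations (45 subjects × 288 experimental trials,
common commission rate 0.03, baseline estimated from 45 × 72 catch
trials), the per-subject flag rate is ≈ 0.044 rather than 0.050; with
the baseline known exactly it would be ≈ 0.029 — the estimation noise in
p₀ partially smooths the discreteness. Downstream this mild conservatism
slightly *understates* θ for a given γ, so prevalence MAPs are, if
anything, slightly conservative and HPDI coverage slightly above
nominal.

A second, sharper caveat: the pooled-baseline null presumes exchangeable
subjects. If true error rates vary across subjects (and non-perceivers'
two-target reports track their own error rate), subjects above the
pooled mean are *genuinely* above the baseline, and the flag rate under
γ = 0 can far exceed α (≈ 0.21 under a beta spread matching a
between-subject SD of 4.5 percentage points around a 3.3% mean). That is
a property of the pooled-baseline design, not a software artifact; the
per-participant baseline option (`pooling="per_participant"`) removes it
at the cost of a noisier null.

### The prevalence posterior

Let k of n subjects be flagged. Both supported models place a uniform
prior on the prevalence γ ∈ [0, 1]:

- **simple_beta** — treats the flags as a direct binomial sample of γ:
  posterior Beta(1 + k, 1 + n − k). Mode (α−1)/(α+β−2) = k/n, with the
  boundary conventions mode 0 at k = 0 and 1 at k = n.
- **test_calibrated** (default) — recognizes that a flag occurs with
  probability θ(γ) = α_fp + (1 − α_fp)·γ where α_fp is the per-test
  false-positive rate: effect-free subjects are flagged at rate α_fp,
  subjects with the effect are assumed flagged with certainty (per-test
  power ≈ 1, reasonable at hundreds of trials per subject). The
  posterior ∝ θᵏ(1 − θ)ⁿ⁻ᵏ; MAP = clip((k/n − α_fp)/(1 − α_fp), 0, 1).

The default α_fp equals the per-test α, 0.05. Note the asymmetry of the
model: it corrects for false positives but not for false negatives, so
with weak per-subject power it is a lower bound on γ.

Internally both posteriors are one object: a Beta(k+1, n−k+1) density on
θ truncated to [α_fp, 1], mapped linearly to γ — at α_fp = 0 this *is*
the simple model, which the tests assert pointwise. Normalization uses
the regularized incomplete beta function (the truncated-beta survival
mass), so densities, CDFs and quantiles are closed-form up to scipy's
special functions, with no quadrature in the hot path.

### HPDI computation

The highest-posterior-density interval is found by bisecting on a
horizontal density threshold: for a candidate threshold the two crossing
points are located by Brent root-finding on either side of the mode
(an endpoint clamps to 0 or 1 where the density is monotone there), the
enclosed mass is read off the closed-form CDF, and the threshold is
bisected until the mass matches the request. 100 bisection steps with a
relative stop of 1e-10 put the mass error far below the 0.002 the tests
assert. The interval is computed on the γ scale; because the γ↔θ map is
linear, this coincides with the transformed truncated-beta HPD on θ,
which the test suite uses as an independent grid-accumulation oracle.
Degenerate cases: k = 0 (or a MAP clamped at 0) yields [0, q] with q the
`mass`-quantile; k = n symmetrically yields [q', 1].

Reported values round to 2 decimals, the field's reporting precision;
full precision is always kept on the estimate objects.

### Group statistics

Implemented directly from their definitions (and cross-checked in the
tests against independent scipy routines): Welch's t with
Welch–Satterthwaite df, accepting either raw values or published
(M, SD, n) triples so printed comparisons can be recomputed; OLS
regression of per-(subject, condition-value) mean percentages on the
condition value, reported as R² and F(1, N−2); one-way ANOVA on
per-(subject, block) means via the between/within sum-of-squares
decomposition; and Bayes factors by the BIC approximation
BF₁₀ = exp((BIC₀ − BIC₁)/2), always labelled "BIC approximation" —
a coarse unit-information-prior surrogate, suitable for order-of-
magnitude statements about null effects, not for fine evidence grading.

The unit of analysis for regressions and ANOVAs is the subject-by-level
mean percentage (levels sharing a factor value are first averaged within
subject), which is what the printed degrees of freedom of such studies
imply (e.g. 405 subject×speed points → F(1, 403); 255 subject×block
means → F(2, 252)). The between-experiment comparison is an unpaired
Welch test even when the same subjects did both tasks, matching reported
df of that form.

## The synthetic-observer model

What it emulates: a mixture of perceivers (fraction γ) and
non-perceivers; perceiver report-2 probability follows a logistic link
in the primary condition value (increasing in speed, weakly increasing
in opacity — matching the observed positive regressions); non-perceivers
report two targets at their own commission-style rate; per-subject
commission and omission rates are beta-distributed with set mean and SD;
responses are independent across trials with exact per-design trial
counts and randomized order.

Defaults are illustrative operating points chosen to resemble the
published group-level rates, not fitted estimates: γ = 0.5, commission
mean 3.27% (the published pooled catch-trial error), omission mean
1.24%, zero between-subject spread, and link coefficients (−2.8, 0.07/°s
for speed; −2.0, 0.01/% for opacity) that put overall illusion-report
rates near 10–12%. Spread parameters should be raised to match observed
subject-level dispersion when that matters (see the calibration caveat
above for the consequence under γ = 0).

What it does not model: sequential dependence, learning or fatigue,
response bias shifts between blocks, attention effects (the default
generator makes attention blocks exchangeable, consistent with the null
ANOVA result such designs produced), and any psychophysical mechanism of
the illusion itself. Passing recovery tests therefore show that the
estimator chain is correct *under its own assumptions*, not that real
data meet them.

Two samplers share the generative law: the trial-level sampler (exact
layout, randomized order, CSV interchange) and a count-level sampler
drawing the per-cell binomial/multinomial counts directly. The
equivalence is by construction (independent trials) and checked by
moment tests; Monte-Carlo studies (calibration over 500 null studies,
recovery over 100, coverage over 300, study size 45 × 360) use the count
path so the suite stays fast.

## Numerical and design choices

- Error-rate beta distributions are parameterized by (mean m, SD s) via
  ν = m(1−m)/s² − 1; s = 0 degenerates to the constant m; s² ≥ m(1−m)
  is rejected at validation.
- A perceiver's omission rate is capped at 1 − max p_report2 so the
  per-trial outcome probabilities stay a proper simplex.
- Commission errors on catch trials default to one-dot reports
  (uncertain observers default to "one"); the two-dot share is a
  parameter.
- Seeds: population draw and trial draw use separate streams derived
  from the run seed, so the same subjects can be re-run with fresh
  trial noise.
- Constant-y regression returns R² = 0, F = 0, p = 1 (nothing to
  explain) rather than the 0/0 indeterminate.
- Prevalence with n = 0 subjects is an error, not a flat posterior.

## Known limitations

- The test-calibrated model assumes per-subject power 1; prevalence is
  underestimated when subjects with weak effects fail their individual
  tests. No hierarchical or covariate-dependent prevalence model is
  provided, and only the uniform prior is supported.
- The simple-beta model's verbal "add one" recipe gives a mode of k/n,
  which differs from the calibrated MAP whenever α_fp > 0; for k = 0 its
  mode is exactly 0 while its *mean* is 1/(n + 2) ≈ 0.02 at n = 45 —
  summaries near a boundary should say which statistic they quote.
- The Bayes factors are BIC approximations and are not comparable to
  default-prior Bayes factors from dedicated tools beyond their order of
  magnitude.
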