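# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical conventions that make results bit-reproducible.

## Synthetic cohort model

The generator produces the data-generating process the analysis assumes,
not a forgery of any particular dataset.

**Demographics.** Age and education are normal per group (education clipped
to [5, 25] years); sex is Bernoulli. Defaults are the published group means,
SDs, sizes, and sex ratios (e.g. C9orf72: n = 69, age 55 (12.0), education
13.7 (3.1), 30 F : 39 M; controls: n = 275, age 45.8 (12.7)). Test language
is categorical (en/nl/es/fr at 0.4/0.2/0.2/0.2) — a simplification of the
many-site reality that suffices to exercise language-offset estimation.

**Latent deficits.** Each participant has a latent z-deficit vector over
the 19-test battery, drawn from a multivariate normal. Controls have mean 0
and unit SD. Carriers have per-test means and marginal SDs taken from the
packaged per-gene deficit table (e.g. C9orf72 FCSRT free recall −1.68,
SD 1.36). Correlation is block-exchangeable: 0.5 within a cognitive domain,
0.2 between domains — typical neuropsychological battery intercorrelations;
no published covariance exists for these data, so this default is a modeling
choice and is fully configurable. Validity (positive semi-definiteness) is
checked at configuration time.

**CDR stage gradient.** Carrier stages are drawn from a configurable
distribution over {0.5, 1, 2, 3} (default 0.45/0.25/0.20/0.10, a plausible
mix for a cohort enrolled at CDR ≥ 0.5). Deficit means are scaled by
stage-severity multipliers (0.5/1.0/1.6/2.1), *normalized so that their
mean under the stage distribution is exactly 1*: the marginal per-gene
means therefore still equal the configured table, while prodromal (CDR 0.5)
carriers are milder than symptomatic ones. This gradient is what gives the
sample-size stage contrast μ₀.₅ ≠ μ₁ a non-degenerate value; without it the
effect-size convention would be undefined. Within-stage SDs are shrunk so
the marginal SDs also match the table (floored at 0.1× the marginal SD
when the between-stage variance would exceed the marginal variance).

**Raw scores.** Controls' raw scores follow a linear demographic model per
test: intercept and residual scale set to plausible raw-score units (e.g.
TMT-B: 80 s ± 30), slopes proportional to the residual scale (performance
declines 0.02 SD/year of age, improves 0.06 SD/year of education, small
sex effect; signs flipped for timed tests, which live on a "higher raw =
slower = worse" scale). Language-dependent tests carry per-language
intercept offsets (±0.25 SD). Raw scores are produced by *inverting* the
normative transform — raw = prediction ± scale × z — so the scoring stage
has true parameters and true latent deficits to recover; round-trip
recovery is a tested invariant. Missingness is completely at random at 2%
per cell by default (the analysis handles missingness by complete-case
exclusion, so only the rate matters; 2% keeps the complete-case fraction
near 68% over 19 tests, proportionate to a well-run multicentre battery).

**Conversion histories.** Prodromal carriers get a latent conversion time
from a piecewise-constant annual hazard via inverse-transform sampling.
Default rates over years (0,1], (1,2], (2,3] are λ₁ = λ₂ = 0.11786115,
λ₃ = 0.49824691, derived in closed form so that the cumulative conversion
probability is 21% at 2 years and 52% at 3 years; the constants are
committed, not re-fit at run time. Visits occur on a fixed grid (default
annual for 3 years); a converter's first CDR ≥ 1 observation falls at the
first scheduled visit at or after the latent time, which preserves the
latent CDF exactly at grid points. Per-visit dropout (default 10%) censors
all later visits; because censoring is independent of the event process,
Kaplan–Meier estimates remain unbiased.

**What is not emulated:** family structure, site effects, practice effects,
item-level responses, informative missingness, informative censoring, and
biomarkers. Tests passing on this cohort therefore demonstrate correctness
of the *procedures* under the assumed data-generating process, not clinical
validity on real cohorts.

## Normative scoring

One OLS regression per test over the controls: raw ~ intercept + age +
education + sex (F = 0, M = 1), plus categorical language intercept offsets
(reference level = alphabetically first) for language-dependent tests only —
the smallest model consistent with standard regression-based norming.
z = (raw − prediction) / residual SD, where the residual SD uses the
unbiased n − p denominator; timed-test z-scores are multiplied by −1.
Extreme z-values are propagated untruncated. Fits require at least 20
usable controls per test (configurable) and reject degenerate fits with
numerically zero residual variance. Whether stratified means or regression
residuals is the "correct" correction is unobservable from the available
description; regression-based norms are the standard neuropsychology choice
and recover the generator's truth.

## Composite derivation

Complete cases only. Predictors are standardized once on the analysis
sample (the glmnet convention); coefficients are reported back on the
z-score scale. The penalty grid is 100 log-spaced values from the analytic
all-zero bound λ_max = maxⱼ |⟨xⱼ, y − ȳ⟩|/n down four decades. Fold
assignment is stratified by carrier status with a recorded seed. The
default selection rule is minimum mean cross-validated binomial deviance;
the one-SE rule is available (`lambda_rule="1se"`). Because fold seeds are
not knowable for the original analysis, exact coefficient reproduction is
out of scope; the published coefficients and weights ship as a frozen JSON
fixture for *applying* the composites.

Selection takes exactly the tests with strictly negative coefficients
(carriers worse than controls); positive-coefficient tests are excluded by
design. Coefficients below 1e-8 in magnitude count as zero. Weighted-mode
weights are |βᵢ|/Σ|βⱼ| at full precision (rounding only at presentation);
average mode uses 1/k. Missing included tests make the composite missing by
default; an explicit `renormalize` policy re-scales weights over available
tests and flags the output column.

The L1 solver is liblinear (C = 1/(nλ), tolerance 1e-8, fixed internal
permutation seed for bit-reproducibility). An independent unpenalized
logistic solver is used in the tests as an oracle at negligible penalty —
never as the implementation.

## Sample size

Direct evaluation of n = (1 − ρ²)(2σ²)/δ² · f(α, β) with
f(α, β) = (z₁₋α/₂ + z₁₋β)². δ = effect size × |μ₀.₅ − μ₁|, with μ and σ
estimated from whichever outcome column is supplied (individual test z or
composite) — no re-standardization happens inside this module. ρ defaults
to 0.5, a typical baseline–follow-up correlation for cognitive measures;
outcome-specific values were not derivable and should be supplied when
known. Rounding is ceiling (conservative trial-planning convention), so
integer per-arm sizes are upper bounds on the unrounded formula. Equal
stage means raise an explicit infinite-n error; a zero prodromal SD is
flagged degenerate. The conversion adjustment multiplies the planned effect
size by the expected conversion probability before the formula is applied
(20% planned × 0.5 conversion ⇒ powered as 10%).

## Survival analysis

Eligibility: baseline visit at CDR 0.5 with at least one follow-up. Event
time = first visit with CDR ≥ 1 (interval censoring ignored — the visit-
based convention); otherwise censored at the last visit. The Kaplan–Meier
product-limit estimator is computed directly over distinct event times with
Greenwood variance; 95% bounds use the log(−log) transform so they stay in
[0, 1] (the original CI method is unstated, so CIs are descriptive, not a
comparison target). All-censored inputs return a flat curve with a warning.
The k-group log-rank test (hypergeometric variance at ties, df = k − 1)
delegates to lifelines and is verified in tests against an explicit
observed-minus-expected hand computation and a 2,000-replicate null
calibration (uniform p-values, ~5% type-I error).

## Problem sizes used in verification

Stochastic checks use sizes chosen to make Monte-Carlo error small relative
to the tolerances: 5,000 participants for profile/slope recovery (3·SE
bands), ≥ 20,000 histories for the 21%/52% conversion milestones (±1.5
percentage points), 20 seeds × 2,000 participants for selection recovery
(≥ 90% success), and 2,000 replicates for log-rank null calibration.

## Known limitations

- Correlation structure, stage mix, stage-severity gradient, raw-score
  scales, and ρ are modeling choices where no published values exist; all
  are configurable, and conclusions that depend on them (e.g. composite vs
  single-test sample sizes) are qualitative.
- Exact reproduction of the published LASSO coefficients, sample-size table
  cells, and per-gene KM percentages would require the restricted
  individual-level data; the package instead reproduces every quantity that
  is derivable from printed inputs and verifies the rest by construction.
- No elastic-net or grouped penalties, no longitudinal composite
  derivation, no Cox or covariate-adjusted survival modeling.
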