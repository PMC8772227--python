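# ftdcog

Cognitive composite endpoints for clinical trials in genetic frontotemporal
dementia (FTD).

Carriers of pathogenic *C9orf72*, *GRN*, or *MAPT* variants progress from an
asymptomatic stage through a prodromal stage (CDR® plus NACC FTLD global
score 0.5) to fully symptomatic disease (global score ≥ 1). Upcoming
prevention trials need cognitive outcome measures that are sensitive in the
prodromal window, where single neuropsychological tests are noisy. This
package implements, end to end, the derivation and evaluation of
**gene-specific cognitive composite scores** ("GENFI-Cog"-style endpoints)
from a multi-domain neuropsychological battery:

1. **Synthetic cohort generation** — carriers and mutation-negative family
   controls with configurable demographic structure, per-gene z-score
   deficit profiles, correlated test scores, missing data, CDR stage mix,
   and longitudinal conversion histories under a piecewise-constant annual
   hazard. This makes every downstream stage testable without access to
   restricted patient-level data.
2. **Normative z-scoring** — per-test ordinary least squares regression of
   raw scores on age, education, and sex over the controls; z = residual /
   control residual SD, with per-language intercept offsets for tests whose
   stimuli differ across languages (FCSRT, letter fluency) and sign
   inversion for timed tests (TMT, D-KEFS CWIT), so lower z = worse on
   every measure.
3. **Composite derivation** — per gene, an L1-penalized (LASSO) logistic
   regression of carrier status on the battery z-scores with stratified
   10-fold cross-validation; the penalty λ minimizes mean cross-validated
   binomial deviance. Tests with negative coefficients form the composite;
   weights are wᵢ = |βᵢ| / Σⱼ|βⱼ| (the unweighted average is also built).
   The published composite definitions ship as a frozen fixture and can be
   applied to any z-score table.
4. **Trial sample size** — per-arm size for a two-arm 1:1 trial on a change
   score: n = (1 − ρ²)(2σ²)/δ² · f(α, β), with f(α, β) =
   (z₁₋α/₂ + z₁₋β)², σ the outcome SD in the CDR 0.5 group, and
   δ = effect size × |μ₀.₅ − μ₁| (a 100% effect equals the CDR 0.5 → 1
   stage difference). A conversion-probability adjustment dilutes the
   planned effect when only part of the trial population is expected to
   progress.
5. **Time-to-conversion analysis** — Kaplan–Meier product-limit estimation
   (Greenwood variance, log(−log) confidence bounds) of progression from
   CDR 0.5 to ≥ 1, and the k-group log-rank test across genes.

## Worked example

Run the full pipeline on a simulated cohort with the default configuration
(69/41/28 carriers, 275 controls — the published group sizes):

```bash
ftdcog run --seed 7 --out run/
```

This writes `cohort.csv`, `visits.csv`, `zscores.csv`, `coefficients.csv`,
`composites.csv`, `sample_sizes.csv`, `km_curves.csv`, and `report.json`
under `run/`, and prints the report:

```json
{
 "config_hash": "cf3d675b42d41693",
 "km_conversion_2y": 0.1978260869565217,
 "km_conversion_3y": 0.6103726708074533,
 "logrank": {"df": 2, "p_value": 0.1186..., "statistic": 4.2639...},
 "n_histories": 53,
 "n_participants": 413,
 "seed": 7
}
```

Reading the report: of the 53 prodromal carriers with follow-up, an
estimated 20% converted to CDR ≥ 1 by year 2 and 61% by year 3 (at this
small sample size the Kaplan–Meier estimate is noisy around its calibrated
21%/52% targets), and the log-rank test finds no significant difference in
progression between the three genetic groups (χ²(2) = 4.26, p = 0.12).

The C9orf72 block of `sample_sizes.csv` from the same run (per-arm sizes at
10/20/40% effect sizes, ρ = 0.5):

| outcome              | ES 10%  | ES 20% | ES 40% |
|----------------------|--------:|-------:|-------:|
| fcsrt_free           |     981 |    246 |     62 |
| cwit_ink             |  16,563 |  4,141 |  1,036 |
| digit_span_forward   | 117,075 | 29,269 |  7,318 |
| weighted composite   |   2,457 |    615 |    154 |
| average composite    |   2,068 |    517 |    130 |

The composites require far fewer participants than most individual tests
(compare digit span forward), illustrating the rationale for composite
endpoints; halving the effect size quadruples the required n.

To apply the published composite definitions to your own z-score table
instead of refitting:

```bash
ftdcog zscore --cohort run/cohort.csv --out z.csv
ftdcog apply --zscores z.csv --out composites.csv
```

Library use mirrors the CLI: see `ftdcog.generate_cohort`,
`ftdcog.fit_normative_models` / `compute_z`, `ftdcog.fit_penalized_logistic`
/ `derive_weights` / `compute_composite`, `ftdcog.sample_size`, and
`ftdcog.km_estimate` / `logrank_test`. Model and procedure details are in
`docs/methods.md`.

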