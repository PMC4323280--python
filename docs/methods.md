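# Methods

This note documents the models, rules and numerical choices behind the
package, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scoring model

### Instrument scoring

Every battery instrument is declared as a schema (items, per-item response
bounds, reverse-coded subset, subscale partition) and scored the same way:
reverse-coded items are reflected (`v ↦ min + max − v`), then items are
summed per subscale and overall. Reflection maps the response interval onto
itself, so the attainable total bounds are `n·min` to `n·max` regardless of
the reverse set — that is the analytic basis of the score-range checks
(PSS-14 0–56, ESI 0–60, HSCL-25 anxiety 10–40 / depression 15–60, SCL-90-R
somatization 0–48, PDS severity 0–51, PSS-4 0–16).

Built-in schema choices that the source instruments do not pin down, and
which are therefore shipped as overridable JSON defaults:

- **PSS-14 reverse set** — the standard published positive-item set
  (items 4, 5, 6, 7, 9, 10, 13).
- **PSS-4 embedded items** — the standard 4-item short form with its second
  and third items reverse-coded.
- **CFV subscale lengths** — not standardized across translations; the
  defaults (binary items: physical 9, verbal-emotional 4, witnessed 3,
  sexual 2, neglect 2) are chosen so each subscale's attainable maximum is
  at least the maximum observed in validation cohorts. They are explicitly
  non-authoritative.
- **PDS** — Part 1 is scored as a count of endorsed event types (0–12) and
  Part 3 as symptom severity (0–51); criterion-A2 and functional-
  interference parts are recorded but unscored because no composite uses
  them. No DSM diagnostic algorithm is implemented: the tool is a screen,
  not a diagnostic instrument.

### Risk recoding

The 31 indicators partition into 11 areas with item counts
(1, 2, 1, 2, 3, 5, 1, 2, 4, 6, 4). All cutoffs are fixed constants, not
sample quantiles: the bonding quartile cuts (joy 0–3, worries 7–10) and the
PSS-4 cut (≥ 12) are recode rules of the instrument itself. Two
rule-sheet decisions:

- **Housing index**: a ratio of exactly 0.5 *counts* as risk (≤ 0.5); a
  strict-comparator option exists because the instrument's prose and its
  rule table disagree. The comparison is done in exact integer arithmetic
  (`rooms·q ≤ persons·p`), never in floats.
- **Sum score**: all 31 indicators enter the sum. The 28-item subset exists
  only inside the reliability analysis, where constant indicators are
  excluded because they carry no covariance information; in the cohorts
  studied, "single parent", maternal illicit-drug use and inpatient
  psychiatric treatment never occurred.

`pss4_stress_risk` takes already reverse-coded items (its stated
precondition); the interview stores raw answers and `derive_indicators`
applies the schema reversal before the cutoff.

Missing handling is complete-case everywhere: a missing raw answer makes
its indicator missing and the sum score missing, while per-area partial
counts and a diagnostic naming the failed rule are still reported.

## Composites

Each battery total is standardized over the analysis cohort's complete
cases, `(x − x̄)/s`, with the **sample SD (n − 1)** by default (a `ddof`
switch exposes the population convention, since legacy statistics packages
differ). Composites are unit-weighted sums of z-scores and are missing for
a respondent exactly when any component is missing; with one missing
PTSD-symptom item in a cohort of 67, the psychopathology composite has
N = 66 while the other composites keep N = 67. Because standardization uses
the cohort itself, composites are cohort-relative, not externally normed.

## Statistical battery

- **Cronbach's α** on the binary indicator matrix, after dropping
  zero-variance items: `α = k/(k−1)·(1 − Σ s²ᵢ / s²_total)` with n−1
  variances. Cross-checked in the tests against an independent library
  implementation and against the closed form `k·r̄/(1+(k−1)·r̄)` on
  simulated equicorrelated items.
- **Spearman ρ** as the product-moment correlation of midranks, pairwise
  complete, with per-pair n; a constant variable yields an undefined (NaN)
  ρ rather than an error.
- **Mann–Whitney U**: the reported statistic is the first group's U from
  midrank sums (`U_A + U_B = n_A n_B` always). The p-value is by exact
  permutation enumeration when `min(n_A, n_B) ≤ 8` and there are no ties,
  and a tie-corrected normal approximation without continuity correction
  otherwise. Per-group median/min/max are carried along for the report
  tables.
- **Kruskal–Wallis H** with tie correction, df = k − 1, chi-square p;
  for two untied groups H = z² of the U normal approximation (verified
  numerically in the tests).
- **Pooled-variance t-test** (df = n_A + n_B − 2) for the
  interviewer-profession comparison; a zero-pooled-variance configuration
  with unequal means is reported as an error, not an infinite statistic.
- **Pearson chi-square** on 2×2 tables, continuity correction off by
  default (switchable); a zero margin is an error naming the margin.
- **Normality gate**: Kolmogorov–Smirnov with the **Lilliefors
  correction**, because mean and SD are estimated from the data — plain
  K-S p-values would be conservative. Implemented via statsmodels'
  table/simulation-calibrated p-values; the gate flags non-normal at
  α = 0.05, and its type-I behavior is checked by replicate simulation.
- p-values are two-sided by default with a one-sided option; no
  multiple-testing correction is applied (matching the single-study
  analysis convention), and the report annotates the number of tests run.

## Synthetic-cohort generator

One latent adversity factor `A ~ N(0,1)` per respondent drives everything
(a single factor is the default because the three global criteria are
mutually correlated in validation data; the code structure admits
per-instrument loadings).

- **Binary risk conditions**: `Bernoulli(logistic(αᵢ + λ_B·A))`. The
  intercept αᵢ is calibrated by Gauss–Hermite quadrature (96 nodes) plus
  Brent root-finding so the marginal prevalence matches its target to well
  below 1e-3. Default targets follow the prevalence profile of a Spanish
  public-maternity cohort (e.g. lifetime psychiatric diagnosis 24.4%,
  physical symptoms 54.6%, childhood physical abuse 11.8%). Three targets
  are exactly zero (single parent, maternal drugs, inpatient treatment) to
  reproduce the zero-variance reliability condition. Ambiguously reported
  substance-use prevalences are set to plausible values and are
  user-settable.
- **Ordinal items** (bonding ratings, PSS-4, all battery items):
  `y = λ·A + ε`, `ε ~ N(0, σ²)`, discretized at fixed thresholds placed at
  the marginal quantiles of `N(0, λ² + σ²)` for a target per-item category
  distribution — so the marginal item distribution is invariant to the
  loading, and tuning the coupling never distorts the score distributions.
  Default category distributions put the instrument means near the
  validation-cohort values (PSS-14 ≈ 26, ESI ≈ 29, SCL somatization ≈ 10.6,
  PDS events ≈ 1.9, CFV ≈ 2.8). Bonding ratings use discretized normals
  (e.g. mother's joy mean 7.66, SD 2.32) with adversity loading negatively
  on joy and positively on worries.
- **Consistency of raw fields**: drawn conditions are materialized as
  consistent raw answers (a crowded-housing draw yields rooms/persons with
  ratio ≤ 0.5; an age-risk draw yields age 20–21, otherwise uniform 22–42,
  giving the observed mean age ≈ 32). Reverse-coded items are stored
  reflected so that scoring recovers the construct-aligned value.
- **Missingness**: with probability 1/67 per respondent, one random PDS
  symptom item is blanked — emulating the single missing battery value per
  validation subsample, and exercising the complete-case machinery.
- Everything is driven by one `numpy` Generator seeded from the config:
  identical config ⇒ bit-for-bit identical cohort.

### What the generator does and does not emulate

It reproduces marginal prevalences, score distributions, the zero-variance
indicators, the missingness pattern and a controllable screen–criterion
rank-correlation structure. It does **not** model multi-factor risk
structure, item-level dependence beyond the single factor, informative
missingness, interviewer effects, or reporting biases (e.g. face-to-face
underreporting of abuse). Passing tests therefore demonstrate correctness
of the pipeline and calibration machinery under a plausible one-factor
world, not validity of the instrument on real populations.

## Calibration and recovery experiment

A global `loading_scale` multiplies all loadings. For a target population
ρ between sum score and global stress, the scale is found by Brent's
method on one large simulated cohort (n = 20 000, common random numbers
across evaluations, tolerance 0.005); ρ(scale) is monotone, which the
tests verify on a loading grid. The recovery experiment then simulates
replicate cohorts at the validation-subsample size n = 67, runs the full
pipeline per replicate, and summarizes the ρ̂ distribution (mean, SD,
rejection rate at α = 0.05). With the scale calibrated to ρ = 0.45, the
replicate mean recovers the target within 0.05; with zero loadings the
rejection rate sits at the nominal 5% level. Problem sizes (20 000 for
calibration, 200–400 replicates of 67) were chosen so Monte-Carlo error is
comfortably below the tolerances being asserted.

## Numerical and degenerate-input conventions

- Exact rational arithmetic for the housing rule; integer sums for scores.
- z-transform requires ≥ 2 complete values and nonzero spread; the error
  names the offending variable.
- Normality test requires n ≥ 4 and non-constant input.
- Ties: midranks everywhere; exact U enumeration only for small untied
  samples.
- Seeds derived for replicates come from a `SeedSequence` and stay below
  2³¹.

## Known limitations

- The CFV item structure and the identity of the embedded PSS-4 items are
  conventions, not facts recoverable from the instrument's public
  description; both are schema-overridable.
- Composites are cohort-relative; comparing them across cohorts requires
  re-standardization and is intentionally unsupported.
- No sensitivity/specificity/ROC analysis and no predictive modelling: the
  package evaluates concurrent validity only.
- The one-factor generator cannot produce differential validity across the
  three criteria (all composite correlations rise and fall together).
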