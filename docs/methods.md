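# Methods

## Scope and data model

`reekit` operates on cohorts of adult subjects, each described by sex,
age (years), weight (kg), height (cm) and optionally REE measured by
indirect calorimetry (kcal/day). The supported domain is 18–60 y; ages
outside it raise a `DomainWarning` rather than an error, since every
registry equation extrapolates smoothly even where its validity is
unestablished. BMI is derived as weight/(height/100)². Equations
requiring body composition (fat-free mass) are out of scope by design:
the registry is restricted to predictors that are practical in routine
clinical settings.

## Equation registry

Each of the 20 equations is stored as data: one or more strata (a
predicate on sex, age and BMI plus a coefficient row), a sex coding, and
an output unit. Evaluation selects the single matching stratum, computes
`w·WT^e + h·HT + a·AGE + s·S + c`, and converts to kcal/day. Published
coefficients are stored verbatim; nothing is re-fit.

Decisions where the published formulations are ambiguous:

- **Mifflin–St Jeor constants.** Some secondary sources bracket the
  formula as "− [5·age + 5]", which would flip the male constant to −5.
  We implement the original constants (+5 male, −161 female): evaluating
  that form at a validation group's mean inputs reproduces the group-mean
  prediction reported for this equation (1493.2 kcal/day), while the
  bracketed reading does not.
- **Sex codings** are stored per equation, never assumed globally:
  male = 1 for Müller, Korth, Frankenfield, Fairoosa, Marra, Nichols and
  the new equation; female = 1 for de la Cruz Marcos (−308/day for women)
  and Ganpule (−547.3 kJ applied to women only). Müller's coding is not
  stated alongside its coefficients; male = 1 follows the equation's
  original publication, and because the equation is BMI-stratified the
  choice cannot be confirmed from pooled group means.
- **Age strata** (FAO/WHO/UNU, Schofield, Nikooyeh) are half-open:
  [18, 30) and [30, 60]. Printed stratum labels overlap at 30 y; age
  exactly 30 is assigned to the older stratum.
- **Müller BMI strata** are [0, 18.5), [18.5, 25], (25, 30], (30, ∞).
  BMI exactly 18.5 is ambiguous between the printed "<18.5" and
  ">18 ≤25" labels; we place it in the normal-weight row.
- **Frankenfield BMI boundary**: BMI exactly 30 uses the obese row
  ("BMI ≥ 30" as printed).
- **Unit conversions**: De Lorenzo and Korth divide kJ/day by 4.184,
  Ganpule by 4.186, each exactly as published for that equation. Müller
  outputs MJ/day, converted with 1000/4.184 ≈ 239.006 kcal/MJ
  (thermochemical calorie, consistent with the 4.184 divisors used
  elsewhere).
- **Livingston** is a power law (293·WT^0.433 − 5.92·AGE for men,
  248·WT^0.4356 − 5.09·AGE for women); it cannot go non-positive on the
  supported domain.
- **Nikooyeh 18–30 y rows** carry a positive age coefficient (+27.5/y) in
  the published table, unlike every other equation; we implement it as
  published. Being age-stratified, it cannot be cross-checked against a
  pooled group mean.

A registry invariant, enforced by tests over the domain sex × age
[18, 60] × weight [40, 150] kg × height [140, 200] cm: exactly one
stratum matches any subject and every equation returns a finite value in
(500, 4500) kcal/day.

### Group means by linearity

For equations linear in weight/height/age with an additive sex indicator,
the cohort-mean prediction equals the prediction at the cohort-mean
inputs, averaged over the sex mix. `group_mean_prediction` implements
this, which is what lets `scripts/acceptance.py` reproduce published
group-level validation results from printed summary statistics alone.
For sex-stratified equations with sex-specific slopes (Harris–Benedict
family) the identity holds within each sex but not for pooled means.

## Model development

- **Split**: simple unstratified random halving, driven by a NumPy
  `default_rng(seed)` permutation. Near-balance of the halves is an
  empirical check (Table-1-style comparison), not a constraint.
- **Group comparison**: independent-samples t (two-sided) per continuous
  variable; Pearson chi-square *without* continuity correction for sex,
  the primary statistic reported by mainstream statistical packages.
  Zero-variance degenerate inputs yield p = 1 (equal means) or NaN, not a
  crash.
- **Stepwise regression**: forward entry / backward removal on
  partial-F (equivalently t) p-values, thresholds p_enter = 0.05 and
  p_remove = 0.10 — the defaults of the software traditionally used for
  this procedure. p_remove > p_enter is enforced so a predictor cannot be
  entered and removed in the same step; the loop therefore terminates.
  Individual fits come from `statsmodels` OLS. In zero-residual
  (noise-free) fits, t statistics for null predictors are 0/0; such NaN
  p-values are treated as 1 at entry and 0 at removal, the conservative
  reading in each direction. With degenerate thresholds (p_enter = 1) the
  procedure reduces to full OLS on all candidates, which the tests verify
  against a direct least-squares fit to 1e−8.
- Sex is coded male = 1, female = 0 before regression. The fitted model
  is wrapped into a registry-compatible spec so validation treats it
  exactly like the published equations. Validation-phase statistics are
  computed on the held-out half without refitting.

## Validation statistics

All differences are predicted − measured (overprediction positive).

- **Accuracy rate**: share of subjects with |predicted − measured| ≤
  10% of measured; the band boundary is inclusive. Complemented by
  under-/over-prediction shares; the three sum to 100%.
- **Mean percentage error**: mean of (predicted − measured)/measured ×
  100 — group-level bias.
- **Precision**: paired two-sided t on the differences; Pearson r; from
  the simple regression of *measured on predicted*: R², adjusted
  R² = 1 − (1−R²)(n−1)/(n−2), and RMSE = √(SSres/(n−2)) (residual
  standard error). This orientation ties RMSE to R² and the SD of
  measured values via RMSE = SD(measured)·√((1−R²)(n−1)/(n−2)) — an
  identity the tests verify to 1e−8 and which reconciles published
  precision tables (e.g. R² 0.544, SD 400.65, n 142 → RMSE ≈ 271.4).
- **Bland–Altman**: limits of agreement mean(d) ± 1.96·SD(d) with the
  n−1 sample SD; the share of subjects strictly outside the limits;
  proportional bias as the Pearson correlation of differences with
  averages (negative when low-REE subjects are overpredicted and
  high-REE subjects underpredicted). Degenerate zero-variance inputs
  collapse the limits and mark the correlation NaN.
- Report tables round only at the presentation layer (CSV/markdown);
  JSON keeps full precision.

## Synthetic cohorts

The generator emulates a pooled urban adult IC study population: sex ~
Bernoulli (55.6% female); per-sex weight/height from a bivariate normal
with correlation 0.5 (a typical adult value; configurable); age from a
normal(33.35, 10.44²) truncated to [18, 60] (uniform available); measured
REE = 8.957·WT + 280.613·SEX − 7.795·AGE + 1039.837 + N(0, σ²).

Pooled targets (weight 71.93 ± 16.36 kg, height 168.27 ± 9.50 cm) are
decomposed into per-sex components using standard adult sex offsets —
men 79.4 ± 14.9 kg and 176.1 ± 6.4 cm, women 66.0 ± 14.9 kg and
162.0 ± 6.4 cm — chosen once so the mixture reproduces the pooled
mean ± SD within 2%. The decomposition is configuration, not asserted
truth.

The default noise SD is calibrated in closed form so that the correlation
between the noise-free signal and measured REE is 0.74, the centre of the
0.72–0.75 predicted-vs-measured band typical of REE validation studies:
σ = SD(signal)·√(1/r² − 1), with SD(signal) computed analytically from
the mixture moments (≈ 249 kcal/day under defaults, giving σ ≈ 227). An
optional proportional-noise mode scales the error with the signal to
reproduce the negative difference-vs-average correlation (proportional
bias) that real equations show.

What the generator does *not* emulate: measurement-protocol artifacts
(calorimeter drift, air leaks), day-to-day intra-individual REE
variation, non-Gaussian REE tails, and any weight–age or height–age
dependence. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not equation
performance in any real population.

A frozen 12-subject fixture covers both sexes, both age strata (including
the age-30 boundary) and all four BMI strata for hand-checkable
regression tests.

## Problem sizes and numerical choices

Simulation-based tests use study-scale cohorts (n = 142–284) and, where a
distributional property is asserted, n = 10,000–50,000 draws; the
stepwise parameter-recovery experiment uses 200 replicates at n = 142
(height included as a correlated decoy), sizes at which the Monte-Carlo
error of each check is comfortably below its tolerance. All evaluation is
double precision. All randomness flows through seeded NumPy generators;
reruns are bit-identical.

## Known limitations

- The stepwise criteria are partial-F thresholds only; no AIC/BIC or
  cross-validated selection is offered.
- The registry covers equations using sex, age, weight, height and BMI;
  fat-free-mass equations are out of scope.
- Proportional bias is summarised by a single correlation; no regression-
  based LoA adjustment is implemented.
- Pediatric (<18 y) and elderly (>60 y) predictions are extrapolations
  and only warned about, not refused.
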