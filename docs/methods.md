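# Methods

This note documents the statistical model behind `comorisk`, the
assumptions of its synthetic-cohort generator, and the numerical and design
choices made where the procedure left room.

## 1. Dietary network and intake score

**Model.**  The 16 food-group intakes (g/day) are treated as a
multivariate-normal system whose precision matrix `Ω` encodes conditional
dependence: `ω_ij = 0` means groups i and j are independent given the other
14.  A sparse `Ω̂` is estimated by graphical lasso on the column-standardized
data (partial correlations are scale-free, so standardization is purely
presentational) over a grid of penalties — by default 100 log-spaced values
from 1% of the largest absolute off-diagonal sample correlation up to that
maximum.  The penalty is selected by minimizing the extended Bayesian
information criterion

```
EBIC(Ω̂) = -2 l(Ω̂) + E log n + 4 E γ log p
```

with `l` the Gaussian log-likelihood, `E` the number of nonzero
upper-triangle edges (the diagonal is never counted), and `γ = 0.5` by
default; `γ = 0` recovers ordinary BIC.  Entries shrunk to zero by the
penalty are stored as exact zeros.  A penalty of exactly 0 is solved by
direct inversion of the sample covariance and silently dropped (with a
warning) when that matrix is singular.

**Centrality weights.**  Node weights are eigenvector centralities of the
selected network, computed by power iteration to a 1e-10 successive-iterate
tolerance and scaled so the maximum is exactly 1; isolated nodes receive 0.
Because partial-correlation networks carry negative edges while eigenvector
centrality is defined (via Perron–Frobenius) for nonnegative matrices, the
adjacency must be made nonnegative.  The default convention keeps **only
positive edges**.  This choice was validated against the published weight
table: on the published two-decimal adjacency, the positive-edge convention
reproduces the published centralities of the three benchmark nodes within
±0.05 (Seasonings 1.000 vs 1.00, Vegetables 0.722 vs 0.76, Fish and
shellfish 0.712 vs 0.70), whereas taking absolute values promotes the
oils–sugars dyad (edge 0.70) to the top (Seasonings 0.93 ≠ 1.00) and the
signed matrix misses Vegetables by 0.07.  `absolute` and `signed` variants
remain available behind a flag.  Power iteration runs on the spectrally
shifted matrix `M + σI` (σ = 1 + max row sum), which has the same
eigenvectors but a strictly dominant leading eigenvalue; the unshifted
iteration oscillates on bipartite-like graphs.

**Score and tertiles.**  The dietary score is `Σ_g w_g x_g` in g/day.
Tertile cutpoints are the empirical 1/3 and 2/3 quantiles; ties on a
cutpoint go to the lower class.  Multiplying all intakes by c > 0 scales
every score by c and leaves tertile membership unchanged.  Energy
adjustment is implemented as the 500–4000 kcal/day plausibility exclusion
only; a residual-on-energy adjustment is deliberately not applied by
default because the procedure being reproduced specifies only the
exclusion.

## 2. Marker categories and the exclusion cascade

Blood pressure: normal (<120/80 mmHg), elevated (120–139/80–89), or
hypertension (≥140/90, or self-reported treatment/diagnosis).  Total
cholesterol: low (<180 mg/dL), normal (180–200; the boundary 200 belongs to
normal, matching the printed closed range), elevated (>200 or
treated/diagnosed).  Fasting glucose: normal (<110 mg/dL) vs prediabetes
and diabetes (≥110 or treated/diagnosed).  GFR by the 4-variable MDRD study
equation `175 · SCr^-1.154 · age^-0.203 · (0.742 if female)`, categorized
≥90 / 60–89 / <60 mL/min/1.73 m²; the race coefficient (×1.212) is off by
default for this East-Asian screenee setting but available.  The
"treated or diagnosed" input is a single boolean per condition (therapy OR
prior diagnosis), since all three definitions combine them identically.

Exclusions run sequentially — missing/unrealistic energy, prior cancer,
missing covariates (complete-case on the model covariates), cancer
diagnosed within `latency_years` (default 1; 0 reproduces the
early-case-included sensitivity cohort) — and each subject is counted once,
at the first gate it fails.  The final cohort size is invariant to gate
order; only the per-gate attribution shifts.

## 3. Risk points, score strata, association

A single joint Cox model contains age (per year), indicator terms for every
non-reference marker category (mutual adjustment across the four markers
stands in for "other chronic diseases"), and — in the fully adjusted preset
— sex, marital status, education, employment, income, smoking, drinking,
physical activity, BMI band, and the continuous dietary score.  The partial
likelihood uses the Efron tie correction by default (screening cohorts
carry tied event times); Breslow is available.  Standard errors come from
the observed information.

Points are `round(β_j / β_age)`, halves away from zero; reference
categories score 0; negative points are retained (and logged), not
clamped.  The rule is undefined for `β_age ≤ 0` and fails loudly there.
The published point table (max attainable score 30; 23 with cholesterol
excluded) ships with the package for scoring without refitting.

Strata are configuration, defaulting to the printed labels: 0–8 / 9–10 /
11–15 / 16–30 for the main analysis, 0–2 / 3–8 / 9–10 / 11–23 with
cholesterol excluded, 0–4 / 5–8 / 9–10 / 11–24 with early cases included
(only the bottom and top labels of that last set are printed; the middle
cutpoints keep the main analysis' 9–10 band).  When refit point tables
push observed scores outside the template, the outer bins widen and
relabel rather than fail, because a score produced by the pipeline's own
point table is a valid configuration, not an error.

Association models: crude; adjusted (age, sex, education, employment,
income, smoking, drinking, BMI band); fully adjusted (additionally marital
status, physical activity, eating behavior as a 3-level categorical with
light as reference).  Sex subgroups drop the sex term.  The lowest stratum
is the reference (HR exactly 1); Wald 95% CIs.  The trend test replaces
each subject's stratum with the stratum's mean comorbidity score and
reports the Wald p-value of that single continuous term in the same
preset.  Death and administrative end of follow-up are treated as
censoring; competing-risk modelling is deliberately out of scope.

**Degenerate strata.**  An event-free non-reference stratum has a divergent
partial-likelihood MLE; it is excluded from the fit and reported as HR 0
with an infinite upper CI bound, with a warning.  An event-free reference
stratum makes every contrast divergent; eventful strata are then reported
as HR ∞.  These cases arise in practice when a noisy refit point table
concentrates events in one stratum.

## 4. Synthetic cohort generator

The generator defines the study conditions the tests run under.  Defaults:
13,644 recruited subjects; intakes from a Gaussian copula whose latent
16-dimensional normal has the published partial-correlation matrix
(precision `Ω = I − P`, verified positive definite for the published `P`;
if a user-supplied `P` is not, the diagonal is inflated with a warning,
which uniformly shrinks the realized partial correlations) and log-normal
marginals moment-matched to the published intake means/SDs; marker
categories at the published prevalences, with continuous measurements and
self-report flags drawn so classification reproduces the drawn category
exactly; demographics from plausible screenee distributions (these are
*not* calibrated to the source cohort's covariate joint distribution and
are not meant to be).

Event times are exponential with hazard
`λ0 · exp(β_age·age + Σ category log-hazards)`; `β_age = 0.0556` per year
(not printed by the source; chosen because `round(ln HR / 0.0556)`
reproduces 6 of the 7 published points, the seventh differing by one from
two-decimal HR rounding — a scan of [0.04, 0.07] is part of the acceptance
suite) and category log-hazards default to `point × β_age`.  The baseline
`λ0 = 1.85e-4`/year is calibrated so the default post-exclusion cohort
carries ~176 incident cancers, the reference study's observed count.
Follow-up is `horizon − entry` with entry uniform over a 7-year enrollment
window and a 9.25-year horizon (administrative censoring), giving a median
near the reference 5.3 years.  Exclusion material — energy outside
500–4000 kcal, prior cancer, MCAR missingness in one covariate, forced
early cases (event in the first year) — is injected at configurable
fractions defaulting to the published flowchart's proportions.

What the generator does **not** emulate: covariate–marker dependence (age
and blood pressure are independent here, unlike reality), cancer-site
structure, informative censoring, measurement error in intakes, and any
diet–cancer effect (dietary score coefficients are null by construction).
Passing tests therefore certify the pipeline's statistical machinery under
proportional hazards with known truth, not epidemiological realism.

Partial-correlation fidelity checks run on **log intakes**, the latent
Gaussian scale on which the copula preserves the network exactly; Pearson
partial correlations of the raw skewed intakes are attenuated (the 0.70
edge drops to ≈0.62), which is a property of the copula, not an estimation
error.

## 5. Numerical choices and test scales

* Graphical lasso via scikit-learn (off-diagonal penalty, coordinate
  descent); precision entries below 1e-8 are treated as exact zeros; the
  column-order dependence of coordinate descent bounds reproducibility of
  individual edges at the solver tolerance (~1e-4).
* Cox fits via statsmodels `PHReg` (chosen for Efron *and* Breslow ties);
  coefficients |β| > 50 raise a separation error in ordinary fits; a
  singular information matrix raises with the offending term list.
* Simulation-based tests use fixed seeds throughout and these scales,
  chosen once: 5,000-subject shared cohort for distributional checks;
  100 replicates at n = 1,500–2,500 for CI-coverage checks; 50 replicates
  at n = 20,000 with `λ0 = 9.5e-5` (~400 events) for point-recovery and
  HR-band checks; 1,000 replicates at n = 600 for the trend-test type-I
  calibration (empirical size 0.049 at nominal 0.05).
* At the ~400-event scale, a category coefficient's standard error
  (~0.11) exceeds the half-point rounding margin (0.028) several-fold, so
  *exact* recovery of a full 7-entry point table is essentially
  impossible by design; the corresponding acceptance test documents this
  gap and fails honestly rather than loosening the bound.  Interval-scale
  results (the top-stratum HR band, CI coverage, trend calibration) are
  the meaningful checks at this scale.

## 6. Known limitations

* The centrality convention (positive edges) is an inference from the
  published weight table; the source does not state its convention.
* Stratum cutpoint derivation is unspecified in the source and treated
  purely as configuration.
* The questionnaire logic linking drug names/durations to treatment flags
  is unpublished; flags are simple booleans.
* `RunConfig`/pipeline reports are deterministic given a seed, but
  graphical-lasso edge sets near the selection boundary can differ across
  BLAS builds at the solver-tolerance level.
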