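# comorisk

Dietary-network intake scores and additive comorbidity risk points for
cancer-incidence cohort analysis.

Epidemiological cohorts routinely carry two kinds of baseline signal that
single-variable analyses treat poorly: whole-diet consumption patterns (16
correlated food-group intakes, not one "fruit and vegetables" item) and
clusters of comorbidity markers (blood pressure, total cholesterol, fasting
glucose, kidney function) whose individual associations with cancer are
weak but whose joint burden may not be.  `comorisk` implements, as a tested
and reusable library, a data-driven pipeline that addresses both:

1. **Dietary network score.**  A Gaussian graphical model is fit to the 16
   food-group intakes by graphical lasso, with the penalty selected by the
   extended Bayesian information criterion,
   `EBIC = -2 l(Ω̂) + E log n + 4 E γ log p` (γ = 0.5, `E` = number of
   edges).  Nonzero precision entries give regularized partial correlations
   `ρ_ij = -ω_ij / √(ω_ii ω_jj)`.  Each food group is weighted by its
   max-normalized eigenvector centrality in that network, and a subject's
   dietary score is the weighted intake sum `Σ_g w_g x_g` (g/day), cut into
   tertiles (light / normal / heavy eating behavior).
2. **Comorbidity risk points.**  Markers are classified into clinical
   categories (JNC blood-pressure bands; total cholesterol <180 / 180–200 /
   >200 mg/dL; fasting glucose <110 / ≥110 mg/dL; MDRD-estimated GFR ≥90 /
   60–89 / <60 mL/min/1.73 m²; self-reported diagnosis or treatment
   dominates the measured value).  A joint Cox proportional-hazards model
   with age and all marker categories yields coefficients `β_j`, converted
   to Framingham-style integer points `pt_j = round(β_j / β_age)`
   (Sullivan's procedure).  A subject's comorbidity score is the sum of
   their four category points; score strata (0–8 / 9–10 / 11–15 / 16–30)
   are compared by Kaplan–Meier curves, stratified Cox hazard ratios, and a
   mean-score linear trend test.

Because the cohort the method was developed on is not public, the package
ships a first-class synthetic-cohort generator
(`comorisk.simulate`): food-group intakes follow a Gaussian copula with the
published partial-correlation network and log-normal marginals matched to
the published means/SDs, marker categories follow the published
prevalences, and event times are exponential with log-hazard
`β_age·age + Σ points·β_age` under staggered-entry administrative
censoring.  Every downstream stage is tested against it.

## Worked example

Centrality weights of the published food-group network
(`examples/01_dietary_network_weights.py`):

```
food group               centrality  published
Potatoes and starches          0.67       0.68
Vegetables                     0.72       0.76
Fish and shellfish             0.71       0.70
Seasonings                     1.00       1.00
...
```

Seasonings are the most central food group (weight exactly 1 after
max-normalization); weights computed from the two-decimal published
adjacency reproduce the published values closely for well-separated nodes.

Dose-response of the comorbidity score on a simulated cohort of 20,000
subjects scored with the published point table
(`examples/04_score_association.py`):

```
            n  events    hr  ci_low  ci_high
stratum
0-8      7421     184  1.00     NaN      NaN
9-10     5582     207  1.51    1.24     1.85
11-15    4104     175  1.74    1.41     2.14
16-30    2893     165  2.37    1.92     2.93

p_trend = 1.51e-16
```

Hazard ratios rise monotonically across strata — the dose-dependent
pattern the score is designed to expose (the reference study reports
HR 2.15, 95% CI 1.39–3.31 for the top stratum and p-trend < 0.001).

The other examples cover cohort generation and the exclusion cascade (02),
risk-point recovery from a joint Cox fit (03), and the two sensitivity
pipelines — cholesterol-free score, early cases retained (05).

A thin CLI mirrors the library:

```bash
comorisk simulate --n 13644 --seed 0 --out cohort.csv
comorisk classify --cohort cohort.csv --out classified.csv --report gates.json
comorisk run --seed 0 --out-dir results/
```

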