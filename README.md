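# reekit

A toolkit for predicting and validating resting energy expenditure (REE) in
children and adolescents:

* **equations** — 14 pediatric REE prediction equations (WHO/FAO/UNU,
  Schofield, IOM, Kim, Henry, Molnar, Müller weight/height and FFM forms,
  Derumeaux-Burel, Schmelzle, Tverskaya, Lazzer weight/height and FFM forms,
  and an FFM-only equation `REE = 505.412 + 24.383·FFM`), with per-equation
  sex/age-bracket dispatch, per-equation sex codings, and normalization of
  kJ/d and MJ/d forms to kcal/d (thermochemical 4.184 kJ/kcal).
* **anthro** — BMI, LMS (Box-Cox) BMI-for-age z-scores with linear age
  interpolation over any user-supplied reference CSV, and WHO-2007-style
  weight-status classes (overweight > +1 SD, obese > +2 SD, thin < −2 SD).
* **metrics** — the validation statistic suite: predicted−measured
  difference, accurate-prediction % (within 90–110 % of measured, boundary
  inclusive), bias % (measured as denominator), RMSE (1/n), and Bland-Altman
  agreement with limits at mean ± 2 SD of the differences; all computed
  overall and stratified by BMI group × sex.
* **modeling** — equation development: univariate OLS screening (p ≤ 0.05),
  backward stepwise elimination with rank-based resolution of exact
  collinearities (e.g. weight = FFM + FM), and packaging of the final fit as
  an equation spec the prediction machinery consumes directly.
* **synth** — a calibrated synthetic cohort generator: multivariate-Gaussian
  (age, height, FFM, FM) block, weight = FFM + FM, REE from the linear FFM
  model plus noise whose SD is derived from a variance identity, and BMI
  groups assigned by age-adjusted BMI rank. Marginal moments, the weight SD
  and the univariate R² structure of REE on FFM/weight/height/age are
  emergent properties of the calibration, not per-variable knobs.
* **cli** — a `reekit` command tying the stages together.

Gaussian-mode cohorts are deliberately untruncated (so moment and R²
recovery is unbiased); a few percent of subjects draw negative fat mass,
which `Cohort.quality()` reports. Use `--mode realistic` for demo cohorts
with clipped masses and ages in [6, 18].

Two published idiosyncrasies are preserved on purpose: the Müller equations
are coded male=0/female=1 here (the original 2004 publication codes male=1),
and Derumeaux-Burel is a single sex-free formula. Coefficients are stored
exactly as tabulated, without re-derivation.

## CLI

```bash
# simulate a calibrated cohort (275 subjects, groups 105/52/118)
reekit simulate --n 275 --seed 1 --out cohort.csv

# apply all 14 equations
reekit predict --cohort cohort.csv --out predictions.csv

# full validation: summary tables + Bland-Altman exports
reekit validate --cohort cohort.csv --out-dir validation/

# derive BMI groups from an LMS reference instead
reekit validate --cohort cohort.csv --lms who2007_lms.csv --out-dir validation/

# develop a new equation (univariate screen + backward elimination)
reekit develop --cohort cohort.csv --out-dir develop/

# validate the developed equation alongside / instead of the registry
reekit validate --cohort cohort.csv --out-dir validation2/ \
    --equation-spec develop/equation_spec.json --equations developed

# wide presentation table
reekit report --validation validation/validation.csv --out table.csv
```

Cohort CSVs have columns
`id,sex,age_years,weight_kg,height_cm,fat_mass_kg,fat_free_mass_kg,measured_ree_kcal_d,bmi_z,bmi_group`
(empty cell = absent, `#` lines are comments). Sex is always the string
`male`/`female` in files; numeric sex codings live inside each equation
spec.

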