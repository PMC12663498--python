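# Methods

## The risk engine

The harmonised HFA-ICOS variant is a deterministic rule set over complete
baseline profiles (see README for the point/flag table). Choices that the
published rule text leaves open, and how this implementation resolves them:

* **Threshold inequalities are strict**: BP > 140/90, BMI > 30, non-HDL
  > 3.8 mmol/L; eGFR < 60 defines CKD; age bands are [65, 80) and [80, ∞),
  reading "65–79" as < 80. Boundary cases (BMI exactly 30, BP exactly
  140/90) therefore do not fire.
* **Hypertension** = antihypertensive use OR systolic > 140 OR diastolic
  > 90. The conventional "140/90" notation is read disjunctively; a
  systolic-only variant is available via
  `ScoringConfig(hypertension_rule="systolic_only")` because published rule
  statements of this form do not distinguish the two.
* **Valvular disease is a high factor by default.** It is absent from the
  harmonised point table, but the published category-stratified prevalence
  table shows exactly 0% valvular disease in the low and moderate
  categories, which is only possible if valvular disease forces ≥ high.
  This inference is a modelling choice, not a documented rule; it is
  toggleable (`ScoringConfig(valvular_is_high=False)`).
* **Coronary artery disease** is one input flag covering MI, PCI/CABG and
  stable angina (the source rows are aggregated the same way in cohort
  descriptions).
* **Prior exposures vs treatments received**: anthracycline/chest-RT/chemo
  *before* baseline feed the score; treatments received *after* baseline
  never do — they only define subgroups.
* Scoring requires complete data (strict mode errors, naming subject and
  field). Missingness is resolved upstream by imputation; a non-strict mode
  treats missing as factor-absent for complete-case analyses.

## Endpoints and competing risks

The composite outcome is the first of: HF hospitalisation (primary
diagnosis), stroke (primary), MI (primary or secondary), CVD death.
Non-CVD death before any qualifying event is the competing event (status 2);
otherwise the subject is censored at the administrative horizon (status 0).
Conventions: follow-up starts at cancer diagnosis (time 0, no delayed
entry); an event at exactly the horizon counts, censoring applies strictly
after; a qualifying event tied with a death at the identical time resolves
to the CVD event ("first occurrence" semantics — the ordering only matters
at exact ties, which continuous time makes negligible). Single-cause
variants (HF alone, MI alone) keep the diagnosis-position rules and treat
*all* deaths as competing. The follow-up horizon is a per-subject value
(`followup_years`) because administrative censoring varies with diagnosis
date; a global cap can be layered on top in `RunConfig.horizon_years`.

## Estimators

All estimators are implemented directly (no survival library in the
package; lifelines, statsmodels and R `cmprsk` serve as test oracles only):

* **Kaplan-Meier** product-limit estimate with Greenwood variance and a
  plain normal CI, clipped to [0, 1].
* **Nelson-Aalen** H(t) = Σ d_i/n_i with variance Σ d_i/n_i².
* **Aalen-Johansen** CIFs for two causes: F_k(t) = Σ S(t_i−) d_{k,i}/n_i,
  where S is the all-cause KM. The identity F_1 + F_2 + S = 1 holds at
  every step to machine precision and is asserted in tests.
* **Harrell's C**: pair (i, j) comparable iff subject i had the event and
  t_i < t_j (time-tied event pairs excluded); concordant iff score_i >
  score_j; score ties count 1/2. Competing deaths are treated as censoring
  in the C computation — common practice when validating an ordinal score
  against a composite, and stated explicitly because competing-risk
  alternatives (e.g. Wolbers' C) would give systematically different
  values. The CI is a normal approximation with the U-statistic
  linearisation variance (per-subject influence residuals); a naive
  pair-count binomial variance is badly anti-conservative because pairs
  share subjects.
* **Cox PH**: Breslow tie handling; Newton-Raphson on the partial
  likelihood with step-halving, gradient tolerance 1e-8, max 100
  iterations; SEs from the inverse observed information; |β| > 10 raises a
  separation flag (monotone likelihood has no finite maximiser).
  Rank-deficient or constant design columns are rejected up front.
* **Fine-Gray**: the IPCW weighted partial likelihood. Subjects failing
  from the competing cause stay in later risk sets with weight
  w_i(t) = Ĝ(t−)/Ĝ(T_i−), where Ĝ is the pooled (covariate-free) KM of the
  censoring distribution, per the original formulation. Cox and Fine-Gray
  share one weighted Newton-Raphson core — the Cox weights are plain
  risk-set indicators — so the reduction "no competing events ⇒ Fine-Gray
  ≡ Cox" is exact by construction; independence of the check is preserved
  by external oracles (lifelines / statsmodels for Cox, R `cmprsk::crr`
  for Fine-Gray, which agrees to ~1e-6 on simulated data).
* **Classification metrics** from the dichotomised score (positive = high
  or very high; condition = composite event over full follow-up): standard
  2×2 formulas as percentages, rounded half away from zero for report
  tables, raw floats retained; zero-denominator metrics are returned as an
  explicit undefined marker rather than NaN.
* **Crude cumulative incidence** (the headline per-category figures) is the
  raw proportion of subjects with status 1 over the entire follow-up — the
  printed per-category proportions multiply back to the printed event
  total, so this is the estimand the published figures use; Aalen-Johansen
  curves are the competing-risk-adjusted supplement.

## Imputation

Minimal MICE: m = 5 completed datasets, 5 chained sweeps each, columns
visited in ascending-missingness order. Continuous columns use predictive
mean matching (OLS on complete cases, k = 5 nearest predicted-mean donors,
uniform donor draw — so imputations always lie in the observed support);
binary and polytomous columns use (multinomial) logistic regression with
draws from the predicted class probabilities (scikit-learn's default L2
regularisation stabilises the inner fits against separation in small
strata). The outcome enters every model as the Nelson-Aalen cumulative
hazard at the subject's own time plus the event indicator. Observed cells
are never altered; a fixed seed makes the full procedure bit-reproducible.
Diagnostics expose per-iteration imputed-cell means per chain for visual
convergence checking. The default analysis selects one completed dataset
uniformly at random (seeded, index logged); Rubin pooling is possible by
analysing all m outputs but is not the default pipeline. The PMM posterior
draw of β (fully Bayesian PMM) is deliberately omitted: with percent-level
missingness the between-imputation variance it adds is negligible, and the
default analysis uses a single dataset anyway. Source descriptions of the
procedure mention imputing "a random sample of the data set"; that reads as
a tooling artifact and is not implemented — the full table is imputed.

## Synthetic cohorts

The generator emulates a ~2,290-subject unselected cancer cohort with the
published category mix (28/35/34/3%), category-conditional predictor
prevalences, cancer-type and treatment distributions, and event rates:

* **Category-first construction**: intended category → conditional
  predictor draw → minimal repair so the scoring engine reproduces the
  intended category exactly (e.g. heart failure forced for very-high; high
  factors stripped and points capped at 1 for low). Repairs follow a fixed
  priority order, change as few fields as possible, and are counted per
  field so prevalence distortion is measurable. Scored category ==
  intended category holds for every subject by construction and is
  asserted in tests.
* **Event model**: per category, latent T_cvd ~ Exp(λ_cvd) and T_death ~
  Exp(λ_death), independent. The earlier one is the first event; CVD first
  events are fatal (CVD death) with probability 0.18 — the published share
  of CVD deaths among first events — otherwise the subject's later death at
  T_death is also emitted. The composite first-event split across HF
  hospitalisation / MI / stroke / CVD death defaults to 19/35/28/18%
  (published counts 87/161/130/82 of 460). MI diagnosis position is
  primary or secondary with equal probability.
* **Calibration**: λ_cvd and λ_death solve two equations — the
  competing-exponential CIF of the composite equals the published
  per-category incidence (7/21/29/37%) at the pooled median follow-up of
  6.9 years, and closed-form all-cause mortality equals the published
  32/55/79/89% at 8.7 years. Mortality must be calibrated as *all-cause*
  (deaths after nonfatal CVD events included): treating the published
  mortality as a competing-cause CIF is mathematically infeasible for the
  high and very-high categories, where the two targets sum past 1. A pure
  two-CIF calibration (`calibrate_exponential_hazards`, closed form) is
  kept for scenarios where both targets really are first-event CIFs.
  Anchoring every category at the pooled medians is an approximation —
  per-category follow-up medians are not published.
* **Censoring**: administrative, Uniform(11, 17) years, reflecting
  diagnoses spread over 2006–2012 with follow-up through 2023. Because
  follow-up extends well past the 6.9-year anchor, crude full-follow-up
  incidences in generated cohorts run higher than the anchored targets —
  expected, and matching how the longer-followed published strata behave.
* **Missingness** is MCAR per predictor and off by default; pipeline
  examples use 1–4% per predictor to exercise imputation, matching the
  percent-level missingness the tool is meant to tolerate.
* Event times can be made Weibull (`weibull_shape`) for robustness tests;
  exponential is the default because it gives closed-form CIFs for
  calibration.

**What passing tests do and do not show.** The generator reproduces
published *margins* (category mix, per-category incidence and mortality,
first-event composition) under independence assumptions: predictors are
conditionally independent given category, event times are exponential and
independent of predictors given category, and censoring is purely
administrative. Real cohorts have correlated predictors, time-varying
hazards, treatment effects and informative early mortality. The headline
concordance check (mean Harrell C ≈ 0.69 across seeded cohorts, within
±0.03 of the published 0.696) is therefore a *calibration-plausibility*
result — the published margins imply roughly this discrimination under a
neutral event model — not a reproduction of the registry analysis. Cox
hazard ratios between categories in synthetic cohorts are much larger than
published ones, as expected: within-category risk heterogeneity, which
attenuates fitted HRs in real data, is not modelled.

## Problem sizes

Defaults used by the test suite and the acceptance script: cohorts of
n = 2,290 (the published cohort size), 20 seeds for the concordance
average; parameter-recovery suites use 50 replicates at n = 2,000;
calibration round-trips use 10⁵ Monte-Carlo draws; property fuzzing uses
200–300 random profiles per invariant. These sizes were chosen so every
Monte-Carlo tolerance sits at ≥ 4 standard errors while the whole suite
runs in well under a minute per module.

## Known limitations

* Biomarker (troponin, NT-proBNP), ECG and LVEF rules are out of scope —
  the modified tool exists precisely because they are often unavailable.
* The seven original treatment-specific HFA-ICOS weighting schemes are not
  implemented; only the harmonised variant is.
* No time-dependent covariates, frailty, recurrent events, or calibration
  curves (the consensus tool publishes no risk equation to calibrate
  against).
* The Fine-Gray IPCW uses the pooled censoring distribution; covariate-
  dependent censoring would bias sHRs.
* Synthetic predictors are conditionally independent given category; do
  not use generated cohorts to study predictor correlation structure.
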