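# Methods notes

This note records the modelling assumptions, parameter choices and known
limitations behind `pci_traj`. It is written for someone auditing or
extending the package, not as a user guide.

## The synthetic cohort: what it emulates, and what it does not

`synthetic.generate_cohort` produces a sepsis-like ICU cohort with the
statistical structure every downstream stage assumes:

* **Latent trajectory classes.** Five classes with mixing proportions
  (0.2279, 0.0355, 0.5167, 0.1119, 0.1080) and quadratic mean SOFA
  trajectories; classes 1–2 rise over days 1–10, classes 3–5 fall from
  increasingly high starting severity. The exact quadratic coefficients are
  not published anywhere we could draw from, so the defaults were chosen
  once to match the qualitative shapes (low-rising, rising, moderate-
  falling, high-falling, persistent-high) with day-1 means spanning ≈4–13
  SOFA points. A shared random intercept (σ_b = 1.2) and residual noise
  (σ_e = 1.5, both in SOFA points) give within-class heterogeneity.
* **Labs by band inversion.** The integerised daily SOFA total is split
  across the six organ systems (cardiovascular capped at 2 — the schema
  carries a vasopressor flag without doses, so scores 3–4 are not
  representable) and each subscore is converted to a raw lab drawn
  uniformly inside that subscore's cutoff band. Scoring the generated labs
  therefore reproduces the generated subscores *exactly*, which is what the
  round-trip tests exploit.
* **Outcomes.** Death time follows a piecewise-exponential hazard
  λ(t) = λ0 · exp(β_a(t)·acute + β_z(t)·antecedent), where the acute score
  is the standardised day-1 SOFA and the antecedent score a standardised
  combination of age and comorbidity count. β_a steps from its first to its
  second value at `attenuation_day` — the ground-truth transition. Discharge
  alive competes as an independent exponential ICU-discharge time plus an
  exponential ward stay; lengths of stay are ceiled to whole days. Defaults
  (λ0 = 0.012/day, acute (0.9, 0.1), antecedent (0.4, 0.4), discharge
  0.13/day, ward 0.25/day) give ≈16% in-hospital mortality and median stays
  of a few days, matching the scale of the motivating cohort.
* **Catabolic signature.** The urea-to-creatinine ratio drifts upward
  within the stay for long-stayers (`ucr_drift` per day, scaled by
  stay-length fraction); albumin/haemoglobin fall and the
  neutrophil-to-lymphocyte ratio rises on the same within-stay trend; CRP
  has no group difference. All drifts are zero on day 1 by construction so
  that day-1 acute covariates carry no information about the eventual
  length of stay — an early version violated this and spuriously kept the
  "acute" family predictive after the hazard switch.
* **Missingness** is MCAR per cell at per-variable rates (defaults 4–8% for
  the signature labs). Values under missing cells are retained as ground
  truth for imputation experiments.

Not emulated: realistic cross-lab correlation, informative (MNAR)
missingness, ICU readmission, per-class outcome differences beyond what the
trajectory→acute-score pathway induces. Passing tests on this generator
show the *estimators* work when their assumptions hold; they say nothing
about robustness to violations real data would bring.

## Preprocessing

Outlier rules (negative vital signs, age > 200, negative urine output) set
cells to missing and log each change. The missingness screen drops
variables with **strictly more than 10%** missing; pH, PaCO2 and urine
output are always excluded from model covariates. Longitudinal imputation
fits, per patient-variable series and per target day, a quadratic-in-time
weighted least squares with tricube weights (bandwidth = the panel's day
span), falling back to cohort day-means when a series has fewer than three
observations. Cross-sectional imputation is chained equations with
regression/classification trees (10 sweeps, minimum leaf 5), drawing each
imputed value uniformly from the observed donors in the terminal node; m=5
completed tables by default, downstream analyses using the first unless
pooling is requested. We draw donors rather than node means because proper
imputation needs residual noise; the cost is that the per-cell RMSE is
≈√2 × the oracle regression RMSE, which the tests assert as ≤1.5×.

## The growth mixture model

Class-specific quadratic fixed effects; one shared random intercept;
homoscedastic residuals; intercept-only membership. This is the minimal
model that yields distinct mean trajectory profiles with closed-form
M-steps: richer structures (random slopes, class-specific variances,
ordinal links) are out of scope. Each patient's marginal contribution is
multivariate normal with covariance σ_e²I + σ_b²11ᵀ over their observed
days; the Woodbury identity reduces everything to the per-patient residual
sums Σr and Σr², so the E-step is O(n·T·G). The M-step is exact given the
E-step moments (class posteriors and random-intercept conditional moments):
weighted least squares for each β_g, then closed-form variance updates at
the new β (a conditional-maximisation step; the marginal log-likelihood is
still non-decreasing, which the tests check to 1e-8).

Initialisation: per-patient OLS quadratic coefficients, standardised and
clustered by k-means into G groups; further starts perturb that solution.
Degenerate starts (a class with expected share below 1/n) are discarded and
redrawn. Parameters: `n_starts=10` (tests and pipeline use 2–4 for speed),
`tol=1e-6` on the log-likelihood change, `max_iter=500`.

Model count is selected by BIC among fits whose smallest modal class has at
least `min_class_n` patients (500 at the motivating cohort's n≈23k;
pro-rated when we run smaller cohorts), ties toward fewer classes. Relative
entropy 1 − Σ p log p/(n log G) is reported but not used to select: the
usual convention is that *larger* relative entropy means crisper
classification, and we did not want selection to hinge on a direction that
is frequently misstated.

`n_params = 3G + (G−1) + 2` counts our parametrisation. Note the published
5-class fit this package is patterned on implies k=20 via the AIC/BIC gap
identity, i.e. one parameter fewer than ours — consistent with a slightly
different variance structure in their mixed-model software. The
information-criterion checks are therefore pure arithmetic on
(loglik, k, n), not a claim that our parametrisation equals theirs.

## The transition estimator

Risk set at day d: patients with hospital stay strictly greater than d.
Outcome: in-hospital death. Families: acute = screened day-1 physiology
(17 covariates by default), antecedent = age, sex, seven comorbidity flags.
Fits are logistic with a small ridge (λ=1e-4 on standardised slopes, none
on the intercept) so that quasi-separated late-day risk sets remain
estimable; the in-house Newton/IRLS fitter is used because a cohort run
needs up to 28 × 2 × 100 = 5,600 fits and determinism matters. Each day
draws `iters` random 70/30 splits (one permutation stream per day, spawned
from the master seed); both families share each split, so the replicate
AUC differences are paired. Days are non-evaluable when the risk set — or
any validation fold — has fewer than `min_events=10` deaths or survivors.

Significance: one-sided paired t-test of the replicate AUC differences
(H1: acute > antecedent) at α=0.05. The default readout is the **last day
of the initial significant run**, with a loss of significance required to
persist for 3 consecutive evaluable days (or to the end of the horizon).
Both the readout convention and the persistence length are switches.

### What "recovering the transition day" can and cannot mean

With the hazard's acute coefficient switching off at day D, the AUC-crossing
estimand is **not** automatically D:

* *Dilution.* The outcome is eventual in-hospital death, so the acute
  family's edge at day d < D is proportional to the share of the risk set's
  future deaths that fall in (d, D). Any post-switch death mass pulls the
  crossing earlier than D.
* *Selection.* Surviving in hospital to day d depletes the high-acute-score
  tail, eroding the day-1 marker's discrimination even before the switch.
* *Frozen split noise.* Late-day risk sets are small, and the 100 split
  replicates all see the same cohort; a chance AUC pattern in one cohort is
  reproduced by every replicate, so the paired t-test can hold an
  arbitrary-sign "difference" significant indefinitely.

The recovery experiments therefore use conditions under which the estimand
coincides with the switch: a strong acute effect with a clean switch to
zero (acute (1.2, 0.0)), a modest post-switch antecedent edge
(antecedent (0.1, 0.2)) so the pre-switch acute advantage survives until
the switch, and λ0=0.04, discharge 0.15/day, ward 0.3/day. The readout is
the **first non-significant risk day** (the day-D risk set is the first
whose deaths are all post-switch) with the persistence guard off (because
of the frozen-noise pathology above). Under these conditions cohorts of
n=10,000 recover switches at days 5, 10 and 15 within ±2 days in ≈90% of
runs (10 seeds per switch day). Under the *default*, paper-patterned
conditions — overlapping effects, residual post-switch acute effect — the
crossing sits 3–5 days before the hazard switch: that is a property of the
estimand, not an estimator bug, and is worth remembering when interpreting
transition days estimated from real cohorts.

PCI labelling: `icu_los > transition_day`; bed-day shares use integer
lengths of stay with no partial days. Subset analysis reruns the entire
procedure (fits included) within each subset, skipping subsets that are too
small or have no deaths/survivors.

## The step-coefficient Cox model

Scores: per-family logistic linear predictors on the full cohort
(statsmodels MLE, ridge fallback on separation), standardised so hazard
ratios are per SD of score. Episodes are split at days 2, 3, 7, 14, 21 (the
48 h / 72 h / 7 d / 14 d / 21 d grid); the design interacts each score with
the interval indicator (12 coefficients). Breslow tie handling — event
times are coarse (whole days) in pipeline use, and Breslow is the
transparent baseline; there is no Efron implementation. Risk-set sums for
the partial likelihood, score and information are assembled with sorted
cumulative sums (O(m log m) per Newton step); step-halving keeps the
likelihood monotone; convergence at relative log-likelihood change < 1e-9;
intervals without events — or score columns without variation — are
dropped and reported as NaN rows. Confidence intervals are Wald, from the
inverse observed information. Discharge alive is right-censoring (the
competing-risk structure of discharge is not modelled). A single-interval
fit reproduces lifelines' time-fixed Cox estimates to ≤1e-6, and simulated
step log-hazards (0.7→0.2 acute, 0.3 antecedent) are recovered within
±0.1 as a 30-seed median at n=5,000.

## Signatures

Two-sided Wilcoxon rank-sum everywhere (with an explicit p=1 for the
degenerate all-tied case); star coding at 0.05/0.01/0.001/0.0001; no
multiplicity correction by default to match the conventional presentation,
with a Benjamini–Hochberg switch. The urea-to-creatinine change matrix uses
within-patient later-minus-earlier differences over patients observed on
both days; patients with ICU stays under 2 days are excluded; cells at or
below the diagonal are zero by convention in the heatmap grid. The
neutrophil-to-lymphocyte ratio is undefined (cell excluded) when
lymphocytes are zero. The "total" column is computed on the union of the
two groups.

## Problem sizes and runtimes

The test suite runs the full machinery at reduced but non-trivial sizes
chosen to keep the whole suite around five minutes: mixtures at n=200–2,500
(G≤3 recovery, G=1 oracle), transition recovery at n=10,000 × 30 runs with
60 replicate splits, Cox recovery at n=4,000–5,000 × 30 seeds, imputation
properties at n=60–1,000. `scripts/acceptance.py` uses n=4,000–10,000 per
stage and completes in about a minute. All randomness flows from explicit
seeds; reruns are byte-identical.

## Known limitations

* The LGMM treats integer SOFA (0–24, here 0–22 due to the cardiovascular
  cap) as continuous Gaussian; fine for mean-trajectory clustering, wrong
  for tail probabilities.
* The transition day inherits the estimand caveats above; on real cohorts
  the "true" switch day is not identified, only the AUC crossing.
* The cross-sectional imputer does not implement predictive mean matching
  variants or pooling inference (Rubin's rules) — point analyses use the
  first completed table.
* The Cox module has no Efron ties option and no spline β(t); the step grid
  is fixed by configuration.
* The generator's independence assumptions (labs given subscores, discharge
  times, missingness) are simplifications; see the synthetic-cohort section.
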