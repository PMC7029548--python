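# pci-traj

When does a septic ICU patient stop being acutely ill and become
*persistently* critically ill? `pci_traj` is a Python toolkit for the
trajectory-based, prediction-based definition of **persistent critical
illness (PCI)**: the state in which a patient's continued ICU stay is driven
more by acquired complications than by the condition that brought them in.
It is aimed at intensive-care epidemiologists and biostatisticians who want
to apply — or stress-test — this definition on their own cohort data.

## The methods

Four statistical components, each usable on its own:

**1. Latent growth mixture model (LGMM) of daily SOFA.** Daily Sequential
Organ Failure Assessment scores over ICU days 1–10 are modelled as a finite
mixture of quadratic growth curves: patient *i* in latent class *g* has

```
y_it = β0g + β1g·t + β2g·t² + b_i + ε_it,   b_i ~ N(0, σ_b²),  ε_it ~ N(0, σ_e²)
```

with multinomial class membership π. The EM algorithm integrates the random
intercept in closed form (rank-one covariance), handles missing days, and is
guaranteed monotone in the marginal log-likelihood. Class count is chosen by
AIC/BIC/sample-size-adjusted BIC plus a minimum-class-size rule; relative
entropy of the posterior classification is reported.

**2. The transition-day estimator.** For each day *d*, two logistic models
are fit on the patients still in hospital after day *d*: one on day-1
*acute* physiology, one on *antecedent* characteristics (age, sex, chronic
comorbidities), both predicting in-hospital death. Each is refit on repeated
random 70/30 splits (shared between families) and scored by validation AUC
(Mann–Whitney). PCI begins on the day the acute family stops being
significantly better (one-sided paired t-test across replicate AUC
differences). Patients still in ICU past that day are labelled PCI, and
their share of ICU/hospital bed-days quantifies the resource burden.

**3. Step-function time-varying-coefficient Cox model.** Acute and
antecedent covariates are collapsed into standardised scores and entered in
a Cox model whose coefficients are constant within 0–48 h, 48–72 h,
72 h–7 d, 7–14 d, 14–21 d and >21 d. Episodes are expanded to
counting-process rows and the Breslow partial likelihood is maximised by
Newton–Raphson, giving per-interval hazard ratios that show the acute
effect attenuating while the antecedent effect persists.

**4. Biochemical signatures.** Day-by-day PCI vs non-PCI comparisons
(Wilcoxon rank-sum) for SOFA, albumin, haemoglobin, CRP, the
neutrophil-to-lymphocyte ratio, and the urea-to-creatinine ratio (BUN /
creatinine, both mg/dl), plus the full later-minus-earlier change matrix of
the urea-to-creatinine ratio across all ordered day pairs.

Because the clinical source data sit behind credentialed access, the package
ships a **synthetic-cohort generator** with the same statistical structure —
five latent SOFA trajectory classes, raw labs invertible through the SOFA
cutoff bands, a piecewise-exponential death hazard whose acute coefficient
switches off at a configurable day — so every stage is testable against
known ground truth.

## Worked example

```python
from pci_traj import (SimConfig, generate_cohort, bootstrap_auc_series,
                      transition_day, label_pci)

cfg = SimConfig(n_patients=4000, seed=1, attenuation_day=10.0,
                acute_effect=(1.2, 0.0), antecedent_effect=(0.1, 0.2),
                baseline_hazard=0.04, discharge_rate=0.15, ward_rate=0.3)
cohort, panel = generate_cohort(cfg)

series = bootstrap_auc_series(cohort, horizon=20, iters=40, seed=2)
day = transition_day(series, persistence=1, convention="first_nonsignificant")
res = label_pci(cohort, day)
print(f"transition day: {day}")
print(f"PCI patients: {res.pci_count} ({100*res.pci_share:.1f}%)")
print(f"ICU bed-day share: {100*res.icu_bedday_share:.1f}%")
print(f"day-1 AUC acute {series.auc_acute[1].mean():.3f} "
      f"vs antecedent {series.auc_antecedent[1].mean():.3f}")
```

prints

```
transition day: 9
PCI patients: 695 (17.4%)
ICU bed-day share: 46.7%
day-1 AUC acute 0.711 vs antecedent 0.527
```

The generator's death hazard stopped depending on acute physiology at day
10; the estimator places the transition at day 9 — on day 1 the acute model
clearly out-predicts the antecedent one (AUC 0.711 vs 0.527), and that
advantage is gone by day 9. The 695 patients still in ICU past the
transition hold a disproportionate 46.7% of all ICU bed-days.

There is also a CLI covering each stage and a one-config pipeline:

```bash
pci-traj simulate --out data/ --seed 1 --n 4000
pci-traj find-transition --cohort data/cohort.csv --horizon 20 --iters 40 --out out/
pci-traj run --config pipeline.yaml --out out/
```

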