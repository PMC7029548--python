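"""Synthetic sepsis-cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* five latent classes with quadratic mean SOFA trajectories over ICU days
  1..10 (two rising, three falling), a shared patient random intercept and
  homoscedastic day-level noise;
* raw labs obtained by *inverting* the SOFA subscore bands (uniform within
  the band), so scoring the generated labs reproduces the generated
  subscores exactly;
* an in-hospital death hazard that is piecewise-exponential in time,
  ``lambda(t) = lambda0 * exp(beta_a(t)*acute + beta_z(t)*antecedent)``,
  where the acute coefficient steps down after ``attenuation_day`` (the
  ground-truth transition day) while the antecedent coefficient persists;
* discharge alive as an independent competing exponential time (ICU
  discharge followed by a ward stay);
* item-level MCAR missingness at configurable per-variable rates.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .panel import LongitudinalPanel
from . import schema

#: per-organ subscore caps; cardiovascular capped at 2 because the schema
#: carries a vasopressor flag without doses
_ORGAN_CAPS = np.array([4, 4, 4, 2, 4, 4])
_MAX_TOTAL = int(_ORGAN_CAPS.sum())

_COMORBIDITY_PREV = {
    "aids": 0.003,
    "hepatic_failure": 0.022,
    "lymphoma": 0.010,
    "metastatic_cancer": 0.035,
    "leukemia": 0.016,
    "immunosuppression": 0.057,
    "cirrhosis": 0.028,
}

_INFECTION_PROBS = {
    "pulmonary": 0.383,
    "renal_uti": 0.228,
    "gi": 0.124,
    "cutaneous": 0.083,
    "gynecologic": 0.003,
    "unknown": 0.113,
    "other": 0.066,
}

_DISCHARGE_ALIVE_PROBS = {
    "home": 0.52,
    "skilled_nursing_facility": 0.23,
    "nursing_home": 0.02,
    "rehabilitation": 0.035,
    "other_hospital": 0.055,
    "other_external": 0.14,
}


def _decompose_total(totals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly split integer totals into 6 organ subscores within caps.

    Vectorised greedy allocation: one point per round to a uniformly chosen
    organ with remaining capacity (Gumbel-argmax over admissible organs).
    """
    flat = totals.reshape(-1).astype(int)
    sub = np.zeros((flat.size, 6), dtype=int)
    remaining = flat.copy()
    for _ in range(_MAX_TOTAL):
        need = remaining > 0
        if not need.any():
            break
        cap_ok = sub[need] < _ORGAN_CAPS  # (k, 6)
        g = rng.gumbel(size=cap_ok.shape)
        g[~cap_ok] = -np.inf
        organ = np.argmax(g, axis=1)
        rows = np.nonzero(need)[0]
        sub[rows, organ] += 1
        remaining[rows] -= 1
    return sub.reshape(totals.shape + (6,))


def _invert_labs(sub: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw raw labs uniformly within each subscore's band.

    ``sub`` has shape (..., 6) ordered respiration, coagulation, liver,
    cardiovascular, cns, renal. Round-trips exactly through the shipped
    SOFA cutoff table.
    """
    shape = sub.shape[:-1]
    u = lambda lo, hi: rng.uniform(lo, hi, size=shape)

    # respiration: PF band, ventilation required for scores >= 3
    pf_lo = np.array([400.0, 300.0, 200.0, 100.0, 60.0])
    pf_hi = np.array([500.0, 400.0, 300.0, 200.0, 100.0])
    s = sub[..., 0]
    pf = pf_lo[s] + u(0, 1) * (pf_hi[s] - pf_lo[s])
    vent = s >= 3
    fio2 = u(0.3, 0.8)
    pao2 = pf * fio2

    plate_lo = np.array([150.0, 100.0, 50.0, 20.0, 5.0])
    plate_hi = np.array([350.0, 150.0, 100.0, 50.0, 20.0])
    s = sub[..., 1]
    platelets = plate_lo[s] + u(0, 1) * (plate_hi[s] - plate_lo[s])

    bili_lo = np.array([0.2, 1.2, 2.0, 6.0, 12.0])
    bili_hi = np.array([1.19, 1.99, 5.99, 11.99, 25.0])
    s = sub[..., 2]
    bilirubin = bili_lo[s] + u(0, 1) * (bili_hi[s] - bili_lo[s])

    s = sub[..., 3]  # cardiovascular: 0, 1, or 2 (vasopressor)
    vaso = s == 2
    mean_bp = np.where(s == 0, 70.0 + u(0, 1) * 29.0, 50.0 + u(0, 1) * 19.0)

    gcs_lo = np.array([15, 13, 10, 6, 3])
    gcs_span = np.array([1, 2, 3, 4, 3])
    s = sub[..., 4]
    gcs = gcs_lo[s] + np.floor(u(0, 1) * gcs_span[s]).astype(int)

    creat_lo = np.array([0.3, 1.2, 2.0, 3.5, 5.0])
    creat_hi = np.array([1.19, 1.99, 3.49, 4.99, 10.0])
    s = sub[..., 5]
    creatinine = creat_lo[s] + u(0, 1) * (creat_hi[s] - creat_lo[s])

    return {
        "pao2": pao2,
        "fio2": fio2,
        "mech_vent": vent.astype(int),
        "platelets": platelets,
        "bilirubin": bilirubin,
        "mean_bp": mean_bp,
        "vasopressor": vaso.astype(int),
        "gcs": gcs.astype(float),
        "creatinine": creatinine,
    }


def latent_trajectories(cfg: SimConfig, classes: np.ndarray, rng: np.random.Generator
                        ) -> np.ndarray:
    """Latent continuous SOFA, shape (n_patients, n_days): quadratic class
    mean + random intercept + residual noise."""
    days = np.arange(1, cfg.n_days + 1, dtype=float)
    beta = np.asarray(cfg.growth_coef, dtype=float)  # (G, 3)
    mean = beta[classes, 0:1] + beta[classes, 1:2] * days + beta[classes, 2:3] * days**2
    b = rng.normal(0.0, cfg.sigma_b, size=(len(classes), 1))
    eps = rng.normal(0.0, cfg.sigma_e, size=(len(classes), cfg.n_days))
    return mean + b + eps


def simulate_outcomes(acute: np.ndarray, antecedent: np.ndarray, cfg: SimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw death/discharge times from the piecewise-constant hazard.

    The death hazard is ``lambda0 * exp(ba(t)*acute + bz(t)*antecedent)``
    with (ba, bz) switching from their first to their second value at
    ``cfg.attenuation_day``. Discharge alive competes as an independent
    exponential ICU-discharge time followed by an exponential ward stay.

    Returns a frame with raw times (``death_time`` may be ``inf``) and the
    integer-day LOS / vital-status fields used by the analysis.
    """
    acute = np.asarray(acute, dtype=float)
    antecedent = np.asarray(antecedent, dtype=float)
    if not (np.all(np.isfinite(acute)) and np.all(np.isfinite(antecedent))):
        raise ValueError("scores must be finite")
    if cfg.baseline_hazard < 0:
        raise ValueError("baseline hazard must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = acute.shape[0]
    d_star = cfg.attenuation_day
    lam1 = cfg.baseline_hazard * np.exp(
        cfg.acute_effect[0] * acute + cfg.antecedent_effect[0] * antecedent
    )
    lam2 = cfg.baseline_hazard * np.exp(
        cfg.acute_effect[1] * acute + cfg.antecedent_effect[1] * antecedent
    )
    e = rng.exponential(1.0, size=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(lam1 > 0, e / lam1, np.inf)
        extra = e - lam1 * d_star  # residual exponential mass past the switch
        t2 = d_star + np.where(lam2 > 0, extra / lam2, np.inf)
    death_time = np.where(t1 < d_star, t1, t2)
    death_time = np.where(np.isnan(death_time), np.inf, death_time)

    icu_discharge = rng.exponential(1.0 / cfg.discharge_rate, size=n)
    ward = rng.exponential(1.0 / cfg.ward_rate, size=n)
    hosp_discharge = icu_discharge + ward

    icu_death = death_time < icu_discharge
    ward_death = (~icu_death) & (death_time < hosp_discharge)
    hosp_death = icu_death | ward_death

    icu_end = np.where(icu_death, death_time, icu_discharge)
    hosp_end = np.where(hosp_death, death_time, hosp_discharge)
    icu_los = np.maximum(1, np.ceil(icu_end)).astype(int)
    hosp_los = np.maximum(icu_los, np.ceil(hosp_end).astype(int))

    loc = np.empty(n, dtype=object)
    loc[hosp_death] = "death"
    alive = ~hosp_death
    cats = list(_DISCHARGE_ALIVE_PROBS)
    probs = np.array(list(_DISCHARGE_ALIVE_PROBS.values()))
    loc[alive] = rng.choice(cats, size=int(alive.sum()), p=probs / probs.sum())

    return pd.DataFrame(
        {
            "death_time": death_time,
            "icu_discharge_time": icu_discharge,
            "hosp_discharge_time": hosp_discharge,
            "icu_death": icu_death.astype(int),
            "hosp_death": hosp_death.astype(int),
            "icu_los": icu_los,
            "hosp_los": hosp_los,
            "discharge_location": loc,
        }
    )


def apply_missingness(panel: LongitudinalPanel, miss_rates: dict[str, float],
                      seed: int) -> LongitudinalPanel:
    """Flip panel cells to missing, MCAR per cell at each variable's rate.

    Values under newly-missing cells stay in ``panel.values`` as ground
    truth for imputation experiments; only the mask changes.
    """
    for k, r in miss_rates.items():
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"missingness rate for {k!r} must be in [0, 1], got {r}")
    out = panel.copy()
    rng = np.random.default_rng(seed)
    for name, rate in miss_rates.items():
        if name not in out.variables or rate == 0.0:
            continue
        j = out.var_index(name)
        drop = rng.random(out.mask[:, :, j].shape) < rate
        out.mask[:, :, j] &= ~drop
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(cfg: SimConfig) -> tuple[pd.DataFrame, LongitudinalPanel]:
    """Generate a full synthetic cohort and its longitudinal panel.

    Returns
    -------
    cohort : DataFrame
        One row per patient: antecedents, day-1 acute physiology, outcomes,
        ``true_class`` (1-based) and the latent scores driving the hazard.
    panel : LongitudinalPanel
        patient x day x variable labs for days 1..n_days with MCAR
        missingness already applied (ground-truth values retained).
    """
    rng = np.random.default_rng(cfg.seed)
    n, t = cfg.n_patients, cfg.n_days
    g = cfg.n_classes

    classes = rng.choice(g, size=n, p=np.asarray(cfg.class_props))
    latent = latent_trajectories(cfg, classes, rng)
    totals = np.clip(np.round(latent), 0, _MAX_TOTAL).astype(int)
    sub = _decompose_total(totals, rng)  # (n, t, 6)
    labs = _invert_labs(sub, rng)

    # antecedents
    age = np.clip(np.round(rng.normal(65.0, 16.0, size=n)), 18, 100)
    sex = rng.integers(0, 2, size=n)
    comorb = {k: (rng.random(n) < p).astype(int) for k, p in _COMORBIDITY_PREV.items()}
    infection = rng.choice(
        list(_INFECTION_PROBS),
        size=n,
        p=np.array(list(_INFECTION_PROBS.values())) / sum(_INFECTION_PROBS.values()),
    )
    comorb_count = np.sum([v for v in comorb.values()], axis=0)
    antecedent_lp = 0.035 * (age - 65.0) + 0.7 * comorb_count
    antecedent_z = _standardize(antecedent_lp)

    day1_sofa = totals[:, 0].astype(float)
    acute_z = _standardize(day1_sofa)

    outcomes = simulate_outcomes(acute_z, antecedent_z, cfg, rng)

    # labs that drift with length of stay (catabolic signature of persistence)
    # within-stay catabolic drift for long-stayers; zero on day 1 so day-1
    # acute covariates carry no information about the eventual stay length
    stay_frac = np.clip(outcomes["icu_los"].to_numpy() / t, 0.0, 1.0)[:, None]
    day0 = np.arange(t, dtype=float)[None, :]
    trend = stay_frac * day0 / max(t - 1, 1)  # 0 on day 1, stay_frac on day n_days
    ucr = (
        rng.normal(15.0, 4.0, size=(n, 1))
        + cfg.ucr_drift * stay_frac * day0
        + rng.normal(0.0, 1.5, size=(n, t))
    )
    ucr = np.clip(ucr, 1.0, None)
    bun = ucr * labs["creatinine"]
    albumin = np.clip(2.7 - 0.6 * trend + rng.normal(0, 0.3, size=(n, t)), 1.0, 4.5)
    hemoglobin = np.clip(11.5 - 1.5 * trend + rng.normal(0, 1.2, size=(n, t)), 5.0, 17.0)
    crp = np.exp(rng.normal(np.log(80.0), 0.5, size=(n, t)))  # no group difference
    neutrophils = np.clip(9.0 + 3.5 * trend + rng.normal(0, 2.5, size=(n, t)), 0.5, None)
    lymphocytes = np.clip(1.2 - 0.35 * trend + rng.normal(0, 0.4, size=(n, t)), 0.05, None)

    panel_vals = {
        **labs,
        "sofa": totals.astype(float),
        "bun": bun,
        "albumin": albumin,
        "hemoglobin": hemoglobin,
        "crp": crp,
        "neutrophils": neutrophils,
        "lymphocytes": lymphocytes,
    }
    variables = schema.PANEL_VARIABLES
    values = np.stack([np.asarray(panel_vals[v], dtype=float) for v in variables], axis=2)
    panel = LongitudinalPanel(values, np.ones_like(values, dtype=bool), list(variables))
    panel = apply_missingness(panel, cfg.miss_rates, seed=int(rng.integers(2**31 - 1)))

    # day-1 acute covariates: SOFA-component labs + additional physiology
    # correlated with day-1 severity
    cohort = pd.DataFrame({"patient_id": np.arange(n)})
    for c in ("gcs", "bilirubin", "creatinine", "platelets", "pao2", "fio2",
              "mean_bp", "mech_vent"):
        cohort[c] = np.asarray(panel_vals[c])[:, 0]
    cohort["wbc"] = np.clip(13.0 + 2.0 * acute_z + rng.normal(0, 5.0, n), 0.5, None)
    cohort["temperature"] = 36.6 - 0.15 * acute_z + rng.normal(0, 0.5, n)
    cohort["resp_rate"] = np.clip(26 + 3.0 * acute_z + rng.normal(0, 7.0, n), 8, None)
    cohort["sodium"] = 138.0 + rng.normal(0, 6.5, n)
    cohort["heart_rate"] = np.clip(108 + 7.0 * acute_z + rng.normal(0, 16.0, n), 40, None)
    cohort["hematocrit"] = np.clip(31.0 - 0.5 * acute_z + rng.normal(0, 6.0, n), 12, 60)
    cohort["albumin"] = albumin[:, 0]
    cohort["bun"] = bun[:, 0]
    cohort["glucose"] = np.clip(163.0 + rng.normal(0, 100.0, n), 30, None)
    cohort["age"] = age
    cohort["sex"] = sex
    for k, v in comorb.items():
        cohort[k] = v
    cohort["infection_source"] = infection
    cohort["surgical"] = rng.integers(0, 2, size=n) * (rng.random(n) < 0.3)
    for col in outcomes.columns:
        cohort[col] = outcomes[col].to_numpy()
    cohort["true_class"] = classes + 1
    cohort["acute_score_true"] = acute_z
    cohort["antecedent_score_true"] = antecedent_z
    return cohort, panel


def write_outputs(cohort: pd.DataFrame, panel: LongitudinalPanel, cfg: SimConfig,
                  outdir: str | Path) -> dict[str, Path]:
    """Write cohort CSV, long-format panel CSV, and a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "panel": outdir / "panel.csv",
        "truth": outdir / "truth.json",
    }
    cohort.to_csv(paths["cohort"], index=False)
    panel.to_long().to_csv(paths["panel"], index=False)
    truth = {
        "true_class": cohort["true_class"].tolist(),
        "attenuation_day": cfg.attenuation_day,
        "config": json.loads(cfg.model_dump_json()),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
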