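"""Column-name contracts for cohort and panel tables.

A cohort table has one row per patient; a longitudinal panel is patient x day x
variable. Acute covariates are day-1 physiology reflecting the admitting
illness; antecedent covariates are pre-admission characteristics (age, sex,
chronic comorbidity flags).
"""

from __future__ import annotations

#: day-1 acute physiological covariates entering the "acute" prognostic family
ACUTE_COLS: list[str] = [
    "gcs",
    "bilirubin",
    "creatinine",
    "platelets",
    "pao2",
    "fio2",
    "mean_bp",
    "mech_vent",
    "wbc",
    "temperature",
    "resp_rate",
    "sodium",
    "heart_rate",
    "hematocrit",
    "albumin",
    "bun",
    "glucose",
]

COMORBIDITY_COLS: list[str] = [
    "aids",
    "hepatic_failure",
    "lymphoma",
    "metastatic_cancer",
    "leukemia",
    "immunosuppression",
    "cirrhosis",
]

#: antecedent covariates entering the "antecedent" prognostic family
ANTECEDENT_COLS: list[str] = ["age", "sex"] + COMORBIDITY_COLS

OUTCOME_COLS: list[str] = [
    "icu_los",
    "hosp_los",
    "hosp_death",
    "icu_death",
    "discharge_location",
]

ID_COL = "patient_id"
CLASS_COL = "true_class"

#: variables excluded from regression models regardless of completeness
FORCED_DROP_VARS: frozenset[str] = frozenset({"ph", "paco2", "urine_output"})

#: columns subject to the negative-vital-sign outlier rule
VITAL_SIGN_COLS: list[str] = [
    "heart_rate",
    "resp_rate",
    "temperature",
    "mean_bp",
]

INFECTION_SOURCES: list[str] = [
    "pulmonary",
    "renal_uti",
    "gi",
    "cutaneous",
    "gynecologic",
    "unknown",
    "other",
]

DISCHARGE_LOCATIONS: list[str] = [
    "death",
    "home",
    "skilled_nursing_facility",
    "nursing_home",
    "rehabilitation",
    "other_hospital",
    "other_external",
]

#: variables carried in the longitudinal panel (days 1..n_days)
PANEL_VARIABLES: list[str] = [
    "pao2",
    "fio2",
    "mech_vent",
    "platelets",
    "bilirubin",
    "mean_bp",
    "vasopressor",
    "gcs",
    "creatinine",
    "sofa",
    "bun",
    "albumin",
    "hemoglobin",
    "crp",
    "neutrophils",
    "lymphocytes",
]
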