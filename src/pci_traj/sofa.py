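"""SOFA organ-failure scoring from raw labs/vitals.

Six organ subscores (respiration, coagulation, liver, cardiovascular, CNS,
renal), each 0-4, summed to a 0-24 total. Cutoffs are shipped as a versioned
JSON fixture so the exact bands used are auditable. The cardiovascular
subscore is simplified to mean arterial pressure plus a binary vasopressor
flag (dose data are not part of the schema), which caps it at 2.

Also provides the urea-to-creatinine ratio, computed from BUN (mg/dl) over
creatinine (mg/dl); BUN is the nitrogen fraction of urea, so this is the
US-convention "BUN:creatinine" ratio, not the SI urea:creatinine ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SUBSCORES = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")


def load_cutoffs() -> dict[str, Any]:
    """Load the versioned SOFA cutoff table shipped with the package."""
    with resources.files("pci_traj.data").joinpath("sofa_cutoffs.json").open() as fh:
        return json.load(fh)


_CUTOFFS = load_cutoffs()


@dataclass(frozen=True)
class SofaDay:
    """One day's SOFA subscores and total."""

    respiration: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int

    @property
    def total(self) -> int:
        return (
            self.respiration
            + self.coagulation
            + self.liver
            + self.cardiovascular
            + self.cns
            + self.renal
        )

    def as_dict(self) -> dict[str, int]:
        d = {k: getattr(self, k) for k in _SUBSCORES}
        d["total"] = self.total
        return d


def _band_score_lower(value: float, lower_bounds: list[float]) -> int:
    """Score 0..len(bounds) where value >= bounds[k-1] means score < k."""
    score = 0
    for b in lower_bounds:
        if value < b:
            score += 1
        else:
            break
    return score


def _band_score_upper(value: float, upper_bounds: list[float]) -> int:
    score = 0
    for b in upper_bounds:
        if value >= b:
            score += 1
        else:
            break
    return score


def respiration_score(pao2: float, fio2: float, ventilated: bool,
                      cutoffs: Mapping[str, Any] | None = None) -> int:
    c = (cutoffs or _CUTOFFS)["respiration"]
    if not (0 < fio2 <= 1):
        raise ValueError(f"FiO2 must be in (0, 1], got {fio2}")
    if pao2 < 0:
        raise ValueError(f"PaO2 must be non-negative, got {pao2}")
    pf = pao2 / fio2
    score = _band_score_lower(pf, c["pf_lower_bounds"])
    if score >= c["vent_required_from_score"] and not ventilated:
        score = c["vent_required_from_score"] - 1
    return score


def coagulation_score(platelets: float, cutoffs: Mapping[str, Any] | None = None) -> int:
    if platelets < 0:
        raise ValueError(f"platelets must be non-negative, got {platelets}")
    c = (cutoffs or _CUTOFFS)["coagulation"]
    return _band_score_lower(platelets, c["platelet_lower_bounds"])


def liver_score(bilirubin: float, cutoffs: Mapping[str, Any] | None = None) -> int:
    if bilirubin < 0:
        raise ValueError(f"bilirubin must be non-negative, got {bilirubin}")
    c = (cutoffs or _CUTOFFS)["liver"]
    return _band_score_upper(bilirubin, c["bilirubin_upper_bounds"])


def cardiovascular_score(mean_bp: float, vasopressor: bool,
                         cutoffs: Mapping[str, Any] | None = None) -> int:
    if mean_bp < 0:
        raise ValueError(f"mean BP must be non-negative, got {mean_bp}")
    c = (cutoffs or _CUTOFFS)["cardiovascular"]
    if vasopressor:
        return int(c["vasopressor_score"])
    return 1 if mean_bp < c["map_threshold"] else 0


def cns_score(gcs: float, cutoffs: Mapping[str, Any] | None = None) -> int:
    if not (3 <= gcs <= 15):
        raise ValueError(f"GCS must be in [3, 15], got {gcs}")
    c = (cutoffs or _CUTOFFS)["cns"]
    return _band_score_lower(gcs, c["gcs_lower_bounds"])


def renal_score(creatinine: float, urine_output: float | None = None,
                use_urine: bool = False,
                cutoffs: Mapping[str, Any] | None = None) -> int:
    if creatinine < 0:
        raise ValueError(f"creatinine must be non-negative, got {creatinine}")
    c = (cutoffs or _CUTOFFS)["renal"]
    score = _band_score_upper(creatinine, c["creatinine_upper_bounds"])
    # urine-output criterion off by default: the analytic schema drops urine
    # output from model covariates, but the criterion is available when raw
    # data carry it
    if use_urine and urine_output is not None:
        if urine_output < 0:
            raise ValueError("urine output must be non-negative")
        ub = c["urine_bounds"]
        if urine_output < 200:
            score = max(score, ub["lt_200"])
        elif urine_output < 500:
            score = max(score, ub["lt_500"])
    return score


def sofa_subscores(day_labs: Mapping[str, Any], missing_policy: str = "zero",
                   use_urine: bool = False) -> SofaDay:
    """Compute the six SOFA subscores for one patient-day.

    Parameters
    ----------
    day_labs
        Mapping with any of the keys ``pao2, fio2, mech_vent, platelets,
        bilirubin, mean_bp, vasopressor, gcs, creatinine, urine_output``.
        ``None``/NaN values are treated as missing.
    missing_policy
        ``"zero"`` (default) scores a component with missing inputs as 0 and
        logs a warning; ``"error"`` raises.
    """

    def get(key: str):
        v = day_labs.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    def handle_missing(component: str) -> int:
        if missing_policy == "error":
            raise ValueError(f"missing inputs for SOFA component {component!r}")
        logger.warning("SOFA %s inputs missing; scored 0 by policy", component)
        return 0

    pao2, fio2 = get("pao2"), get("fio2")
    if pao2 is not None and fio2 is not None:
        resp = respiration_score(pao2, fio2, bool(get("mech_vent") or False))
    else:
        resp = handle_missing("respiration")

    plate = get("platelets")
    coag = coagulation_score(plate) if plate is not None else handle_missing("coagulation")

    bili = get("bilirubin")
    liver = liver_score(bili) if bili is not None else handle_missing("liver")

    mbp = get("mean_bp")
    if mbp is not None:
        cardio = cardiovascular_score(mbp, bool(get("vasopressor") or False))
    else:
        cardio = handle_missing("cardiovascular")

    gcs = get("gcs")
    cns = cns_score(gcs) if gcs is not None else handle_missing("cns")

    creat = get("creatinine")
    if creat is not None:
        renal = renal_score(creat, get("urine_output"), use_urine=use_urine)
    else:
        renal = handle_missing("renal")

    return SofaDay(resp, coag, liver, cardio, cns, renal)


def urea_creatinine_ratio(bun, creatinine):
    """BUN / creatinine, both in mg/dl. Vectorised over array inputs.

    Raises
    ------
    ValueError
        if any creatinine is <= 0 (the ratio is undefined).
    """
    bun = np.asarray(bun, dtype=float)
    creatinine = np.asarray(creatinine, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(creatinine[np.isfinite(creatinine)] <= 0):
            raise ValueError("urea-to-creatinine ratio undefined for creatinine <= 0")
    out = bun / creatinine
    return float(out) if out.ndim == 0 else out


def score_panel(panel_df: pd.DataFrame, missing_policy: str = "zero") -> pd.DataFrame:
    """Score every (patient, day) row of a wide panel DataFrame.

    ``panel_df`` needs columns ``patient_id, day`` plus the lab columns named
    in :func:`sofa_subscores`. Returns a DataFrame with patient_id, day, the
    six subscores and the total.
    """
    rows = []
    lab_cols = [c for c in panel_df.columns if c not in ("patient_id", "day")]
    for _, row in panel_df.iterrows():
        sd = sofa_subscores({c: row[c] for c in lab_cols}, missing_policy=missing_policy)
        rows.append({"patient_id": row["patient_id"], "day": row["day"], **sd.as_dict()})
    return pd.DataFrame(rows)
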