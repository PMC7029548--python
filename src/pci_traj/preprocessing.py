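"""Outlier exclusion, missingness screening, and imputation.

Three stages mirror a typical ICU-cohort cleaning pipeline:

1. :func:`filter_outliers` — physiologically impossible entries (negative
   vital signs, age > 200, negative urine output) are set to missing and
   logged, never silently altered.
2. :func:`screen_missingness` — variables with more than 10% missing values
   are excluded from model covariates; pH, PaCO2 and urine output are
   force-dropped regardless of completeness.
3. Imputation — longitudinal labs are imputed per patient-variable series by
   a polynomial-in-time weighted regression (observations near the missing
   day get more weight, tricube kernel); cross-sectional day-1 covariates are
   imputed by chained equations with regression/classification trees,
   drawing donors from terminal nodes (CART multiple imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .panel import LongitudinalPanel
from .schema import FORCED_DROP_VARS, VITAL_SIGN_COLS


def filter_outliers(records: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Set impossible values to missing and log each exclusion.

    Rules: vital signs < 0; age > 200; urine output < 0.
    """
    out = records.copy()
    log: list[dict] = []

    def flag(col: str, bad: pd.Series, rule: str) -> None:
        for idx in out.index[bad.fillna(False)]:
            log.append({"row": idx, "column": col, "value": out.at[idx, col], "rule": rule})
        out.loc[bad.fillna(False), col] = np.nan

    for col in VITAL_SIGN_COLS:
        if col in out.columns:
            flag(col, out[col] < 0, "negative vital sign")
    if "age" in out.columns:
        flag("age", out["age"] > 200, "age > 200")
    if "urine_output" in out.columns:
        flag("urine_output", out["urine_output"] < 0, "negative urine output")
    return out, log


@dataclass
class ScreenReport:
    """Result of the >10%-missing screen plus forced exclusions."""

    missing_fraction: dict[str, float]
    kept: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    forced_drop: list[str] = field(default_factory=list)
    threshold: float = 0.10

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "missing_fraction": self.missing_fraction,
            "kept": self.kept,
            "dropped": self.dropped,
            "forced_drop": self.forced_drop,
        }


def screen_missingness(table: pd.DataFrame, threshold: float = 0.10,
                       forced_drop: frozenset[str] | set[str] = FORCED_DROP_VARS
                       ) -> ScreenReport:
    """Partition variables into kept / dropped (> threshold missing) / forced-drop.

    The comparison is strict: a variable with missingness exactly at the
    threshold is kept.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if len(table) == 0:
        raise ValueError("empty table")
    report = ScreenReport(missing_fraction={}, threshold=threshold)
    for col in table.columns:
        frac = float(table[col].isna().mean())
        report.missing_fraction[col] = frac
        if col in forced_drop:
            report.forced_drop.append(col)
        elif frac > threshold:
            report.dropped.append(col)
        else:
            report.kept.append(col)
    return report


def _tricube(u: np.ndarray) -> np.ndarray:
    a = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - a**3) ** 3


def impute_longitudinal(panel: LongitudinalPanel, degree: int = 2) -> LongitudinalPanel:
    """Fill missing panel cells by per-series weighted polynomial regression.

    For each missing (patient, day, variable) cell the patient's observed
    values of that variable are regressed on day and day^2 with tricube
    weights decaying with distance from the target day (bandwidth = the
    panel's day span), and the fit is evaluated at the target day. Series
    with fewer than ``degree + 1`` observations fall back to the cohort's
    per-day mean of that variable. Observed cells are never altered.
    """
    out = panel.copy()
    days = out.days.astype(float)
    span = max(days[-1] - days[0], 1.0)
    design = np.vander(days, degree + 1, increasing=True)  # (T, degree+1)
    for j in range(len(out.variables)):
        vals = out.values[:, :, j]
        obs = out.mask[:, :, j]
        col_obs = np.where(obs, vals, np.nan)
        with np.errstate(invalid="ignore"):
            day_means = np.nanmean(col_obs, axis=0)
        day_means = np.where(np.isfinite(day_means), day_means,
                             np.nanmean(col_obs) if np.isfinite(col_obs).any() else 0.0)
        need_rows = np.nonzero(~obs.all(axis=1))[0]
        for i in need_rows:
            m = obs[i]
            missing_days = np.nonzero(~m)[0]
            if m.sum() < degree + 1:
                vals[i, missing_days] = day_means[missing_days]
            else:
                X = design[m]
                y = vals[i, m]
                for d0 in missing_days:
                    w = _tricube((days[m] - days[d0]) / span)
                    sw = np.sqrt(np.maximum(w, 1e-12))
                    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
                    vals[i, d0] = design[d0] @ coef
            out.mask[i, missing_days, j] = True
    return out


def impute_cross_sectional(table: pd.DataFrame, m: int = 5, seed: int = 0,
                           n_iter: int = 10, min_samples_leaf: int = 5
                           ) -> list[pd.DataFrame]:
    """CART-based multiple imputation by chained equations.

    Each incomplete variable is imputed by a regression (numeric) or
    classification (categorical) tree fit on all other variables; imputed
    values are drawn uniformly from the observed donors in the terminal node
    the incomplete row lands in. Returns ``m`` completed tables; observed
    cells are identical across them.
    """
    rng = np.random.default_rng(seed)
    incomplete = [c for c in table.columns if table[c].isna().any()]
    for c in incomplete:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing; screen it out first")
    if not incomplete:
        return [table.copy() for _ in range(m)]

    numeric = {c: pd.api.types.is_numeric_dtype(table[c]) for c in table.columns}
    completed: list[pd.DataFrame] = []
    for _ in range(m):
        work = table.copy()
        # initialize each hole with a random observed donor of its column
        for c in incomplete:
            miss = work[c].isna()
            donors = work.loc[~miss, c].to_numpy()
            work.loc[miss, c] = rng.choice(donors, size=int(miss.sum()))
        for _ in range(n_iter):
            for c in incomplete:
                miss = table[c].isna().to_numpy()
                predictors = [p for p in table.columns if p != c]
                X = pd.get_dummies(work[predictors], drop_first=True).to_numpy(dtype=float)
                y_obs = work.loc[~miss, c].to_numpy()
                tree_cls = DecisionTreeRegressor if numeric[c] else DecisionTreeClassifier
                tree = tree_cls(min_samples_leaf=min_samples_leaf,
                                random_state=int(rng.integers(2**31 - 1)))
                tree.fit(X[~miss], y_obs)
                leaves_obs = tree.apply(X[~miss])
                leaves_mis = tree.apply(X[miss])
                drawn = np.empty(leaves_mis.shape[0],
                                 dtype=float if numeric[c] else object)
                for k, leaf in enumerate(leaves_mis):
                    pool = y_obs[leaves_obs == leaf]
                    drawn[k] = pool[rng.integers(len(pool))]
                work.loc[miss, c] = drawn
        completed.append(work)
    return completed
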