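"""Biochemical signatures of persistent critical illness.

Compares lab trajectories over days 1..10 between PCI and non-PCI patients
(two-sided Wilcoxon rank-sum per day) and computes the urea-to-creatinine
change matrix: within-patient later-minus-earlier differences for every
ordered day pair, summarised as group medians/IQRs with a rank-sum p-value
per cell. No multiplicity correction is applied by default, matching the
presentation style of the underlying heatmap/figure conventions; a
Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LongitudinalPanel
from .sofa import urea_creatinine_ratio

DEFAULT_VARIABLES = (
    "sofa",
    "albumin",
    "hemoglobin",
    "crp",
    "nl_ratio",
    "ucr",
)

_STARS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_stars(p: float) -> str:
    for cut, s in _STARS:
        if p < cut:
            return s
    return ""


def _ranksum(a: np.ndarray, b: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        return np.nan
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: identical constant groups
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _derived_matrix(panel: LongitudinalPanel, name: str) -> np.ndarray:
    """(n, days) matrix for a panel variable or a derived ratio; NaN = missing."""
    if name == "ucr":
        bun = panel.get("bun")
        creat = panel.get("creatinine")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = bun / creat
        out[~np.isfinite(out)] = np.nan
        return out
    if name == "nl_ratio":
        neut = panel.get("neutrophils")
        lymph = panel.get("lymphocytes")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(lymph > 0, neut / lymph, np.nan)
        return out
    return panel.get(name)  # raises KeyError naming the variable


def daily_group_compare(panel: LongitudinalPanel, pci_flags: np.ndarray,
                        variables: tuple[str, ...] = DEFAULT_VARIABLES,
                        bh_correct: bool = False) -> pd.DataFrame:
    """Per-day PCI vs non-PCI comparison for each variable.

    Returns a long frame with day, variable, group medians and counts, the
    two-sided rank-sum p-value and its star code. Days where either group is
    empty are marked not computable (NaN p).
    """
    flags = np.asarray(pci_flags, dtype=bool)
    if flags.shape[0] != panel.n_patients:
        raise ValueError("pci_flags length must match the panel")
    rows = []
    for var in variables:
        mat = _derived_matrix(panel, var)
        for d in range(panel.n_days):
            a = mat[flags, d]
            b = mat[~flags, d]
            p = _ranksum(a, b)
            rows.append({
                "day": d + 1,
                "variable": var,
                "median_pci": float(np.nanmedian(a)) if np.isfinite(a).any() else np.nan,
                "median_non_pci": float(np.nanmedian(b)) if np.isfinite(b).any() else np.nan,
                "n_pci": int(np.isfinite(a).sum()),
                "n_non_pci": int(np.isfinite(b).sum()),
                "p": p,
            })
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        valid = out["p"].notna()
        adj = out["p"].copy()
        adj[valid] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
        out["p_adj"] = adj
        out["stars"] = [p_stars(p) if np.isfinite(p) else "" for p in out["p_adj"]]
    else:
        out["stars"] = [p_stars(p) if np.isfinite(p) else "" for p in out["p"]]
    return out


@dataclass
class ChangeMatrix:
    """Urea-to-creatinine change summaries for all ordered day pairs."""

    table: pd.DataFrame  # ref_day, day, group, n, median, q1, q3, p

    def median_grid(self, group: str = "pci") -> pd.DataFrame:
        """Heatmap-ready grid of median changes; cells at or below the
        diagonal are zero by convention."""
        sub = self.table[self.table["group"] == group]
        days = sorted(set(sub["day"]) | set(sub["ref_day"]))
        grid = pd.DataFrame(0.0, index=days, columns=days)
        for _, r in sub.iterrows():
            grid.loc[r["ref_day"], r["day"]] = r["median"]
        return grid


def ucr_change_matrix(panel: LongitudinalPanel, pci_flags: np.ndarray,
                      icu_los: np.ndarray, min_icu_days: int = 2) -> ChangeMatrix:
    """Within-patient later-minus-earlier urea-to-creatinine changes.

    Patients with an ICU stay shorter than ``min_icu_days`` are excluded (no
    within-stay comparison is possible for them). For each ordered day pair
    (r < c) and each group (total / non-PCI / PCI), the median and IQR of
    the per-patient day-c minus day-r ratio difference is reported over
    patients observed on both days, with a two-sided rank-sum p-value
    between groups.
    """
    flags = np.asarray(pci_flags, dtype=bool)
    icu_los = np.asarray(icu_los, dtype=float)
    keep = icu_los >= min_icu_days
    bun = panel.get("bun")[keep]
    creat = panel.get("creatinine")[keep]
    flags = flags[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = bun / creat
    ratio[~np.isfinite(ratio)] = np.nan

    rows = []
    t = ratio.shape[1]
    for r in range(t - 1):
        for c in range(r + 1, t):
            diff = ratio[:, c] - ratio[:, r]
            groups = {"total": diff, "non_pci": diff[~flags], "pci": diff[flags]}
            p = _ranksum(diff[flags], diff[~flags])
            for gname, vals in groups.items():
                ok = np.isfinite(vals)
                if ok.any():
                    med = float(np.median(vals[ok]))
                    q1, q3 = (float(x) for x in np.percentile(vals[ok], [25, 75]))
                else:
                    med = q1 = q3 = np.nan
                rows.append({
                    "ref_day": r + 1, "day": c + 1, "group": gname,
                    "n": int(ok.sum()), "median": med, "q1": q1, "q3": q3, "p": p,
                })
    return ChangeMatrix(table=pd.DataFrame(rows))


# convenience re-export so callers comparing raw day-1 labs need one import
__all__ = [
    "daily_group_compare",
    "ucr_change_matrix",
    "ChangeMatrix",
    "p_stars",
    "urea_creatinine_ratio",
]
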