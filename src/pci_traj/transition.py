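"""The persistent-critical-illness transition estimator.

The operational definition: on each day ``d`` (1..horizon), two prognostic
families are compared on the risk set of patients still in hospital after
day ``d`` — a model on day-1 *acute* physiology and a model on *antecedent*
characteristics (age, sex, comorbidities), both predicting in-hospital
death. Each family is refit on ``iters`` random 70/30 splits (shared
between families, so replicates are paired) and scored by validation AUC.
The transition day is where the acute family stops being significantly
better: patients still in ICU beyond it are labelled as having persistent
critical illness (PCI), and their share of ICU/hospital bed-days quantifies
the resource burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import RidgeLogit
from . import schema


def mann_whitney_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC estimate; ties count one half.

    ``labels`` must contain both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def build_risk_set(cohort: pd.DataFrame, day: int,
                   acute_cols: list[str] | None = None,
                   antecedent_cols: list[str] | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrices and outcome for patients still in hospital after ``day``.

    Membership is strict: a patient with ``hosp_los == day`` has left.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    acute_cols = acute_cols or [c for c in schema.ACUTE_COLS if c in cohort.columns]
    antecedent_cols = antecedent_cols or [c for c in schema.ANTECEDENT_COLS if c in cohort.columns]
    risk = cohort[cohort["hosp_los"] > day]
    if len(risk) == 0:
        raise ValueError(f"empty risk set at day {day}")
    Xa = risk[acute_cols].to_numpy(dtype=float)
    Xz = risk[antecedent_cols].to_numpy(dtype=float)
    y = risk["hosp_death"].to_numpy(dtype=int)
    return Xa, Xz, y


@dataclass
class AucSeries:
    """Replicate validation AUCs for both model families, day by day."""

    horizon: int
    iters: int
    auc_acute: dict[int, np.ndarray] = field(default_factory=dict)
    auc_antecedent: dict[int, np.ndarray] = field(default_factory=dict)
    risk_n: dict[int, int] = field(default_factory=dict)
    risk_events: dict[int, int] = field(default_factory=dict)
    evaluable: dict[int, bool] = field(default_factory=dict)
    reason: dict[int, str] = field(default_factory=dict)

    @property
    def n_model_specs(self) -> int:
        """Two model specifications (acute, antecedent) per day."""
        return 2 * self.horizon

    @property
    def evaluable_days(self) -> list[int]:
        return [d for d in range(1, self.horizon + 1) if self.evaluable.get(d)]

    def paired_pvalues(self) -> dict[int, float]:
        """One-sided paired t-test p-value (acute > antecedent) per evaluable day."""
        out = {}
        for d in self.evaluable_days:
            diff = self.auc_acute[d] - self.auc_antecedent[d]
            if diff.std(ddof=1) == 0:
                out[d] = 0.0 if diff.mean() > 0 else 1.0
            else:
                out[d] = float(stats.ttest_1samp(diff, 0.0, alternative="greater").pvalue)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long frame: day, family, replicate, auc (evaluable days only)."""
        rows = []
        for d in self.evaluable_days:
            for fam, arr in (("acute", self.auc_acute[d]),
                             ("antecedent", self.auc_antecedent[d])):
                for r, a in enumerate(arr):
                    rows.append((d, fam, r, a))
        return pd.DataFrame(rows, columns=["day", "family", "replicate", "auc"])


def bootstrap_auc_series(cohort: pd.DataFrame, horizon: int = 28, iters: int = 100,
                         train_frac: float = 0.7, seed: int = 0, min_events: int = 10,
                         acute_cols: list[str] | None = None,
                         antecedent_cols: list[str] | None = None,
                         lam: float = 1e-4) -> AucSeries:
    """Repeated split-sample AUCs for the acute and antecedent families.

    For each day 1..horizon, ``iters`` random 70/30 splits are drawn; both
    families are fit on the same training part (ridge-stabilised logistic
    regression) and scored by validation AUC, so the ``iters`` replicate
    pairs share their splits. Days whose risk set — or any validation fold —
    has fewer than ``min_events`` deaths or survivors are marked
    non-evaluable with a reason. Deterministic given ``seed``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    acute_cols = acute_cols or [c for c in schema.ACUTE_COLS if c in cohort.columns]
    antecedent_cols = antecedent_cols or [c for c in schema.ANTECEDENT_COLS if c in cohort.columns]
    series = AucSeries(horizon=horizon, iters=iters)
    day_seeds = np.random.SeedSequence(seed).spawn(horizon)

    hosp_los = cohort["hosp_los"].to_numpy()
    y_all = cohort["hosp_death"].to_numpy(dtype=int)
    Xa_all = cohort[acute_cols].to_numpy(dtype=float)
    Xz_all = cohort[antecedent_cols].to_numpy(dtype=float)

    for day in range(1, horizon + 1):
        sel = hosp_los > day
        n_d = int(sel.sum())
        y = y_all[sel]
        events = int(y.sum())
        series.risk_n[day] = n_d
        series.risk_events[day] = events
        if iters < 2:
            series.evaluable[day] = False
            series.reason[day] = "needs >= 2 replicates for a paired comparison"
            continue
        if events < min_events or (n_d - events) < min_events:
            series.evaluable[day] = False
            series.reason[day] = "risk set below min_events"
            continue
        Xa, Xz = Xa_all[sel], Xz_all[sel]
        rng = np.random.default_rng(day_seeds[day - 1])
        n_train = int(round(train_frac * n_d))
        auc_a = np.empty(iters)
        auc_z = np.empty(iters)
        ok = True
        for it in range(iters):
            perm = rng.permutation(n_d)
            tr, va = perm[:n_train], perm[n_train:]
            ev_va = int(y[va].sum())
            if (ev_va < min_events or (len(va) - ev_va) < min_events
                    or y[tr].sum() in (0, len(tr))):
                series.evaluable[day] = False
                series.reason[day] = "sparse validation fold"
                ok = False
                break
            ma = RidgeLogit(lam=lam).fit(Xa[tr], y[tr])
            mz = RidgeLogit(lam=lam).fit(Xz[tr], y[tr])
            auc_a[it] = mann_whitney_auc(ma.decision_function(Xa[va]), y[va])
            auc_z[it] = mann_whitney_auc(mz.decision_function(Xz[va]), y[va])
        if not ok:
            continue
        series.auc_acute[day] = auc_a
        series.auc_antecedent[day] = auc_z
        series.evaluable[day] = True
    return series


def transition_day(series: AucSeries, alpha: float = 0.05, persistence: int = 3,
                   convention: str = "last_significant") -> int | None:
    """Locate the day the acute family stops out-predicting the antecedent one.

    Per evaluable day a one-sided paired t-test across the replicate AUC
    differences (H1: acute > antecedent) is evaluated at ``alpha``. The
    transition day is the last day of the initial run of significant days;
    a loss of significance only counts if it persists for ``persistence``
    consecutive evaluable days (or to the end of the horizon), guarding
    against isolated flips.

    Returns 0 if the very first evaluable day is already non-significant
    ("transition before day 1") and ``None`` if significance is never lost
    within the horizon. ``convention="first_nonsignificant"`` instead
    reports the first day of the confirmed non-significant run.
    """
    days = series.evaluable_days
    if not days:
        raise ValueError("no evaluable days")
    pvals = series.paired_pvalues()
    sig = [pvals[d] < alpha for d in days]
    if not sig[0]:
        return 0
    last_sig = days[0]
    i = 1
    while i < len(days):
        if sig[i]:
            last_sig = days[i]
            i += 1
            continue
        # candidate loss at days[i]: require `persistence` consecutive
        # non-significant evaluable days, or the run to reach the end
        run = 1
        j = i + 1
        while j < len(days) and not sig[j] and run < persistence:
            run += 1
            j += 1
        confirmed = run >= persistence or j >= len(days)
        if confirmed:
            return last_sig if convention == "last_significant" else days[i]
        # isolated flip: resume from the significant day that ended the run
        i = j
    return None


@dataclass
class TransitionResult:
    """PCI labelling and bed-day attribution for one (sub)cohort."""

    subset: str
    transition_day: int | None
    pci_flags: np.ndarray
    pci_count: int
    pci_share: float
    icu_bedday_share: float
    hosp_bedday_share: float

    def as_dict(self) -> dict:
        return {
            "subset": self.subset,
            "transition_day": self.transition_day,
            "pci_count": self.pci_count,
            "pci_share": self.pci_share,
            "icu_bedday_share": self.icu_bedday_share,
            "hosp_bedday_share": self.hosp_bedday_share,
        }


def label_pci(cohort: pd.DataFrame, transition_day: int,
              subset: str = "overall") -> TransitionResult:
    """Flag patients still in ICU after the transition day and attribute bed-days.

    A patient develops PCI iff ``icu_los > transition_day``. Shares are the
    flagged patients' bed-days over everyone's bed-days (integer LOS as
    recorded, no partial days), separately for ICU and hospital.
    """
    if transition_day is None:
        raise ValueError("transition day undefined (never lost within horizon)")
    icu = cohort["icu_los"].to_numpy(dtype=float)
    hosp = cohort["hosp_los"].to_numpy(dtype=float)
    flags = icu > transition_day
    return TransitionResult(
        subset=subset,
        transition_day=transition_day,
        pci_flags=flags,
        pci_count=int(flags.sum()),
        pci_share=float(flags.mean()),
        icu_bedday_share=float(icu[flags].sum() / icu.sum()) if icu.sum() else 0.0,
        hosp_bedday_share=float(hosp[flags].sum() / hosp.sum()) if hosp.sum() else 0.0,
    )


@dataclass
class SubsetTransition:
    """Full transition run for one patient subset (or a reason it was skipped)."""

    label: str
    series: AucSeries | None = None
    transition_day: int | None = None
    result: TransitionResult | None = None
    skipped_reason: str | None = None


def transition_by_subset(cohort: pd.DataFrame, labels, min_subset_n: int = 200,
                         **kwargs) -> dict[str, SubsetTransition]:
    """Rerun the full transition procedure inside each patient subset.

    ``labels`` is a per-patient grouping (e.g. latent class, infection
    source, surgical status). Subsets smaller than ``min_subset_n`` or with
    no deaths/survivors are skipped with a reason. Extra keyword arguments
    are forwarded to :func:`bootstrap_auc_series` / :func:`transition_day`.
    """
    labels = pd.Series(np.asarray(labels), index=cohort.index)
    alpha = kwargs.pop("alpha", 0.05)
    persistence = kwargs.pop("persistence", 3)
    convention = kwargs.pop("convention", "last_significant")
    out: dict[str, SubsetTransition] = {}
    for val in sorted(labels.unique(), key=str):
        key = str(val)
        sub = cohort[labels == val]
        if len(sub) < min_subset_n:
            out[key] = SubsetTransition(key, skipped_reason="subset below minimum size")
            continue
        deaths = int(sub["hosp_death"].sum())
        if deaths == 0:
            out[key] = SubsetTransition(key, skipped_reason="no events")
            continue
        if deaths == len(sub):
            out[key] = SubsetTransition(key, skipped_reason="no survivors")
            continue
        series = bootstrap_auc_series(sub, **kwargs)
        try:
            day = transition_day(series, alpha=alpha, persistence=persistence,
                                 convention=convention)
        except ValueError:
            out[key] = SubsetTransition(key, series=series,
                                        skipped_reason="no evaluable days")
            continue
        result = label_pci(sub, day, subset=key) if day is not None else None
        out[key] = SubsetTransition(key, series=series, transition_day=day, result=result)
    return out
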