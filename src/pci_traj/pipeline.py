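"""End-to-end orchestration: simulate -> preprocess -> score -> mixture ->
transition (overall and per class) -> Cox -> signatures, with a summary
report. Every stage writes plain CSV/JSON so any stage can be rerun from
saved intermediates."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import mixture, preprocessing, signatures, survival, synthetic, transition
from .config import PipelineConfig
from .panel import LongitudinalPanel

logger = logging.getLogger(__name__)


def cohort_summary(cohort: pd.DataFrame, pci_flags: np.ndarray | None = None) -> dict:
    """Headline cohort numbers: mortality, PCI burden, bed-day shares.

    Percentages are rounded to one decimal for report parity; raw fractions
    are included alongside.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    deaths = int(cohort["hosp_death"].sum())
    out = {
        "n_patients": n,
        "deaths": deaths,
        "mortality_fraction": deaths / n,
        "mortality_pct": round(100.0 * deaths / n, 1),
    }
    if pci_flags is not None:
        flags = np.asarray(pci_flags, dtype=bool)
        icu = cohort["icu_los"].to_numpy(dtype=float)
        hosp = cohort["hosp_los"].to_numpy(dtype=float)
        pci_n = int(flags.sum())
        out.update({
            "pci_count": pci_n,
            "pci_fraction": pci_n / n,
            "pci_pct": round(100.0 * pci_n / n, 1),
            "icu_bedday_share_pct": round(100.0 * icu[flags].sum() / icu.sum(), 1)
            if icu.sum() else 0.0,
            "hosp_bedday_share_pct": round(100.0 * hosp[flags].sum() / hosp.sum(), 1)
            if hosp.sum() else 0.0,
            "mortality_pci_pct": round(100.0 * cohort.loc[flags, "hosp_death"].mean(), 1)
            if pci_n else float("nan"),
            "mortality_non_pci_pct": round(
                100.0 * cohort.loc[~flags, "hosp_death"].mean(), 1)
            if pci_n < n else float("nan"),
        })
    return out


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order and write a report bundle.

    Deterministic given the seeds in ``cfg``. A stage failure raises with
    the stage name; files written by earlier stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s starting", name)
        report["stages"].append({"stage": name, "t": round(time.time() - t0, 2)})

    try:
        stage("load")
        if cfg.sim is not None:
            cohort, panel = synthetic.generate_cohort(cfg.sim)
            synthetic.write_outputs(cohort, panel, cfg.sim, outdir)
        else:
            cohort = pd.read_csv(cfg.cohort_csv)
            panel = LongitudinalPanel.from_long(pd.read_csv(cfg.panel_csv))

        stage("preprocess")
        cohort, outlier_log = preprocessing.filter_outliers(cohort)
        screen = preprocessing.screen_missingness(
            cohort.drop(columns=["patient_id", "discharge_location", "infection_source"],
                        errors="ignore"))
        (outdir / "screen_report.json").write_text(json.dumps(screen.as_dict(), indent=1))
        panel = preprocessing.impute_longitudinal(panel)
        model_cols = [c for c in screen.kept if cohort[c].isna().any()]
        if model_cols:
            cohort_imp = preprocessing.impute_cross_sectional(
                cohort[screen.kept], m=1, seed=cfg.seed + 11)[0]
            cohort = cohort.assign(**{c: cohort_imp[c] for c in screen.kept})

        sofa_mat = panel.get("sofa")
        model = None
        if cfg.run_mixture:
            stage("mixture")
            fits = []
            rows = []
            for g in range(1, cfg.gmax + 1):
                m = mixture.fit_lgmm(sofa_mat, G=g, seed=cfg.seed + g,
                                     n_starts=cfg.n_starts)
                s = mixture.fit_stats(m, panel.n_patients)
                fits.append((m, s))
                rows.append({"G": g, "loglik": m.loglik, "aic": s.aic, "bic": s.bic,
                             "sabic": s.sabic, "entropy": s.entropy,
                             **{f"share_{k+1}": v for k, v in enumerate(s.class_share)}})
            pd.DataFrame(rows).to_csv(outdir / "mixture_selection.csv", index=False)
            try:
                model = mixture.select_model(fits, min_class_n=cfg.min_class_n)
            except ValueError:
                model = fits[0][0]  # fall back to G=1 if nothing admissible
            pd.DataFrame({
                "patient_id": cohort["patient_id"],
                "assigned_class": model.assignments,
            }).to_csv(outdir / "class_assignments.csv", index=False)
            report["selected_G"] = model.G

        result = None
        if cfg.run_transition:
            stage("transition")
            series = transition.bootstrap_auc_series(
                cohort, horizon=cfg.horizon, iters=cfg.iters, seed=cfg.seed + 100)
            series.to_frame().to_csv(outdir / "auc_series.csv", index=False)
            day = transition.transition_day(series, alpha=cfg.alpha)
            report["transition_day"] = day
            if day is not None:
                result = transition.label_pci(cohort, day)
                (outdir / "transition.json").write_text(
                    json.dumps(result.as_dict(), indent=1))
            if model is not None:
                per_class = transition.transition_by_subset(
                    cohort, model.assignments, min_subset_n=cfg.min_class_n,
                    horizon=cfg.horizon, iters=cfg.iters, seed=cfg.seed + 200,
                    alpha=cfg.alpha)
                report["per_class_transition"] = {
                    k: (v.transition_day if v.skipped_reason is None else v.skipped_reason)
                    for k, v in per_class.items()
                }

        if cfg.run_survival:
            stage("survival")
            scores = survival.build_scores(cohort)
            episodes = survival.expand_episodes(
                cohort["hosp_los"].to_numpy(dtype=float),
                cohort["hosp_death"].to_numpy(dtype=int))
            fit = survival.fit_tdc_cox(episodes, scores)
            fit.table.to_csv(outdir / "tdc_cox.csv", index=False)
            report["tdc_cox_converged"] = fit.converged

        if cfg.run_signatures and result is not None:
            stage("signatures")
            comp = signatures.daily_group_compare(panel, result.pci_flags)
            comp.to_csv(outdir / "daily_signatures.csv", index=False)
            cm = signatures.ucr_change_matrix(
                panel, result.pci_flags, cohort["icu_los"].to_numpy())
            cm.table.to_csv(outdir / "ucr_change_matrix.csv", index=False)

        stage("summary")
        flags = result.pci_flags if result is not None else None
        report["summary"] = cohort_summary(cohort, flags)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        return report
    except Exception as exc:
        failed = report["stages"][-1]["stage"] if report["stages"] else "init"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc
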