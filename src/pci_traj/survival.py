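"""Step-function time-varying-coefficient Cox model on aggregated scores.

Acute and antecedent covariates are first collapsed into per-patient scores
(standardised linear predictors of family-specific logistic fits on the full
cohort), then entered into a Cox model whose coefficients are constant
within the day intervals (0-2], (2-3], (3-7], (7-14], (14-21], (21, inf) —
the 48 h / 72 h / 7 d / 14 d / 21 d grid expressed in days. Follow-up is
expanded to counting-process (start, stop] rows so that each interval gets
its own pair of coefficients, and the Breslow-ties partial likelihood is
maximised by Newton-Raphson with confidence intervals from the inverse
observed information. Discharge alive is treated as right-censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._glm import RidgeLogit
from . import schema

#: default interval boundaries in days (48 h, 72 h, 7 d, 14 d, 21 d)
DEFAULT_BOUNDARIES = (2.0, 3.0, 7.0, 14.0, 21.0)


@dataclass
class ScorePair:
    """Standardised per-patient acute and antecedent prognostic scores."""

    acute: np.ndarray
    antecedent: np.ndarray
    acute_coef: pd.Series
    antecedent_coef: pd.Series


def _logistic_lp(X: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[np.ndarray, pd.Series]:
    if np.any(X.std(axis=0) == 0):
        zero = [names[j] for j in np.nonzero(X.std(axis=0) == 0)[0]]
        raise ValueError(f"constant covariates have no predictive variance: {zero}")
    Xc = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or not res.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError
        lp = Xc @ res.params
        coef = pd.Series(res.params[1:], index=names)
    except (np.linalg.LinAlgError, Exception):  # separation etc. -> ridge fallback
        m = RidgeLogit(lam=1e-3).fit(X, y)
        lp = m.decision_function(X)
        coef = pd.Series(m.coef_ / m.scale_, index=names)
    return np.asarray(lp, dtype=float), coef


def build_scores(cohort: pd.DataFrame,
                 acute_cols: list[str] | None = None,
                 antecedent_cols: list[str] | None = None) -> ScorePair:
    """Aggregate each covariate family into one standardised score per patient.

    Two logistic regressions of in-hospital death — one on acute day-1
    physiology, one on antecedent characteristics — provide linear
    predictors, which are standardised to mean 0, SD 1 so downstream hazard
    ratios are per-SD of score.
    """
    acute_cols = acute_cols or [c for c in schema.ACUTE_COLS if c in cohort.columns]
    antecedent_cols = antecedent_cols or [c for c in schema.ANTECEDENT_COLS if c in cohort.columns]
    y = cohort["hosp_death"].to_numpy(dtype=float)
    lpa, ca = _logistic_lp(cohort[acute_cols].to_numpy(dtype=float), y, acute_cols)
    lpz, cz = _logistic_lp(cohort[antecedent_cols].to_numpy(dtype=float), y, antecedent_cols)

    def std(x):
        return (x - x.mean()) / x.std()

    return ScorePair(acute=std(lpa), antecedent=std(lpz), acute_coef=ca, antecedent_coef=cz)


def expand_episodes(times: np.ndarray, events: np.ndarray,
                    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES) -> pd.DataFrame:
    """Split each patient's follow-up at the interval boundaries.

    Returns counting-process rows (patient, interval, start, stop, event)
    with one row per interval overlapped; the event flag sits only on the
    final row. Total at-risk time is conserved.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if np.any(times <= 0):
        raise ValueError("follow-up times must be positive")
    edges = [0.0, *boundaries, np.inf]
    rows = []
    for i, (t, e) in enumerate(zip(times, events)):
        for k in range(len(edges) - 1):
            lo, hi = edges[k], edges[k + 1]
            if t <= lo:
                break
            stop = min(t, hi)
            rows.append((i, k, lo, stop, int(e and stop == t)))
    return pd.DataFrame(rows, columns=["patient", "interval", "start", "stop", "event"])


def _breslow_quantities(beta, start, stop, event, X):
    """Penalty-free Breslow partial log-likelihood, score and information.

    Risk-set sums over (start < t <= stop) are assembled with sorted
    cumulative sums, O(m log m) per call.
    """
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    ts = stop[event == 1]
    uniq, counts = np.unique(ts, return_counts=True)

    order_start = np.argsort(start, kind="stable")
    order_stop = np.argsort(stop, kind="stable")
    cs0_start = np.concatenate([[0.0], np.cumsum(w[order_start])])
    cs0_stop = np.concatenate([[0.0], np.cumsum(w[order_stop])])
    cs1_start = np.vstack([np.zeros(X.shape[1]), np.cumsum(wx[order_start], axis=0)])
    cs1_stop = np.vstack([np.zeros(X.shape[1]), np.cumsum(wx[order_stop], axis=0)])
    p = X.shape[1]
    cs2_start = np.concatenate([np.zeros((1, p, p)), np.cumsum(wxx[order_start], axis=0)])
    cs2_stop = np.concatenate([np.zeros((1, p, p)), np.cumsum(wxx[order_stop], axis=0)])

    n_in = np.searchsorted(start[order_start], uniq, side="left")
    n_out = np.searchsorted(stop[order_stop], uniq, side="left")
    S0 = cs0_start[n_in] - cs0_stop[n_out]
    S1 = cs1_start[n_in] - cs1_stop[n_out]
    S2 = cs2_start[n_in] - cs2_stop[n_out]
    S0 = np.maximum(S0, 1e-300)

    # per-unique-time sums of eta and x over the tied events
    ev_idx = np.nonzero(event == 1)[0]
    tie_group = np.searchsorted(uniq, stop[ev_idx])
    ll = float(eta[ev_idx].sum() - np.sum(counts * np.log(S0)))
    grad = X[ev_idx].sum(axis=0) - np.einsum("u,up->p", counts / S0, S1)
    mean = S1 / S0[:, None]
    info = (np.einsum("u,upq->pq", counts / S0, S2)
            - np.einsum("u,up,uq->pq", counts, mean, mean))
    _ = tie_group
    return ll, grad, info


@dataclass
class TdcCoxFit:
    """Per-interval hazard ratios for the acute and antecedent scores."""

    boundaries: tuple[float, ...]
    interval_labels: list[str]
    table: pd.DataFrame  # interval, score, coef, se, hr, hr_lo, hr_hi, p, n_events
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    dropped_intervals: list[int]


def _interval_labels(boundaries) -> list[str]:
    edges = [0.0, *boundaries]
    labels = [f"{edges[k]:g}-{edges[k+1]:g} days" for k in range(len(edges) - 1)]
    labels.append(f">{edges[-1]:g} days")
    return labels


def fit_tdc_cox(episodes: pd.DataFrame, scores: ScorePair,
                boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES,
                tol: float = 1e-9, max_iter: int = 50) -> TdcCoxFit:
    """Fit the step-function-coefficient Cox model on expanded episodes.

    The design interacts each score with the interval indicator, giving
    ``2 * n_intervals`` coefficients (acute first). Intervals without events
    are flagged and dropped from estimation. Newton-Raphson on the
    Breslow-ties partial likelihood; convergence when the relative
    log-likelihood change is below ``tol``.
    """
    n_int = len(boundaries) + 1
    patient = episodes["patient"].to_numpy(dtype=int)
    interval = episodes["interval"].to_numpy(dtype=int)
    start = episodes["start"].to_numpy(dtype=float)
    stop = episodes["stop"].to_numpy(dtype=float)
    event = episodes["event"].to_numpy(dtype=int)
    m = len(episodes)

    X = np.zeros((m, 2 * n_int))
    X[np.arange(m), 2 * interval] = scores.acute[patient]
    X[np.arange(m), 2 * interval + 1] = scores.antecedent[patient]

    events_per_interval = np.bincount(interval[event == 1], minlength=n_int)
    dropped = [k for k in range(n_int) if events_per_interval[k] == 0]
    # estimable columns: interval has events and the column has variation
    active = np.array(
        [j for j in range(2 * n_int)
         if j // 2 not in dropped and np.any(X[:, j] != 0.0)],
        dtype=int,
    )
    Xa = X[:, active]

    beta = np.zeros(active.size)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, info = _breslow_quantities(beta, start, stop, event, Xa)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            info = info + 1e-8 * np.eye(info.shape[0])
            step = np.linalg.solve(info, grad)
        # step-halving keeps the partial likelihood non-decreasing
        for _ in range(20):
            cand = beta + step
            ll_new, _, _ = _breslow_quantities(cand, start, stop, event, Xa)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if np.isfinite(ll_old) and abs(ll_new - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new

    ll_fin, grad_fin, info_fin = _breslow_quantities(beta, start, stop, event, Xa)
    cov_a = np.linalg.inv(info_fin)
    se_a = np.sqrt(np.diag(cov_a))

    coef = np.full(2 * n_int, np.nan)
    se = np.full(2 * n_int, np.nan)
    coef[active] = beta
    se[active] = se_a
    cov = np.full((2 * n_int, 2 * n_int), np.nan)
    cov[np.ix_(active, active)] = cov_a

    labels = _interval_labels(boundaries)
    rows = []
    from scipy import stats as sps

    for k in range(n_int):
        for s, name in ((0, "acute"), (1, "antecedent")):
            j = 2 * k + s
            b, sse = coef[j], se[j]
            if np.isnan(b):
                rows.append((labels[k], name, *([np.nan] * 6), int(events_per_interval[k])))
                continue
            z = b / sse
            rows.append((labels[k], name, b, sse, np.exp(b),
                         np.exp(b - 1.959963984540054 * sse),
                         np.exp(b + 1.959963984540054 * sse),
                         2 * sps.norm.sf(abs(z)), int(events_per_interval[k])))
    table = pd.DataFrame(rows, columns=["interval", "score", "coef", "se", "hr",
                                        "hr_lo", "hr_hi", "p", "n_events"])
    return TdcCoxFit(
        boundaries=boundaries, interval_labels=labels, table=table,
        coef=coef, cov=cov, loglik=ll_fin, converged=converged, n_iter=it,
        dropped_intervals=dropped,
    )


def coxph_counting(start, stop, event, X, tol: float = 1e-9, max_iter: int = 50):
    """Plain counting-process Cox fit (Breslow ties); returns (beta, cov, loglik).

    Shares the Newton machinery with :func:`fit_tdc_cox`; exposed for
    oracle-style comparisons against standard time-fixed Cox software.
    """
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event).astype(int)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, info = _breslow_quantities(beta, start, stop, event, X)
        step = np.linalg.solve(info, grad)
        for _ in range(20):
            ll_new, _, _ = _breslow_quantities(beta + step, start, stop, event, X)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if np.isfinite(ll_old) and abs(ll_new - ll_old) <= tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll_new
    ll, grad, info = _breslow_quantities(beta, start, stop, event, X)
    return beta, np.linalg.inv(info), ll
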