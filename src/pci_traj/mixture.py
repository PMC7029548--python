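"""Latent growth mixture model for daily SOFA trajectories.

The model: patient ``i`` in latent class ``g`` has

    y_it = b0g + b1g * t + b2g * t^2 + b_i + e_it,
    b_i ~ N(0, sigma_b^2),   e_it ~ N(0, sigma_e^2),

with class membership multinomial(pi). Class-specific quadratic fixed
effects, a shared random intercept and homoscedastic residuals keep the
M-step closed-form; SOFA is treated as a continuous Gaussian outcome.
Integrating the random intercept gives each patient an exchangeable
multivariate-normal likelihood contribution with covariance
``sigma_e^2 I + sigma_b^2 11'`` over that patient's observed days, which the
E-step evaluates in O(n_i) via the rank-one Woodbury identity.

Estimation is EM over (class, random intercept) as missing data: the
marginal log-likelihood is non-decreasing every iteration. Initialisation
clusters per-patient OLS quadratic coefficients by k-means; further starts
perturb that solution. Model choice follows information criteria subject to
a minimum class size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TrajectoryModel:
    """Fitted G-class growth mixture."""

    G: int
    beta: np.ndarray  # (G, 3): intercept, day, day^2
    sigma_b: float
    sigma_e: float
    pi: np.ndarray  # (G,)
    loglik: float
    posteriors: np.ndarray  # (n, G)
    assignments: np.ndarray  # (n,), modal class, 1-based
    converged: bool
    n_iter: int
    loglik_history: np.ndarray

    @property
    def n_params(self) -> int:
        return 3 * self.G + (self.G - 1) + 2

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.assignments - 1, minlength=self.G)


@dataclass
class FitStats:
    """Information criteria and classification entropy for one fitted model."""

    aic: float
    bic: float
    sabic: float
    entropy: float
    class_share: np.ndarray


def _prepare(y: np.ndarray, days: np.ndarray | None):
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be (n_patients, n_days)")
    n, t = y.shape
    if days is None:
        days = np.arange(1, t + 1, dtype=float)
    mask = np.isfinite(y)
    n_i = mask.sum(axis=1)
    if np.any(n_i < 1):
        raise ValueError("every patient needs at least one observed value")
    X = np.vander(days, 3, increasing=True)  # (t, 3): 1, day, day^2
    y0 = np.where(mask, y, 0.0)
    return y0, mask.astype(float), n_i.astype(float), X


def _patient_loglik(y0, mask, n_i, X, beta, sigma_b, sigma_e):
    """Per-patient per-class marginal log-density and residual sums.

    Returns (ll, s1, s2): each (n, G); s1/s2 are masked residual sums
    sum(r) and sum(r^2) used again by the M-step.
    """
    mu = X @ beta.T  # (t, G)
    r = y0[:, :, None] - mu[None, :, :]  # (n, t, G)
    r = r * mask[:, :, None]
    s1 = r.sum(axis=1)
    s2 = (r**2).sum(axis=1)
    ve, vb = sigma_e**2, sigma_b**2
    denom = ve + n_i * vb  # (n,)
    logdet = (n_i - 1.0) * np.log(ve) + np.log(denom)
    quad = (s2 - vb * s1**2 / denom[:, None]) / ve
    ll = -0.5 * (n_i[:, None] * _LOG2PI + logdet[:, None] + quad)
    return ll, s1, s2


def _em(y0, mask, n_i, X, beta, pi, sigma_b, sigma_e, tol, max_iter):
    """Run EM from one start; returns dict or None if a class degenerates."""
    n, t = y0.shape
    G = beta.shape[0]
    total_obs = n_i.sum()
    Sxy = np.einsum("nt,tp->np", y0 * mask, X)  # (n, 3)
    XtX_i = np.einsum("nt,tp,tq->npq", mask, X, X)  # (n, 3, 3)
    ones_x = np.einsum("nt,tp->np", mask, X)  # (n, 3): X' 1 over observed days

    history = []
    loglik = -np.inf
    for it in range(max_iter):
        ll, s1, s2 = _patient_loglik(y0, mask, n_i, X, beta, sigma_b, sigma_e)
        logw = np.log(np.maximum(pi, 1e-300))[None, :] + ll
        norm = logsumexp(logw, axis=1)
        new_loglik = float(norm.sum())
        post = np.exp(logw - norm[:, None])

        history.append(new_loglik)
        if it > 0 and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            return dict(beta=beta, pi=pi, sigma_b=sigma_b, sigma_e=sigma_e,
                        loglik=loglik, post=post, converged=True, n_iter=it + 1,
                        history=np.array(history))
        loglik = new_loglik

        # E-step moments of the random intercept given class
        ve, vb = sigma_e**2, sigma_b**2
        denom = ve + n_i * vb
        b_hat = vb * s1 / denom[:, None]  # (n, G)
        v_b = vb * ve / denom  # (n,)

        pi = post.mean(axis=0)
        if np.any(pi < 1.0 / n):
            return None  # degenerate class: caller restarts

        # M-step: class-specific WLS of (y - b_hat) on (1, t, t^2)
        new_beta = np.empty_like(beta)
        for gidx in range(G):
            w = post[:, gidx]
            A = np.einsum("n,npq->pq", w, XtX_i)
            rhs = np.einsum("n,np->p", w, Sxy - b_hat[:, gidx][:, None] * ones_x)
            new_beta[gidx] = np.linalg.solve(A, rhs)
        beta = new_beta

        # variance updates at the new beta, old b-moments (ECM; still monotone)
        _, s1n, s2n = _patient_loglik(y0, mask, n_i, X, beta, sigma_b, sigma_e)
        res_sq = s2n - 2.0 * b_hat * s1n + n_i[:, None] * b_hat**2
        sigma_e = float(np.sqrt(max(
            (np.sum(post * res_sq) + np.sum(post * (n_i * v_b)[:, None])) / total_obs,
            1e-8,
        )))
        sigma_b = float(np.sqrt(max(
            np.sum(post * (b_hat**2 + v_b[:, None])) / n, 1e-8
        )))

    ll, _, _ = _patient_loglik(y0, mask, n_i, X, beta, sigma_b, sigma_e)
    logw = np.log(np.maximum(pi, 1e-300))[None, :] + ll
    norm = logsumexp(logw, axis=1)
    post = np.exp(logw - norm[:, None])
    history.append(float(norm.sum()))
    return dict(beta=beta, pi=pi, sigma_b=sigma_b, sigma_e=sigma_e,
                loglik=float(norm.sum()), post=post, converged=False,
                n_iter=max_iter, history=np.array(history))


def _initial_params(y0, mask, n_i, X, G, rng):
    """k-means on per-patient OLS quadratic coefficients."""
    n = y0.shape[0]
    coefs = np.zeros((n, 3))
    for i in range(n):
        m = mask[i].astype(bool)
        if m.sum() >= 3:
            coefs[i], *_ = np.linalg.lstsq(X[m], y0[i, m], rcond=None)
        else:
            coefs[i] = [y0[i, m].mean() if m.any() else 0.0, 0.0, 0.0]
    if G == 1:
        labels = np.zeros(n, dtype=int)
    else:
        sd = coefs.std(axis=0)
        sd[sd == 0] = 1.0
        km = KMeans(n_clusters=G, n_init=3, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(coefs / sd)
    beta = np.zeros((G, 3))
    resid_var = []
    for gidx in range(G):
        sel = labels == gidx
        if sel.sum() == 0:
            sel = np.ones(n, dtype=bool)
        rows = np.nonzero(sel)[0]
        Xs = np.vstack([X[mask[i].astype(bool)] for i in rows])
        ys = np.concatenate([y0[i, mask[i].astype(bool)] for i in rows])
        beta[gidx], *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid_var.append(np.mean((ys - Xs @ beta[gidx]) ** 2))
    pi = np.bincount(labels, minlength=G).astype(float) + 1.0
    pi /= pi.sum()
    ve = float(np.mean(resid_var))
    sigma_e = np.sqrt(max(ve * 0.7, 1e-4))
    sigma_b = np.sqrt(max(ve * 0.3, 1e-4))
    return beta, pi, sigma_b, sigma_e


def fit_lgmm(y: np.ndarray, G: int, seed: int = 0, n_starts: int = 10,
             tol: float = 1e-6, max_iter: int = 500,
             days: np.ndarray | None = None) -> TrajectoryModel:
    """Fit a G-class growth mixture to a patient x day outcome array.

    Parameters
    ----------
    y
        (n_patients, n_days) array; NaN marks missing days. Every patient
        needs at least one observation.
    G
        Number of latent classes (>= 1).
    seed, n_starts
        The first start is the k-means initialisation; the rest perturb it.
        The best start by final log-likelihood is returned.

    Classes in the returned model are relabelled in decreasing mixing
    proportion for stable reporting.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    y0, mask, n_i, X = _prepare(y, days)
    rng = np.random.default_rng(seed)
    beta0, pi0, sb0, se0 = _initial_params(y0, mask, n_i, X, G, rng)

    best = None
    attempts = 0
    start = 0
    while start < n_starts and attempts < 3 * n_starts:
        attempts += 1
        if start == 0:
            beta, pi, sb, se = beta0.copy(), pi0.copy(), sb0, se0
        else:
            beta = beta0 + rng.normal(0, [1.5, 0.3, 0.03], size=beta0.shape)
            pi = rng.dirichlet(np.full(G, 5.0))
            sb, se = sb0 * rng.uniform(0.5, 2.0), se0 * rng.uniform(0.5, 2.0)
        res = _em(y0, mask, n_i, X, beta, pi, sb, se, tol, max_iter)
        if res is None:
            continue  # degenerate class; try a fresh perturbation
        start += 1
        if best is None or res["loglik"] > best["loglik"]:
            best = res
    if best is None:
        raise RuntimeError("all EM starts degenerated; reduce G")

    order = np.argsort(-best["pi"])
    beta = best["beta"][order]
    pi = best["pi"][order]
    post = best["post"][:, order]
    return TrajectoryModel(
        G=G, beta=beta, sigma_b=best["sigma_b"], sigma_e=best["sigma_e"], pi=pi,
        loglik=best["loglik"], posteriors=post,
        assignments=np.argmax(post, axis=1) + 1,
        converged=best["converged"], n_iter=best["n_iter"],
        loglik_history=best["history"],
    )


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    """(AIC, BIC, SABIC) from a log-likelihood, parameter count and sample size."""
    if n < 1:
        raise ValueError("n must be >= 1")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n)
    sabic = -2.0 * loglik + k * np.log((n + 2.0) / 24.0)
    return aic, bic, sabic


def relative_entropy(posteriors: np.ndarray) -> float:
    """Normalised classification entropy: 1 = crisp assignment, 0 = uninformative.

    Defined as ``1 - sum_i sum_g p_ig ln p_ig / (n ln G)``; 1 when G = 1.
    """
    n, G = posteriors.shape
    if G == 1:
        return 1.0
    p = np.clip(posteriors, 1e-300, 1.0)
    ent = -np.sum(p * np.log(p))
    return float(1.0 - ent / (n * np.log(G)))


def fit_stats(model: TrajectoryModel, n: int) -> FitStats:
    """Model-selection statistics for a fitted mixture."""
    aic, bic, sabic = information_criteria(model.loglik, model.n_params, n)
    return FitStats(
        aic=aic, bic=bic, sabic=sabic,
        entropy=relative_entropy(model.posteriors),
        class_share=model.class_counts / n,
    )


def select_model(fits: list[tuple[TrajectoryModel, FitStats]], min_class_n: int = 500,
                 criterion: str = "bic") -> TrajectoryModel:
    """Choose the class count.

    Only models whose smallest modal class has at least ``min_class_n``
    patients are admissible; among those the lowest value of ``criterion``
    (default BIC) wins, with ties broken toward fewer classes.
    """
    key = {"aic": "aic", "bic": "bic", "sabic": "sabic"}[criterion]
    admissible = [(m, s) for m, s in fits if m.class_counts.min() >= min_class_n]
    if not admissible:
        raise ValueError(f"no model satisfies the minimum class size {min_class_n}")
    admissible.sort(key=lambda ms: (getattr(ms[1], key), ms[0].G))
    return admissible[0][0]
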