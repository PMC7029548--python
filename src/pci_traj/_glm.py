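"""Small ridge-stabilised logistic regression (Newton/IRLS).

Used inside the bootstrap AUC loop, where thousands of fits per cohort make
a tight deterministic solver preferable, and as the separation fallback for
the score-building logistic models. The ridge penalty (default 1e-4 on
standardised slopes, none on the intercept) keeps late-day risk sets with
quasi-separation estimable.
"""

from __future__ import annotations

import numpy as np


class RidgeLogit:
    """Logistic regression with an L2 penalty on standardised coefficients."""

    def __init__(self, lam: float = 1e-4, max_iter: int = 25, tol: float = 1e-8):
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.coef_: np.ndarray | None = None  # on the standardised scale
        self.intercept_: float = 0.0
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeLogit":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        Z = (X - self.mean_) / sd
        n, p = Z.shape
        beta = np.zeros(p + 1)
        Z1 = np.column_stack([np.ones(n), Z])
        pen = np.full(p + 1, self.lam)
        pen[0] = 0.0
        ll_old = -np.inf
        for _ in range(self.max_iter):
            eta = Z1 @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            grad = Z1.T @ (y - mu) - pen * beta
            H = (Z1 * w[:, None]).T @ Z1
            H[np.diag_indices_from(H)] += pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step-halving on the penalised log-likelihood
            for _ in range(10):
                cand = beta + step
                eta_c = Z1 @ cand
                ll = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum()
                           - 0.5 * np.sum(pen * cand**2))
                if ll >= ll_old - 1e-12 or not np.isfinite(ll_old):
                    break
                step *= 0.5
            beta = beta + step
            if np.isfinite(ll_old) and abs(ll - ll_old) < self.tol * (abs(ll_old) + 1.0):
                ll_old = ll
                break
            ll_old = ll
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return self.intercept_ + Z @ self.coef_

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))
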