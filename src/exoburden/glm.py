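"""Logistic regression by IRLS and Firth-penalized logistic regression.

Both fitters are written against plain numpy design matrices and are the
computational core shared by the single-variant, gene-based and burden
comparisons. The Firth fit maximizes the Jeffreys-prior penalized
likelihood ``l(beta) + 0.5 log det I(beta)`` by Newton steps on the
modified score, which keeps estimates finite under complete separation;
its p-values come from the penalized likelihood-ratio test, matching the
convention of the R ``logistf`` package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_ITER = 100
TOL = 1e-8


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    mu: np.ndarray
    converged: bool
    separated: bool
    n_iter: int

    def wald_p(self, j: int) -> float:
        if not np.isfinite(self.se[j]) or self.se[j] == 0:
            return np.nan
        z = self.beta[j] / self.se[j]
        return float(2 * stats.norm.sf(abs(z)))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe: log(1+exp(eta)) via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER,
                 tol: float = TOL) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    ``X`` must include the intercept column. Separation is flagged when
    coefficients diverge or fitted probabilities pin to 0/1 at the
    boundary without the likelihood stabilizing.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, score, rcond=None)[0]
        # step-halving on non-increase
        scale = 1.0
        for _ in range(20):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            ll_new = _loglik(y, eta_new)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, eta = beta_new, eta_new
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    separated = bool(np.abs(beta).max() > 15.0 or not converged)
    return LogisticFit(beta, se, ll, mu, converged, separated, it)


@dataclass
class FirthFit:
    beta: np.ndarray
    se: np.ndarray
    penalized_loglik: float
    mu: np.ndarray
    converged: bool
    n_iter: int


def _penalized_loglik(X, y, beta):
    eta = X @ beta
    ll = _loglik(y, eta)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth(X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER,
              tol: float = TOL, fixed_zero: tuple = ()) -> FirthFit:
    """Firth-penalized logistic fit (Jeffreys-prior penalty).

    Newton iterations on the modified score
    ``U*(beta) = X' (y - mu + h (1/2 - mu))`` with ``h`` the leverages of
    the weighted design; step-halving on decrease of the penalized
    likelihood. ``fixed_zero`` constrains the listed coefficients to
    zero while keeping the full-design penalty — the constrained fit the
    penalized likelihood-ratio test compares against.
    """
    n, p = X.shape
    beta = np.zeros(p)
    free = np.array([j for j in range(p) if j not in set(fixed_zero)])
    pll = _penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        rw = np.sqrt(w)
        Xw = X * rw[:, None]
        XtWX = Xw.T @ Xw
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            XtWX_inv = np.linalg.pinv(XtWX)
        # leverages of the weighted hat matrix (always full design)
        h = np.einsum("ij,jk,ik->i", Xw, XtWX_inv, Xw)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = np.zeros(p)
        sub = XtWX[np.ix_(free, free)]
        try:
            step[free] = np.linalg.solve(sub, score[free])
        except np.linalg.LinAlgError:
            step[free] = np.linalg.lstsq(sub, score[free], rcond=None)[0]
        scale = 1.0
        pll_new = -np.inf
        for _ in range(25):
            beta_new = beta + scale * step
            pll_new = _penalized_loglik(X, y, beta_new)
            if pll_new >= pll - 1e-12:
                break
            scale /= 2.0
        beta = beta_new
        if abs(pll_new - pll) < tol * (abs(pll) + 1.0):
            pll = pll_new
            converged = True
            break
        pll = pll_new

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return FirthFit(beta, se, pll, mu, converged, it)


def firth_lrt_p(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, FirthFit]:
    """Penalized likelihood-ratio p-value for coefficient ``j``.

    As in ``logistf``: the null fit maximizes the same full-design
    penalized likelihood with the coefficient constrained to zero; the
    deviance difference is referred to chi-square with one df.
    """
    full = fit_firth(X, y)
    reduced = fit_firth(X, y, fixed_zero=(j,))
    lr = 2.0 * (full.penalized_loglik - reduced.penalized_loglik)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return p, full
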