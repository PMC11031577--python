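"""Small, fast Newton solvers for logistic and Cox partial likelihoods.

The exhaustive signature search fits on the order of 10^5 models with at
most ~10 covariates and a few hundred rows each, so these routines are
written for low per-call overhead: plain numpy, no model objects.  They
are cross-checked against statsmodels and lifelines in the test suite.

Both return ``(beta, loglik, converged)``.  Non-convergence (including
separation / monotone likelihood, flagged by diverging coefficients) is
reported through ``converged=False`` so callers can assign an infinite
AIC instead of trusting the fit.
"""

from __future__ import annotations

import numpy as np

_MAX_ABS_BETA = 50.0


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic regression with intercept.

    ``X`` is (n, p) without the constant column; the returned ``beta`` has
    the intercept first.  Newton-Raphson with step halving.
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    ll = _logistic_ll(Xd, y, beta)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu)
        hess = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(p + 1), grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        # step halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _logistic_ll(Xd, y, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            return beta, ll, False
        delta = np.abs(cand - beta).max()
        beta, ll = cand, ll_new
        if delta < tol:
            converged = True
            break
    if np.abs(beta).max() > _MAX_ABS_BETA:
        converged = False
    return beta, ll, converged


def _logistic_ll(Xd: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = Xd @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, bool]:
    """Cox proportional hazards fit with Efron tie handling.

    Returns ``(beta, partial_loglik, converged)``.  No intercept (it is
    absorbed by the baseline hazard).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    order = np.argsort(time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order]
    p = X.shape[1]
    layout = _CoxLayout(X, time, event)
    beta = np.zeros(p)
    ll, grad, hess = layout.ll_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = layout.ll_grad_hess(cand, ll_only=True)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            return beta, ll, False
        delta = np.abs(cand - beta).max()
        beta = cand
        ll, grad, hess = layout.ll_grad_hess(beta)
        if delta < tol:
            converged = True
            break
    if np.abs(beta).max() > _MAX_ABS_BETA:
        converged = False  # monotone likelihood
    return beta, ll, converged


def cox_fit_se(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Cox fit plus standard errors from the observed information."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    beta, _, converged = cox_fit(X, time, event)
    order = np.argsort(time, kind="stable")
    layout = _CoxLayout(X[order], time[order], event[order])
    _, _, hess = layout.ll_grad_hess(beta)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.inf)
    return beta, se, converged


class _CoxLayout:
    """Precomputed tie structure for Efron partial-likelihood evaluations.

    Rows must be sorted by time ascending.  Groups of tied times are found
    once; evaluations then vectorize over untied event times and loop only
    over the (usually few) tied groups.
    """

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray):
        self.X = X
        self.event = event.astype(bool)
        n = len(time)
        starts = np.flatnonzero(np.r_[True, time[1:] != time[:-1]])
        self.group_starts = starts
        # death indices per group
        group_of = np.cumsum(np.r_[True, time[1:] != time[:-1]]) - 1
        self.d_count = np.bincount(group_of[self.event], minlength=len(starts))
        self.has_death = self.d_count > 0
        self.single = self.has_death & (self.d_count == 1)
        self.multi_groups = np.flatnonzero(self.has_death & (self.d_count > 1))
        self.death_rows_of = {
            g: np.flatnonzero(self.event & (group_of == g))
            for g in self.multi_groups
        }
        self.x_death_sum = X[self.event].sum(axis=0)

    def ll_grad_hess(self, beta: np.ndarray, ll_only: bool = False):
        X, event = self.X, self.event
        n, p = X.shape
        eta = np.clip(X @ beta, -500, 500)
        w = np.exp(eta)
        S0 = np.cumsum(w[::-1])[::-1][self.group_starts]
        ll = float(eta[event].sum())
        single = self.single
        s0_single = S0[single]
        ll -= float(np.log(s0_single).sum())

        if not ll_only:
            wx = w[:, None] * X
            S1 = np.cumsum(wx[::-1], axis=0)[::-1][self.group_starts]
            wxx = np.einsum("ij,ik->ijk", wx, X)
            S2 = np.cumsum(wxx[::-1], axis=0)[::-1][self.group_starts]
            s1_single = S1[single]
            inv0 = 1.0 / s0_single
            grad = self.x_death_sum - (s1_single * inv0[:, None]).sum(axis=0)
            hess = np.einsum("g,gij->ij", inv0, S2[single]) - np.einsum(
                "g,gi,gj->ij", inv0**2, s1_single, s1_single
            )

        for g in self.multi_groups:
            rows = self.death_rows_of[g]
            d = len(rows)
            s0 = S0[g]
            d0 = w[rows].sum()
            fracs = np.arange(d) / d
            r0 = s0 - fracs * d0
            ll -= float(np.log(r0).sum())
            if not ll_only:
                s1 = S1[g]
                d1 = wx[rows].sum(axis=0)
                s2 = S2[g]
                d2 = wxx[rows].sum(axis=0)
                for f, r0_l in zip(fracs, r0):
                    r1 = s1 - f * d1
                    r2 = s2 - f * d2
                    grad -= r1 / r0_l
                    hess += r2 / r0_l - np.outer(r1, r1) / r0_l**2
        if ll_only:
            return ll
        return ll, grad, hess
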