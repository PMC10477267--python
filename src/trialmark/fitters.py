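"""Regression workhorses: Cox proportional hazards and logistic MLE.

The discovery pipeline fits these models tens of thousands of times
(every feature x stratum x arm combination, then again for every
treatment-label permutation and bootstrap resample), so both fitters are
written as fully vectorised Newton iterations on numpy arrays rather
than going through a modelling framework per fit.  Agreement with
lifelines (Cox, Efron ties) and statsmodels (logistic) is enforced in
the test suite.

Conventions
-----------
* Cox: Efron approximation for tied event times; no intercept (absorbed
  by the baseline hazard).
* Logistic: intercept always included as the first column.
* A fit is flagged ``converged=False`` on monotone likelihood /
  separation (coefficient runaway) or a singular information matrix;
  such fits are excluded from BH families downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))
_MAX_ABS_COEF = 15.0


def safe_exp(x: float) -> float:
    """exp with the argument clipped to the float64 range (CI bounds of
    non-converged fits can be formally infinite)."""
    return float(np.exp(np.clip(x, -745.0, 709.0)))


@dataclass
class FitResult:
    """Coefficients, standard errors and fit diagnostics for one model."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n: int
    n_events: int

    def wald_p(self, j: int = 0) -> float:
        se = self.se[j]
        if not np.isfinite(se) or se <= 0:
            return np.nan
        return float(2.0 * stats.norm.sf(abs(self.beta[j] / se)))

    def ci95(self, j: int = 0) -> tuple[float, float]:
        b, se = self.beta[j], self.se[j]
        return float(b - Z975 * se), float(b + Z975 * se)


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
    presorted: bool = False,
) -> FitResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Partial likelihood with the Efron correction for ties.  ``X`` is the
    (n, p) covariate matrix; returns coefficients in column order.

    Set ``presorted=True`` when rows are already in ascending time order
    (the screening engine keeps its strata pre-sorted for this reason).
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape

    if not presorted:
        order = np.argsort(time, kind="stable")
        time, event, X = time[order], event[order], X[order]
    d = event.astype(bool)
    n_events = int(d.sum())
    if n_events == 0:
        return FitResult(np.zeros(p), np.full(p, np.inf), 0.0, False, n, 0)

    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    np.not_equal(time[1:], time[:-1], out=new_group[1:])
    starts = np.flatnonzero(new_group)
    G = len(starts)
    gidx = np.cumsum(new_group) - 1

    drow = np.flatnonzero(d)
    dg = gidx[drow]
    Dg = np.bincount(dg, minlength=G).astype(np.float64)
    off = np.concatenate(([0.0], np.cumsum(Dg)[:-1]))
    frac = (np.arange(len(drow)) - off[dg]) / Dg[dg]  # Efron tie fractions r/D

    Xd = X[drow]
    sum_xd = Xd.sum(axis=0)

    beta = np.zeros(p)
    loglik = -np.inf
    converged = False
    info = np.eye(p)

    def _quantities(b: np.ndarray):
        eta = X @ b
        eta -= eta.max()  # guard overflow; PL is invariant to this shift
        w = np.exp(eta)
        wX = X * w[:, None]
        wXX = (X[:, :, None] * X[:, None, :]) * w[:, None, None]

        S0 = _revcumsum(np.add.reduceat(w, starts))
        S1 = _revcumsum(np.add.reduceat(wX, starts, axis=0))
        S2 = _revcumsum(
            np.add.reduceat(wXX.reshape(n, p * p), starts, axis=0)
        ).reshape(G, p, p)

        S0d = np.bincount(dg, weights=w[drow], minlength=G)
        S1d = np.zeros((G, p))
        np.add.at(S1d, dg, wX[drow])
        S2d = np.zeros((G, p * p))
        np.add.at(S2d, dg, wXX[drow].reshape(len(drow), p * p))
        S2d = S2d.reshape(G, p, p)

        den = S0[dg] - frac * S0d[dg]
        ll = float(eta[drow].sum() - np.log(den).sum())
        A = (S1[dg] - frac[:, None] * S1d[dg]) / den[:, None]
        score = sum_xd - A.sum(axis=0)
        B = (S2[dg] - frac[:, None, None] * S2d[dg]) / den[:, None, None]
        information = (B - A[:, :, None] * A[:, None, :]).sum(axis=0)
        return ll, score, information

    loglik, score, info = _quantities(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return FitResult(beta, np.full(p, np.inf), loglik, False, n, n_events)
        # step halving keeps the iteration monotone in the partial likelihood
        shrink = 1.0
        for _half in range(30):
            cand = beta + shrink * step
            new_ll, new_score, new_info = _quantities(cand)
            if new_ll >= loglik - 1e-12:
                break
            shrink *= 0.5
        delta = np.max(np.abs(shrink * step))
        improved = new_ll - loglik
        beta, loglik, score, info = cand, new_ll, new_score, new_info
        if delta < tol or abs(improved) < 1e-11:
            converged = True
            break

    if np.max(np.abs(beta)) > _MAX_ABS_COEF:
        converged = False  # monotone likelihood: estimate diverges
    se = _se_from_information(info)
    return FitResult(beta, se, loglik, converged, n, n_events)


def logistic_fit(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> FitResult:
    """Fit a logistic regression (intercept prepended) by Newton-Raphson."""
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    X1 = np.column_stack([np.ones(n), X])
    p = X1.shape[1]
    n_events = int(y.sum())
    if n_events == 0 or n_events == n:
        return FitResult(np.zeros(p), np.full(p, np.inf), 0.0, False, n, n_events)

    def _loglik(b: np.ndarray) -> float:
        eta = X1 @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    beta = np.zeros(p)
    ll = _loglik(beta)
    converged = False
    info = np.eye(p)
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-(X1 @ beta)))
        w = mu * (1.0 - mu)
        score = X1.T @ (y - mu)
        info = (X1 * w[:, None]).T @ X1
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return FitResult(beta, np.full(p, np.inf), ll, False, n, n_events)
        shrink, new_ll = 1.0, -np.inf
        for _half in range(30):
            cand = beta + shrink * step
            new_ll = _loglik(cand)
            if new_ll >= ll - 1e-12:
                break
            shrink *= 0.5
        beta = beta + shrink * step
        if np.max(np.abs(shrink * step)) < tol or abs(new_ll - ll) < 1e-11:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    if np.max(np.abs(beta)) > _MAX_ABS_COEF:
        converged = False  # quasi-complete separation
    mu = 1.0 / (1.0 + np.exp(-(X1 @ beta)))
    w = mu * (1.0 - mu)
    info = (X1 * w[:, None]).T @ X1
    se = _se_from_information(info)
    return FitResult(beta, se, ll, converged, n, n_events)


def _se_from_information(info: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        return np.full(info.shape[0], np.inf)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (textbook formula)."""
    p = np.asarray(p, dtype=np.float64)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
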