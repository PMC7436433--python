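"""Naive comparison fitters: logistic regression on the event indicator and
Cox proportional hazards on time-to-diagnosis.

Both are implemented directly from their estimating equations (Newton–Raphson
with step-halving) rather than wrapping a regression library, because their
behaviour *when misapplied to cure-model data* — the bias of the logistic
slope and the latency-invariance of the Cox estimate — is the object of study
here, and the same weighted Cox kernel drives the EM cure model's M-step.

Fitting a logistic model to δ estimates Pr(diagnosis observed), not
Pr(susceptible); the two differ by the factor E_G[1 − S(C)], which is the
source of the asymptotic bias quantified in :mod:`curemix.bias`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalSample
from .simulate import logistic

__all__ = [
    "LogisticFit",
    "CoxFit",
    "fit_logistic_on_delta",
    "fit_cox_ph",
    "weighted_logistic_mle",
    "weighted_cox_newton",
    "breslow_baseline",
    "NonConvergenceError",
]

MAX_ABS_COEF = 20.0  # separation / monotone-likelihood guard


class NonConvergenceError(RuntimeError):
    """Raised when an estimating equation has no finite solution
    (complete separation, degenerate outcomes)."""


@dataclass
class LogisticFit:
    coef: np.ndarray            # intercept first
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    terms: list = field(default_factory=list)

    def tidy(self, model: str = "logistic") -> pd.DataFrame:
        return pd.DataFrame(
            {"model": model, "part": "incidence", "term": self.terms,
             "estimate": self.coef, "se": self.se}
        )


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    loglik: float               # partial log-likelihood
    converged: bool
    diverged: bool
    n_iter: int
    baseline_times: np.ndarray  # distinct event times
    baseline_increments: np.ndarray  # Breslow cumulative-hazard jumps
    terms: list = field(default_factory=list)

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.baseline_times, t, side="right")
        csum = np.concatenate([[0.0], np.cumsum(self.baseline_increments)])
        return csum[idx]

    def tidy(self, model: str = "cox") -> pd.DataFrame:
        return pd.DataFrame(
            {"model": model, "part": "latency", "term": self.terms,
             "estimate": self.coef, "se": self.se}
        )


# ---------------------------------------------------------------------------
# Logistic regression (weighted Bernoulli likelihood, Newton–Raphson)


def weighted_logistic_mle(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                          max_iter: int = 100, init: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Maximise sum_i [y_i X_i'b - log(1 + e^{X_i'b})] over b.

    ``y`` may be fractional (the EM M-step uses posterior susceptibility
    weights as the working response).  Convergence: max |score| < tol, or a
    Newton step that no longer moves the iterate.  Returns (coef, se,
    loglik, converged, n_iter); raises :class:`NonConvergenceError` on
    separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise NonConvergenceError("design matrix is rank deficient")
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()

    def loglik(b):
        eta = X @ b
        # log(1+e^eta) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = logistic(X @ beta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise NonConvergenceError("singular information matrix")
        # step-halving with a float-noise allowance near the optimum
        new = beta + step
        ll_new = loglik(new)
        halves = 0
        while ll_new < ll - 1e-12 * (abs(ll) + 1.0) and halves < 30:
            step *= 0.5
            new = beta + step
            ll_new = loglik(new)
            halves += 1
        moved = np.max(np.abs(step))
        beta, ll_prev, ll = new, ll, max(ll_new, ll)
        if np.max(np.abs(beta)) > MAX_ABS_COEF and ll > ll_prev:
            raise NonConvergenceError(
                "coefficients diverging with increasing likelihood (separation?)"
            )
        if moved < 1e-12 * (1.0 + np.max(np.abs(beta))):
            converged = True  # stalled on a numerical plateau at the optimum
            break
    mu = logistic(X @ beta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, ll, converged, it


def fit_logistic_on_delta(sample: SurvivalSample) -> LogisticFit:
    """Logistic MLE of Pr(δ = 1 | x), the naive censored-binary analysis.

    For a single binary covariate the slope is exactly the empirical log
    odds ratio of the two exposure strata (invariance of the MLE).
    """
    y = sample.event.astype(float)
    if y.sum() == 0 or y.sum() == sample.n:
        raise NonConvergenceError("all events or all censored: logistic MLE does not exist")
    X = np.column_stack([np.ones(sample.n), sample.x])
    coef, se, ll, conv, it = weighted_logistic_mle(X, y)
    return LogisticFit(coef=coef, se=se, loglik=ll, converged=conv, n_iter=it,
                       terms=["intercept"] + list(sample.x_names))


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties), optionally with fractional risk weights


def _risk_index(times_sorted: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Index of the first subject (ascending order) still at risk at t-."""
    return np.searchsorted(times_sorted, t, side="left")


def weighted_cox_newton(time, event, Z, weights=None, init=None, tol: float = 1e-8,
                        max_iter: int = 100):
    """Newton–Raphson on the (weighted) Cox partial likelihood score.

    Censored subjects enter risk sets with multiplier ``weights`` (the EM
    fractional-risk-set scheme); subjects with an event always carry weight 1.
    Returns (gamma, se, partial loglik, converged, diverged, n_iter, order)
    where ``order`` is the ascending time permutation used.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z.reshape(-1, 1)
    n, p = Z.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).copy()
    w[event == 1] = 1.0

    order = np.argsort(time, kind="mergesort")
    ts, ev, Zs, ws = time[order], event[order], Z[order], w[order]
    ev_idx = np.flatnonzero(ev == 1)
    if ev_idx.size == 0:
        raise NonConvergenceError("no events: partial likelihood is flat")
    risk_start = _risk_index(ts, ts[ev_idx])

    const_cols = np.flatnonzero(np.ptp(Zs, axis=0) == 0)
    if const_cols.size:
        warnings.warn("covariate(s) with no contrast; coefficients fixed at 0", stacklevel=2)

    gamma = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    gamma[const_cols] = 0.0

    def suffix(arr):
        return np.cumsum(arr[::-1], axis=0)[::-1]

    def quantities(g):
        eta = Zs @ g
        r = ws * np.exp(eta)
        s0 = suffix(r)[risk_start]                                   # (m,)
        s1 = suffix(r[:, None] * Zs)[risk_start]                     # (m, p)
        zz = Zs[:, :, None] * Zs[:, None, :]
        s2 = suffix(r[:, None, None] * zz)[risk_start]               # (m, p, p)
        ll = float(np.sum(eta[ev_idx] - np.log(s0)))
        zbar = s1 / s0[:, None]
        score = (Zs[ev_idx] - zbar).sum(axis=0)
        info = (s2 / s0[:, None, None] - zbar[:, :, None] * zbar[:, None, :]).sum(axis=0)
        return ll, score, info

    free = np.setdiff1d(np.arange(p), const_cols)
    ll, score, info = quantities(gamma)
    converged = diverged = False
    it = 0
    if free.size:
        for it in range(1, max_iter + 1):
            if np.max(np.abs(score[free])) < tol:
                converged = True
                break
            try:
                step_f = np.linalg.solve(info[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                raise NonConvergenceError("singular partial-likelihood information")
            step = np.zeros(p)
            step[free] = step_f
            new = gamma + step
            ll_new, score_new, info_new = quantities(new)
            halves = 0
            while ll_new < ll - 1e-12 * (abs(ll) + 1.0) and halves < 30:
                step *= 0.5
                new = gamma + step
                ll_new, score_new, info_new = quantities(new)
                halves += 1
            moved = np.max(np.abs(step))
            gamma, ll_prev, ll = new, ll, max(ll_new, ll)
            score, info = score_new, info_new
            if np.max(np.abs(gamma)) > MAX_ABS_COEF and ll > ll_prev:
                diverged = True
                break
            if moved < 1e-12 * (1.0 + np.max(np.abs(gamma))):
                converged = True
                break
    else:
        converged = True

    if free.size and np.max(np.abs(gamma)) > 15.0:
        diverged = True  # monotone partial likelihood: estimate escaping to +-inf

    se = np.full(p, np.nan)
    if free.size and not diverged:
        try:
            se[free] = np.sqrt(np.diag(np.linalg.inv(info[np.ix_(free, free)])))
        except np.linalg.LinAlgError:
            pass
    return gamma, se, ll, converged, diverged, it


def breslow_baseline(time, event, Z, gamma, weights=None):
    """Breslow cumulative-baseline-hazard increments d_k / sum_{risk} w_j e^{z_j'g}.

    Tied event times are merged into a shared increment.  Returns (distinct
    event times ascending, increments).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z.reshape(-1, 1)
    n = time.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).copy()
    w[event == 1] = 1.0
    order = np.argsort(time, kind="mergesort")
    ts, ev, ws = time[order], event[order], w[order]
    r = ws * np.exp(Z[order] @ np.atleast_1d(gamma)) if Z.size else ws
    s0 = np.cumsum(r[::-1])[::-1]
    etimes = ts[ev == 1]
    uniq, first = np.unique(etimes, return_index=True)
    d = np.diff(np.append(first, etimes.size))          # multiplicity per distinct time
    risk = s0[_risk_index(ts, uniq)]
    return uniq, d / risk


def fit_cox_ph(sample: SurvivalSample, tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Cox PH fit on the latency covariates z (Breslow ties and baseline)."""
    if sample.n_events == 0:
        raise NonConvergenceError("no events")
    Z = sample.z if sample.z.shape[1] else sample.x  # fall back to x for the naive comparison
    names = sample.z_names if sample.z.shape[1] else sample.x_names
    gamma, se, ll, conv, div, it = weighted_cox_newton(
        sample.time, sample.event, Z, tol=tol, max_iter=max_iter
    )
    bt, binc = breslow_baseline(sample.time, sample.event, Z, gamma)
    return CoxFit(coef=gamma, se=se, loglik=ll, converged=conv, diverged=div, n_iter=it,
                  baseline_times=bt, baseline_increments=binc, terms=list(names))
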