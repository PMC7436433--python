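"""Semiparametric mixture cure model fitted by expectation–maximisation.

The latency baseline is an unspecified step-function cumulative hazard
(Breslow increments at the distinct event times).  The EM alternates

* **E-step** — posterior susceptibility weights for censored subjects,
  w_i = π_i S_i(t_i) / (1 − π_i + π_i S_i(t_i)); w_i = 1 for events
  (an observed diagnosis proves susceptibility);
* **M-step** — a weighted logistic MLE for the incidence coefficients with w
  as working response, and a fractional-risk-set weighted Cox partial
  likelihood for the latency coefficients, followed by a weighted Breslow
  baseline update.

Identifiability requires the *zero-tail constraint*: the estimated latency
survival is set to exactly 0 beyond the largest observed diagnosis time, at
every iteration.  A censored subject followed past that time therefore gets
posterior weight 0 — they are treated as certainly nonsusceptible.

Standard errors are by nonparametric bootstrap (resampling subjects), the
only variance estimate offered for this family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalSample, ValidationError
from .naive import (
    NonConvergenceError,
    breslow_baseline,
    fit_logistic_on_delta,
    weighted_cox_newton,
    weighted_logistic_mle,
)
from .results import FitResult
from .simulate import logistic

__all__ = [
    "StepBaseline",
    "EMState",
    "e_step_weights",
    "m_step",
    "fit_em_cure",
    "bootstrap_se",
    "posterior_susceptible",
]


@dataclass
class StepBaseline:
    """Step-function baseline hazard with the zero-tail constraint.

    ``times`` are the ordered distinct event times, ``increments`` the
    Breslow cumulative-hazard jumps ΔΛ_k.  Survival uses the product-limit
    transform Π_{t_k ≤ t} (1 − ΔΛ_k) — the nonparametric-MLE form, reducing
    to Kaplan–Meier when all weights are 1 — truncated to exactly 0 above
    the largest event time (and from any time whose increment reaches 1).
    """

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if np.any(self.increments < 0):
            raise ValidationError("cumulative-hazard increments must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("baseline times must be strictly increasing")
        one_minus = np.clip(1.0 - self.increments, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            self._cum_log_pl = np.concatenate(
                [[0.0], np.cumsum(np.log(np.clip(one_minus, 1e-300, None)))]
            )
        dead = np.flatnonzero(one_minus <= 0.0)
        self._absorbing_time = self.times[dead[0]] if dead.size else np.inf

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        csum = np.concatenate([[0.0], np.cumsum(self.increments)])
        return csum[np.searchsorted(self.times, t, side="right")]

    def _pl(self, t: np.ndarray, side: str) -> np.ndarray:
        s = np.exp(self._cum_log_pl[np.searchsorted(self.times, t, side=side)])
        if side == "right":
            s[t >= self._absorbing_time] = 0.0
        else:
            s[t > self._absorbing_time] = 0.0
        if self.times.size:
            s[t > self.times[-1]] = 0.0  # zero tail
        return s

    def survival(self, t) -> np.ndarray:
        """Product-limit survival S0(t), zero-tailed."""
        return self._pl(np.atleast_1d(np.asarray(t, dtype=float)), "right")

    def survival_left(self, t) -> np.ndarray:
        """Left limit S0(t−), needed for the discrete event mass."""
        return self._pl(np.atleast_1d(np.asarray(t, dtype=float)), "left")


@dataclass
class EMState:
    """Current EM iterate: coefficients, baseline, weights and the
    observed-data log-likelihood trace (nondecreasing across iterations)."""

    beta: np.ndarray
    gamma: np.ndarray
    baseline: StepBaseline
    weights: np.ndarray
    loglik_trace: list = field(default_factory=list)


def _subject_survival(state: EMState, sample: SurvivalSample, Z: np.ndarray) -> np.ndarray:
    s0 = state.baseline.survival(sample.time)
    if state.gamma.size:
        with np.errstate(divide="ignore"):
            logs0 = np.where(s0 > 0, np.log(np.clip(s0, 1e-300, None)), -np.inf)
        out = np.exp(np.exp(Z @ state.gamma) * logs0)
        out[s0 == 0] = 0.0
        return out
    return s0


def e_step_weights(state: EMState, sample: SurvivalSample, X: np.ndarray,
                   Z: np.ndarray) -> np.ndarray:
    """Posterior probability of susceptibility given the observed data."""
    pi = logistic(X @ state.beta)
    s = _subject_survival(state, sample, Z)
    denom = 1.0 - pi + pi * s
    w = np.where(sample.event == 1, 1.0, pi * s / np.clip(denom, 1e-300, None))
    return w


def m_step(sample: SurvivalSample, weights: np.ndarray, X: np.ndarray, Z: np.ndarray,
           gamma_init: np.ndarray | None = None, beta_init: np.ndarray | None = None):
    """One maximisation step given posterior weights.

    Returns (beta, gamma, baseline).  With all weights equal to 1 the γ
    update coincides with an ordinary Cox fit and the Breslow update with
    the Nelson–Aalen estimator.
    """
    w = np.asarray(weights, dtype=float)
    if np.all(w[sample.event == 0] < 1e-12) and sample.n_events == 0:
        raise NonConvergenceError("degenerate weights: nobody susceptible")
    beta, _, _, _, _ = weighted_logistic_mle(X, w, init=beta_init)
    if Z.shape[1]:
        gamma, _, _, _, _, _ = weighted_cox_newton(
            sample.time, sample.event, Z, weights=w, init=gamma_init
        )
    else:
        gamma = np.empty(0)
    bt, binc = breslow_baseline(sample.time, sample.event, Z, gamma, weights=w)
    return beta, gamma, StepBaseline(bt, binc)


def _observed_loglik(state: EMState, sample: SurvivalSample, X: np.ndarray,
                     Z: np.ndarray) -> float:
    """Discrete observed-data log-likelihood: events carry the probability
    mass S_i(t−) − S_i(t) of the product-limit latency law, censored
    subjects the population survival 1 − π + π S_i(t)."""
    pi = logistic(X @ state.beta)
    d = sample.event == 1
    eta = Z @ state.gamma if state.gamma.size else np.zeros(sample.n)
    tilt = np.exp(eta[d])
    s_before = state.baseline.survival_left(sample.time[d])
    s_at = state.baseline.survival(sample.time[d])
    with np.errstate(divide="ignore"):
        mass = (np.exp(tilt * np.log(np.clip(s_before, 1e-300, None)))
                - np.exp(tilt * np.log(np.clip(s_at, 1e-300, None))))
        mass[s_at == 0] = np.exp(tilt[s_at == 0]
                                 * np.log(np.clip(s_before[s_at == 0], 1e-300, None)))
    ll_e = np.log(pi[d]) + np.log(np.clip(mass, 1e-300, None))
    s = _subject_survival(state, sample, Z)
    sp = 1.0 - pi[~d] + pi[~d] * s[~d]
    ll_c = np.log(np.clip(sp, 1e-300, None))
    return float(ll_e.sum() + ll_c.sum())


def _designs(sample: SurvivalSample, incidence: bool, latency: bool):
    X = np.column_stack([np.ones(sample.n)]
                        + ([sample.x] if (incidence and sample.x.shape[1]) else []))
    Z = sample.z if (latency and sample.z.shape[1]) else np.empty((sample.n, 0))
    return X, Z


def fit_em_cure(
    sample: SurvivalSample,
    incidence: bool = True,
    latency: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """EM fit of the semiparametric cure model.

    Convergence: maximum absolute change over (β, γ) below ``tol``.  The
    zero-tail constraint is applied at every iteration.  The returned
    ``diagnostics['loglik_trace']`` is the per-iteration observed-data
    log-likelihood; ``extra`` carries the final :class:`StepBaseline`,
    weights, and an ``EMState``.
    """
    if sample.n_events == 0:
        raise NonConvergenceError("no events")
    X, Z = _designs(sample, incidence, latency)

    try:
        b0, _, _, _, _ = weighted_logistic_mle(X, sample.event.astype(float))
    except NonConvergenceError:
        b0 = np.zeros(X.shape[1])
    w = np.where(sample.event == 1, 1.0, 0.5)
    beta, gamma, baseline = m_step(sample, w, X, Z)
    state = EMState(beta=beta, gamma=gamma, baseline=baseline, weights=w)
    state.beta = b0 if np.all(np.isfinite(b0)) else beta

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = e_step_weights(state, sample, X, Z)
        beta, gamma, baseline = m_step(sample, w, X, Z,
                                       gamma_init=state.gamma if state.gamma.size else None,
                                       beta_init=state.beta)
        change = np.max(np.abs(np.concatenate([beta - state.beta,
                                               gamma - state.gamma if gamma.size else [0.0]])))
        state = EMState(beta=beta, gamma=gamma, baseline=baseline, weights=w,
                        loglik_trace=state.loglik_trace)
        state.loglik_trace.append(_observed_loglik(state, sample, X, Z))
        if change < tol:
            converged = True
            break

    labels = (["incidence:intercept"]
              + [f"incidence:{n}" for n in (sample.x_names if X.shape[1] > 1 else [])]
              + [f"latency:{n}" for n in (sample.z_names if Z.shape[1] else [])])
    values = np.concatenate([state.beta, state.gamma])
    return FitResult(
        model="semiparametric_cure",
        estimates=pd.Series(values, index=labels),
        se=pd.Series(np.full(values.size, np.nan), index=labels),
        loglik=state.loglik_trace[-1],
        converged=converged,
        diagnostics={"n_iter": it, "loglik_trace": list(state.loglik_trace)},
        extra={"baseline": state.baseline, "weights": state.weights, "state": state,
               "incidence": incidence, "latency": latency},
    )


def bootstrap_se(
    sample: SurvivalSample,
    B: int = 100,
    seed: int = 0,
    incidence: bool = True,
    latency: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.Series:
    """Nonparametric bootstrap standard errors for the EM cure model.

    Subjects are resampled with replacement; replicate r is seeded
    ``seed ^ r``.  Non-converged replicates are dropped and counted; if more
    than 20% fail a warning is raised.  Returns the SE Series (the replicate
    matrix and failure count ride along in ``.attrs``).
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    rows = []
    failed = 0
    index = None
    for r in range(1, B + 1):
        rng = np.random.Generator(np.random.PCG64(seed ^ r))
        idx = rng.integers(0, sample.n, size=sample.n)
        try:
            fit = fit_em_cure(sample.subset(idx), incidence=incidence, latency=latency,
                              tol=tol, max_iter=max_iter)
        except NonConvergenceError:
            failed += 1
            continue
        if not fit.converged:
            failed += 1
            continue
        rows.append(fit.estimates.to_numpy())
        index = fit.estimates.index
    if not rows:
        raise NonConvergenceError("all bootstrap replicates failed")
    if failed > 0.2 * B:
        warnings.warn(f"{failed}/{B} bootstrap replicates failed to converge", stacklevel=2)
    mat = np.vstack(rows)
    se = pd.Series(mat.std(axis=0, ddof=1), index=index)
    se.attrs["n_failed"] = failed
    se.attrs["replicates"] = mat
    return se


def posterior_susceptible(fit: FitResult, t, x=None, z=None):
    """Pr(susceptible | no diagnosis by t) for a covariate profile.

    Equals π(x'β̂) at t = 0 and decays to 0 past the last event time under
    the zero-tail constraint; nonincreasing in t.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValidationError("t must be >= 0")
    state: EMState = fit.extra["state"]
    x = np.atleast_1d(np.asarray(x, dtype=float)) if x is not None else np.empty(0)
    z = np.atleast_1d(np.asarray(z, dtype=float)) if z is not None else np.empty(0)
    pi = logistic(state.beta[0] + (x @ state.beta[1:] if state.beta.size > 1 else 0.0))
    s0 = state.baseline.survival(t)
    if state.gamma.size:
        with np.errstate(divide="ignore"):
            s = np.where(s0 > 0, np.exp(np.exp(z @ state.gamma) * np.log(np.clip(s0, 1e-300, None))), 0.0)
    else:
        s = s0
    return pi * s / np.clip(1.0 - pi + pi * s, 1e-300, None)
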