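"""Fully parametric mixture cure model with a gamma baseline.

Population survival
    S_pop(t | x, z) = 1 − π(x'β) + π(x'β) · S0(t)^{exp(z'γ)},

with π the logistic function and S0 the survival function of a
Gamma(a, b) distribution with density (b^a / Γ(a)) t^{a−1} e^{−bt}.  The
full observed-data log-likelihood

    ℓ(β, γ, a, b) = Σ_i δ_i [log π_i + log α0(t_i) + z_i'γ + log S_i(t_i)]
                  + (1 − δ_i) log(1 − π_i + π_i S_i(t_i)),

where α0 = baseline hazard (density / survival), is maximised directly by
quasi-Newton on (β, γ, log a, log b); positivity of the gamma parameters is
enforced by the log reparameterisation.  Covariates may enter both parts,
the latency part only, or the incidence part only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data import SurvivalSample, ValidationError
from .naive import NonConvergenceError, fit_logistic_on_delta
from .results import FitResult
from .simulate import logistic

__all__ = [
    "GammaBaseline",
    "CureParams",
    "population_survival",
    "loglik_cure",
    "fit_gamma_cure",
    "aic",
    "AIC",
]


@dataclass(frozen=True)
class GammaBaseline:
    """Gamma(shape a, rate b) baseline for the susceptible group."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("gamma parameters must be strictly positive")

    def log_survival(self, t):
        return stats.gamma.logsf(t, a=self.a, scale=1.0 / self.b)

    def survival(self, t):
        return stats.gamma.sf(t, a=self.a, scale=1.0 / self.b)

    def log_hazard(self, t):
        return stats.gamma.logpdf(t, a=self.a, scale=1.0 / self.b) - self.log_survival(t)


@dataclass
class CureParams:
    """Parameter bundle: incidence β (intercept first), latency γ, baseline."""

    beta: np.ndarray
    gamma: np.ndarray
    baseline: GammaBaseline

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float)) if np.size(self.gamma) \
            else np.empty(0)


def _linear(coef: np.ndarray, M: np.ndarray) -> np.ndarray:
    return M @ coef if coef.size else np.zeros(M.shape[0])


def population_survival(params: CureParams, t, x=None, z=None):
    """S_pop(t) = 1 − π + π S0(t)^{exp(z'γ)} for one covariate profile.

    ``x``/``z`` are covariate vectors *without* intercept; ``x`` may be None
    when β is intercept-only, ``z`` None when γ is empty.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t must be >= 0")
    x = np.atleast_1d(np.asarray(x, dtype=float)) if x is not None else np.empty(0)
    z = np.atleast_1d(np.asarray(z, dtype=float)) if z is not None else np.empty(0)
    pi = logistic(params.beta[0] + (x @ params.beta[1:] if params.beta.size > 1 else 0.0))
    eta = z @ params.gamma if params.gamma.size else 0.0
    s = np.exp(np.exp(eta) * params.baseline.log_survival(t))
    return 1.0 - pi + pi * s


def loglik_cure(params: CureParams, sample: SurvivalSample) -> float:
    """Observed-data log-likelihood of the gamma-baseline cure model."""
    if np.any((sample.time == 0) & (sample.event == 1)):
        raise ValidationError("events at time exactly 0 are not allowed "
                              "(baseline hazard unbounded at 0)")
    X = np.column_stack([np.ones(sample.n), sample.x])
    pi = logistic(X @ params.beta)
    eta = _linear(params.gamma, sample.z)
    log_s0 = params.baseline.log_survival(sample.time)
    log_si = np.exp(eta) * log_s0
    d = sample.event == 1
    ll_event = (np.log(pi[d]) + params.baseline.log_hazard(sample.time[d])
                + eta[d] + log_si[d])
    surv_pop = 1.0 - pi[~d] + pi[~d] * np.exp(log_si[~d])
    ll_cens = np.log(np.clip(surv_pop, 1e-300, None))
    return float(ll_event.sum() + ll_cens.sum())


def _moment_start(sample: SurvivalSample) -> tuple[float, float]:
    t = sample.time[sample.event == 1]
    m, v = float(np.mean(t)), float(np.var(t))
    if v <= 0 or m <= 0:
        return 1.0, 1.0
    return max(m * m / v, 1e-2), max(m / v, 1e-4)


def fit_gamma_cure(
    sample: SurvivalSample,
    incidence: bool = True,
    latency: bool = True,
    start: np.ndarray | None = None,
) -> FitResult:
    """Maximum likelihood fit of the gamma-baseline cure model.

    ``incidence``/``latency`` toggle whether the sample's x (resp. z)
    covariates enter that part, giving the three standard configurations:
    both parts, latency only (i.i.d. susceptibility), incidence only
    (i.i.d. diagnosis times).  Standard errors come from the inverse
    numerical Hessian at the optimum; if it is not positive definite they
    are reported as NaN.
    """
    if sample.n_events == 0:
        raise NonConvergenceError("no events")
    px = sample.x.shape[1] if incidence else 0
    pz = sample.z.shape[1] if latency else 0
    X = np.column_stack([np.ones(sample.n)] + ([sample.x] if px else []))
    Z = sample.z if pz else np.empty((sample.n, 0))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NonConvergenceError("incidence design not full rank")
    if pz and np.linalg.matrix_rank(Z) < pz:
        raise NonConvergenceError("latency design not full rank")

    def unpack(theta):
        beta = theta[: 1 + px]
        gamma = theta[1 + px: 1 + px + pz]
        a, b = np.exp(theta[-2]), np.exp(theta[-1])
        return beta, gamma, a, b

    d = sample.event == 1
    t, time = sample.time, sample.time

    def negll(theta):
        beta, gamma, a, b = unpack(theta)
        if not (1e-8 < a < 1e4 and 1e-8 < b < 1e4):
            return 1e12
        pi = logistic(X @ beta)
        eta = Z @ gamma if pz else np.zeros(sample.n)
        log_s0 = stats.gamma.logsf(time, a=a, scale=1.0 / b)
        log_si = np.exp(eta) * log_s0
        log_h0 = stats.gamma.logpdf(time[d], a=a, scale=1.0 / b) - log_s0[d]
        ll_e = np.log(pi[d]) + log_h0 + (eta[d] if pz else 0.0) + log_si[d]
        sp = 1.0 - pi[~d] + pi[~d] * np.exp(log_si[~d])
        ll_c = np.log(np.clip(sp, 1e-300, None))
        val = -(ll_e.sum() + ll_c.sum())
        return val if np.isfinite(val) else 1e12

    if start is None:
        try:
            lf = fit_logistic_on_delta(sample)
            beta0 = lf.coef[: 1 + px] if px else lf.coef[:1]
        except NonConvergenceError:
            beta0 = np.zeros(1 + px)
        a0, b0 = _moment_start(sample)
        start = np.concatenate([beta0, np.zeros(pz), [np.log(a0), np.log(b0)]])

    res = optimize.minimize(negll, start, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    if not res.success:  # polish with Nelder-Mead from the BFGS point
        res2 = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    beta, gamma, a, b = unpack(theta)

    hess = _numeric_hessian(negll, theta)
    se_theta = np.full(theta.size, np.nan)
    spd = True
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.all(diag > 0):
            se_theta = np.sqrt(diag)
        else:
            spd = False
    except np.linalg.LinAlgError:
        spd = False
    # delta method for (a, b) from (log a, log b)
    se = se_theta.copy()
    se[-2] *= a
    se[-1] *= b

    labels = (["incidence:intercept"]
              + [f"incidence:{n}" for n in (sample.x_names if px else [])]
              + [f"latency:{n}" for n in (sample.z_names if pz else [])]
              + ["baseline:a", "baseline:b"])
    values = np.concatenate([beta, gamma, [a, b]])
    grad_norm = float(np.max(np.abs(optimize.approx_fprime(theta, negll, 1e-6))))
    return FitResult(
        model="gamma_cure",
        estimates=pd.Series(values, index=labels),
        se=pd.Series(se, index=labels),
        loglik=-float(res.fun),
        converged=bool(res.success or grad_norm < 1e-2),
        diagnostics={"n_iter": int(res.get("nit", -1)), "grad_norm": grad_norm,
                     "hessian_pd": spd},
        extra={"params": CureParams(beta=beta, gamma=gamma, baseline=GammaBaseline(a, b))},
    )


def _numeric_hessian(f, x0, rel_step: float = 1e-4) -> np.ndarray:
    p = x0.size
    h = rel_step * (1.0 + np.abs(x0))
    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


@dataclass(frozen=True)
class AIC:
    """Akaike information criterion in both sign conventions.

    ``standard`` = −2ℓ + 2k (smaller is better); ``paper_sign`` = 2ℓ − 2k
    (larger is better) — some published tables print the latter.
    """

    standard: float
    paper_sign: float


def aic(fit: FitResult) -> AIC:
    k = fit.n_params
    return AIC(standard=-2.0 * fit.loglik + 2.0 * k, paper_sign=2.0 * fit.loglik - 2.0 * k)
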