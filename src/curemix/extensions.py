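"""Two extension models beyond the standard cure framework.

**Two-state ascertainment.**  When the data can also *rule out* the
condition (e.g. a test certifying nonsusceptibility), both latent states
generate observable events: susceptible subjects (Y = 1) are diagnosed with
hazard α(t), nonsusceptible subjects (Y = 0) have their status ascertained
with hazard β(t).  With D = Y for observed events and D = 0 otherwise, the
likelihood is

    L = Π_i [π_i α(t_i) e^{−∫α}]^{D_i δ_i} [(1−π_i) β(t_i) e^{−∫β}]^{(1−D_i) δ_i}
          × [π_i e^{−∫α} + (1−π_i) e^{−∫β}]^{1−δ_i}.

Both hazards are parametric here (exponential or gamma); independent
censoring of both processes is assumed.

**First-hitting-time susceptibility.**  A Wiener process Z(t) with drift μ
and variance σ²t, started at c0 > 0, is absorbed the first time it hits 0;
the hitting time is inverse-Gaussian.  When μ > 0 (drift away from the
barrier) the hitting distribution is improper: the probability of never
being diagnosed is 1 − exp(−2 c0 μ / σ²), so c0 acts as a continuous degree
of (non)susceptibility instead of a binary cure indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import SurvivalSample, ValidationError
from .naive import NonConvergenceError, fit_logistic_on_delta
from .results import FitResult
from .simulate import logistic

__all__ = [
    "ParametricHazard",
    "TwoStateParams",
    "WienerFHT",
    "loglik_two_state",
    "fit_two_state",
    "ig_cure_fraction",
    "sample_fht",
]


@dataclass(frozen=True)
class ParametricHazard:
    """Exponential (rate) or Gamma(a, b) event-time hazard."""

    family: str = "exponential"
    rate: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self):
        if self.family == "exponential":
            if self.rate is None or self.rate <= 0:
                raise ValidationError("exponential hazard needs rate > 0")
        elif self.family == "gamma":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValidationError("gamma hazard needs a, b > 0")
        else:
            raise ValidationError(f"unknown hazard family {self.family!r}")

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            return np.full(t.shape, np.log(self.rate))
        return (stats.gamma.logpdf(t, a=self.a, scale=1.0 / self.b)
                - stats.gamma.logsf(t, a=self.a, scale=1.0 / self.b))

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            return self.rate * t
        return -stats.gamma.logsf(t, a=self.a, scale=1.0 / self.b)


@dataclass
class TwoStateParams:
    """Logistic incidence β plus the two state-specific hazards."""

    beta: np.ndarray
    susceptible_hazard: ParametricHazard
    nonsusceptible_hazard: ParametricHazard

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))


def loglik_two_state(params: TwoStateParams, sample: SurvivalSample,
                     D: np.ndarray) -> float:
    """Log-likelihood of the two-state ascertainment model."""
    D = np.asarray(D)
    if np.any((D == 1) & (sample.event == 0)):
        raise ValidationError("D = 1 requires an observed event (δ = 1)")
    X = np.column_stack([np.ones(sample.n), sample.x])
    pi = logistic(X @ params.beta)
    t = sample.time
    Aa = params.susceptible_hazard.cumulative_hazard(t)
    Ab = params.nonsusceptible_hazard.cumulative_hazard(t)
    d = sample.event == 1
    d1 = d & (D == 1)
    d0 = d & (D == 0)
    ll = 0.0
    ll += float(np.sum(np.log(pi[d1]) + params.susceptible_hazard.log_hazard(t[d1]) - Aa[d1]))
    ll += float(np.sum(np.log(1.0 - pi[d0])
                       + params.nonsusceptible_hazard.log_hazard(t[d0]) - Ab[d0]))
    cens = ~d
    mix = pi[cens] * np.exp(-Aa[cens]) + (1.0 - pi[cens]) * np.exp(-Ab[cens])
    ll += float(np.sum(np.log(np.clip(mix, 1e-300, None))))
    return ll


def fit_two_state(sample: SurvivalSample, D: np.ndarray,
                  family: str = "exponential") -> FitResult:
    """Quasi-Newton MLE of the two-state model with parametric hazards.

    Requires observed events of both types (D = 1 and D = 0 among δ = 1);
    with only one type the split between states is not identified.
    """
    D = np.asarray(D)
    d = sample.event == 1
    if not (np.any(D[d] == 1) and np.any(D[d] == 0)):
        raise NonConvergenceError(
            "events of both ascertainment types are required to identify the model"
        )
    px = sample.x.shape[1]
    n_haz = 1 if family == "exponential" else 2

    def make_hazard(theta_h):
        if family == "exponential":
            return ParametricHazard(rate=float(np.exp(theta_h[0])))
        return ParametricHazard(family="gamma", a=float(np.exp(theta_h[0])),
                                b=float(np.exp(theta_h[1])))

    def unpack(theta):
        beta = theta[: 1 + px]
        ha = make_hazard(theta[1 + px: 1 + px + n_haz])
        hb = make_hazard(theta[1 + px + n_haz:])
        return TwoStateParams(beta=beta, susceptible_hazard=ha, nonsusceptible_hazard=hb)

    def negll(theta):
        if np.max(np.abs(theta)) > 30:
            return 1e12
        val = -loglik_two_state(unpack(theta), sample, D)
        return val if np.isfinite(val) else 1e12

    try:
        b0 = fit_logistic_on_delta(sample).coef
    except NonConvergenceError:
        b0 = np.zeros(1 + px)
    rate_a = max(np.mean(d & (D == 1)) / max(np.mean(sample.time), 1e-8), 1e-4)
    rate_b = max(np.mean(d & (D == 0)) / max(np.mean(sample.time), 1e-8), 1e-4)
    if family == "exponential":
        start = np.concatenate([b0, [np.log(rate_a)], [np.log(rate_b)]])
    else:
        start = np.concatenate([b0, [0.0, np.log(rate_a)], [0.0, np.log(rate_b)]])

    res = optimize.minimize(negll, start, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    theta = res.x
    params = unpack(theta)

    from .parametric import _numeric_hessian

    hess = _numeric_hessian(negll, theta)
    se_theta = np.full(theta.size, np.nan)
    try:
        diag = np.diag(np.linalg.inv(hess))
        if np.all(diag > 0):
            se_theta = np.sqrt(diag)
    except np.linalg.LinAlgError:
        pass

    if family == "exponential":
        haz_labels = ["susceptible:rate", "nonsusceptible:rate"]
        haz_vals = [params.susceptible_hazard.rate, params.nonsusceptible_hazard.rate]
    else:
        haz_labels = ["susceptible:a", "susceptible:b",
                      "nonsusceptible:a", "nonsusceptible:b"]
        haz_vals = [params.susceptible_hazard.a, params.susceptible_hazard.b,
                    params.nonsusceptible_hazard.a, params.nonsusceptible_hazard.b]
    labels = (["incidence:intercept"] + [f"incidence:{n}" for n in sample.x_names]
              + haz_labels)
    # delta method: hazard params were optimised on the log scale
    se = se_theta.copy()
    se[1 + px:] *= np.asarray(haz_vals)
    grad_norm = float(np.max(np.abs(optimize.approx_fprime(theta, negll, 1e-7))))
    return FitResult(
        model=f"two_state_{family}",
        estimates=pd.Series(np.concatenate([params.beta, haz_vals]), index=labels),
        se=pd.Series(se, index=labels),
        loglik=-float(res.fun),
        converged=bool(res.success or grad_norm < 1e-3),
        diagnostics={"n_iter": int(res.get("nit", -1)), "grad_norm": grad_norm},
        extra={"params": params},
    )


# ---------------------------------------------------------------------------
# Wiener first-hitting-time model


@dataclass(frozen=True)
class WienerFHT:
    """Wiener process Z(t) = c0 + μ t + σ W(t), absorbed at 0.

    Sign convention: positive drift μ moves the process *away* from the
    barrier, so hitting is uncertain (improper inverse-Gaussian law) exactly
    when μ > 0.
    """

    c0: float
    mu: float
    sigma2: float = 1.0

    def __post_init__(self):
        if self.c0 <= 0 or self.sigma2 <= 0:
            raise ValidationError("c0 and sigma2 must be strictly positive")


def ig_cure_fraction(fht: WienerFHT) -> float:
    """Probability of never hitting the barrier: 1 − exp(−2 c0 μ / σ²) for
    μ > 0, and 0 otherwise (hitting is certain for μ ≤ 0)."""
    if fht.mu <= 0:
        return 0.0
    return float(1.0 - np.exp(-2.0 * fht.c0 * fht.mu / fht.sigma2))


def sample_fht(fht: WienerFHT, n: int, horizon: float = 100.0, step: float = 1e-3,
               seed: int = 0, block: int = 2000) -> np.ndarray:
    """Euler–Maruyama first-hitting times; np.inf for paths alive at the
    horizon.

    The discrete scheme can miss within-step crossings, so hitting
    probabilities carry a small positive bias that shrinks with ``step``
    (default 1e-3 years).  Simulation proceeds in blocks of ``block`` steps
    with absorbed paths retired, so cost is dominated by never-hitting paths.
    """
    if step <= 0 or horizon <= 0:
        raise ValidationError("step and horizon must be > 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    sigma = np.sqrt(fht.sigma2)
    n_steps = int(np.ceil(horizon / step))
    level = np.full(n, fht.c0)
    hit_time = np.full(n, np.inf)
    alive = np.arange(n)
    done_steps = 0
    while alive.size and done_steps < n_steps:
        m = min(block, n_steps - done_steps)
        incr = rng.normal(fht.mu * step, sigma * np.sqrt(step), size=(alive.size, m))
        paths = level[alive, None] + np.cumsum(incr, axis=1)
        hit_mask = paths <= 0.0
        any_hit = hit_mask.any(axis=1)
        first = np.argmax(hit_mask, axis=1)
        hit_time[alive[any_hit]] = (done_steps + first[any_hit] + 1) * step
        level[alive] = paths[:, -1]
        alive = alive[~any_hit]
        done_steps += m
    return hit_time
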