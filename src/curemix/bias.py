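"""Asymptotic bias of naive analyses of cure-model data.

Fitting logistic regression to the observed event indicator δ estimates
Pr(δ = 1 | x) = π(β0 + β1 x) · E_G[1 − S(C)], not the susceptibility
probability π.  For a binary exposure, the probability limit of the fitted
slope is

    plim β̂1 = β1 − log [ (1 + e^{β0+β1} E_G[S(C)]) / (1 + e^{β0} E_G[S(C)]) ],

so the slope is biased toward zero whenever the mean latency survival at
censoring E_G[S(C)] is positive — negatively when β1 > 0, vanishing as the
latency survival S drops to zero fast (diagnoses early in life) and
shrinking as β0 → −∞ (rare susceptibility).

For the Cox model no closed-form limit exists; the bias is controlled by the
near-constancy in x of g(x, t) = e^{β0 − A(t)} / (1 + e^{β0 + β1 x − A(t)}),
which holds only when β0 is small.  The diagnostic exposed here is the
maximal spread of g over a time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .data import ValidationError
from .simulate import logistic

__all__ = [
    "CensoringModel",
    "LatencyModel",
    "expected_surv_at_censoring",
    "plim_logistic_slope",
    "bias_curve",
    "g_function",
    "g_constancy_diagnostic",
]


@dataclass(frozen=True)
class CensoringModel:
    """Censoring-time distribution G on [0, ∞).

    family: "exponential" (rate), "point" (atom at ``atom``), or "empirical"
    (tabulated atoms with probabilities, defaulting to uniform weights).
    """

    family: str = "exponential"
    rate: float | None = None
    atom: float | None = None
    values: np.ndarray | None = None
    probs: np.ndarray | None = None

    def __post_init__(self):
        if self.family == "exponential":
            if self.rate is None or self.rate <= 0:
                raise ValidationError("exponential censoring needs rate > 0")
        elif self.family == "point":
            if self.atom is None or self.atom < 0:
                raise ValidationError("point-mass censoring needs atom >= 0")
        elif self.family == "empirical":
            v = np.asarray(self.values, dtype=float)
            if v.size == 0 or np.any(v < 0):
                raise ValidationError("empirical censoring needs nonnegative atoms")
            p = (np.full(v.size, 1.0 / v.size) if self.probs is None
                 else np.asarray(self.probs, dtype=float))
            if p.size != v.size or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValidationError("empirical probabilities must sum to 1")
            object.__setattr__(self, "values", v)
            object.__setattr__(self, "probs", p)
        else:
            raise ValidationError(f"unknown censoring family {self.family!r}")


@dataclass(frozen=True)
class LatencyModel:
    """Latency distribution of the susceptible group via its cumulative
    hazard A(t); S(t) = exp(−A(t)) must be proper.

    family: "exponential" (A(t) = rate · t) or "gamma" (A the cumulative
    hazard of a Gamma(a, b) distribution).  ``ph_log_multiplier`` tilts A by
    exp(·), the proportional-hazards effect of a latency covariate profile.
    """

    family: str = "exponential"
    rate: float | None = None
    a: float | None = None
    b: float | None = None
    ph_log_multiplier: float = 0.0

    def __post_init__(self):
        if self.family == "exponential":
            if self.rate is None or self.rate <= 0:
                raise ValidationError("exponential latency needs rate > 0")
        elif self.family == "gamma":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValidationError("gamma latency needs a, b > 0")
        else:
            raise ValidationError(f"unknown latency family {self.family!r}")

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            A = self.rate * t
        else:
            A = -stats.gamma.logsf(t, a=self.a, scale=1.0 / self.b)
        return np.exp(self.ph_log_multiplier) * A

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))


def expected_surv_at_censoring(latency: LatencyModel, censoring: CensoringModel) -> float:
    """E_G[S(C)], the mean latency survival at a random censoring time.

    Closed form λ_C / (λ_S + λ_C) for the exponential/exponential case;
    otherwise adaptive quadrature over [0, 1 − 1e−10 quantile of G] with the
    analytic tail bound added.
    """
    if censoring.family == "point":
        return float(latency.survival(censoring.atom))
    if censoring.family == "empirical":
        return float(np.sum(censoring.probs * latency.survival(censoring.values)))
    lam_c = censoring.rate
    if latency.family == "exponential" and latency.ph_log_multiplier == 0.0:
        return lam_c / (latency.rate + lam_c)
    upper = stats.expon.ppf(1.0 - 1e-10, scale=1.0 / lam_c)
    val, _ = integrate.quad(
        lambda c: latency.survival(c) * lam_c * np.exp(-lam_c * c),
        0.0, upper, epsabs=1e-8, limit=200,
    )
    # tail: S <= S(upper) on (upper, inf)
    val += float(latency.survival(upper)) * np.exp(-lam_c * upper)
    return float(val)


def plim_logistic_slope(beta0: float, beta1: float, latency: LatencyModel,
                        censoring: CensoringModel) -> float:
    """Probability limit of the naive logistic slope on cure data."""
    e = expected_surv_at_censoring(latency, censoring)
    return float(beta1 - (np.log1p(np.exp(beta0 + beta1) * e) - np.log1p(np.exp(beta0) * e)))


def bias_curve(
    grid,
    vary: str = "beta0",
    beta0: float = 1.2,
    beta1: float = 1.5,
    latency: LatencyModel | None = None,
    censoring: CensoringModel | None = None,
    exposure_prob: float = 0.5,
) -> pd.DataFrame:
    """plim, bias and expected uncensored fraction over a parameter grid.

    ``vary`` is "beta0" or "latency_rate".  The event-fraction column pools
    the exposure strata with weight ``exposure_prob`` on x = 1.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValidationError("grid must be nonempty")
    if latency is None:
        latency = LatencyModel(rate=1.0 / 8.0)
    if censoring is None:
        censoring = CensoringModel(rate=1.0 / 8.0)
    rows = []
    for v in grid:
        b0 = v if vary == "beta0" else beta0
        if vary == "latency_rate":
            lat = LatencyModel(family="exponential", rate=float(v),
                               ph_log_multiplier=latency.ph_log_multiplier)
        elif vary == "beta0":
            lat = latency
        else:
            raise ValidationError("vary must be 'beta0' or 'latency_rate'")
        e = expected_surv_at_censoring(lat, censoring)
        plim = plim_logistic_slope(b0, beta1, lat, censoring)
        event_frac = float(
            ((1 - exposure_prob) * logistic(b0) + exposure_prob * logistic(b0 + beta1))
            * (1.0 - e)
        )
        rows.append({vary: float(v), "plim": plim, "bias": beta1 - plim,
                     "event_fraction": event_frac, "EG_S_C": e})
    return pd.DataFrame(rows)


def g_function(beta0: float, beta1: float, latency: LatencyModel, x, t):
    """g(x, t) = e^{β0 − A(t)} / (1 + e^{β0 + β1 x − A(t)})."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t must be >= 0")
    A = latency.cumulative_hazard(t)
    x = np.asarray(x, dtype=float)
    return np.exp(beta0 - A) / (1.0 + np.exp(beta0 + beta1 * x - A))


def g_constancy_diagnostic(beta0: float, beta1: float, latency: LatencyModel,
                           t_grid=None) -> float:
    """max_t |g(1, t) − g(0, t)|: small when the Cox score equation is nearly
    unbiased on cure data (i.e. when β0 is small)."""
    if t_grid is None:
        t_grid = np.linspace(0.0, 40.0, 401)
    g1 = g_function(beta0, beta1, latency, 1.0, t_grid)
    g0 = g_function(beta0, beta1, latency, 0.0, t_grid)
    return float(np.max(np.abs(g1 - g0)))
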