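"""Synthetic right-censored cohorts drawn from a mixture cure model.

Stands in for an access-restricted registry cohort: a binary gestational
exposure shifts the log-odds of a latent susceptibility indicator Y drawn at
birth; susceptible subjects acquire a diagnosis time from a proportional-
hazards latency distribution; everyone is subject to independent exponential
administrative censoring.  Nonsusceptible subjects can never be diagnosed
(no false positives), so their latent event time is +inf and their observed
time is always the censoring time.

Randomness is inverse-transform throughout: one seeded PCG64 stream fills an
(n, k) uniform matrix row-major, so subject i always consumes the same fixed
slice of the stream — increasing n appends subjects without reshuffling the
draws of earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalSample, ValidationError

__all__ = [
    "SimulationConfig",
    "generate_cure_sample",
    "generate_two_state_sample",
    "logistic",
]


def logistic(u):
    """π(u) = e^u / (1 + e^u), evaluated stably."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative design for the cure-model cohort.

    Defaults reproduce the simulation design used throughout: incidence
    intercept β0 = 1.2 and exposure effect β1 = 1.5 on the log-odds scale,
    a balanced binary exposure, exponential latency with cumulative hazard
    A(t) = t/8 (susceptible mean time-to-diagnosis 8 years), and exponential
    censoring with mean 8 years.

    ``gamma_latency`` (if not None) puts a proportional-hazards coefficient on
    the exposure in the latency part, i.e. z = x = the exposure column.
    ``latency_family`` may be "exponential" (A(t) = latency_rate * t) or
    "gamma" (baseline survival that of a Gamma(latency_shape, latency_rate)
    distribution).
    """

    n: int = 4000
    beta0: float = 1.2
    beta1: float = 1.5
    exposure_prob: float = 0.5
    latency_rate: float = 1.0 / 8.0
    gamma_latency: float | None = None
    censor_rate: float = 1.0 / 8.0
    seed: int = 0
    latency_family: str = "exponential"
    latency_shape: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.latency_rate <= 0 or self.censor_rate <= 0:
            raise ValidationError("latency_rate and censor_rate must be > 0")
        if not 0 < self.exposure_prob < 1:
            raise ValidationError("exposure_prob must lie strictly in (0, 1)")
        if self.latency_family not in ("exponential", "gamma"):
            raise ValidationError("latency_family must be 'exponential' or 'gamma'")
        if self.latency_family == "gamma" and (self.latency_shape is None or self.latency_shape <= 0):
            raise ValidationError("gamma latency requires latency_shape > 0")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        return cls(**json.loads(s))


def _uniforms(seed: int, n: int, k: int) -> np.ndarray:
    """(n, k) uniforms filled row-major from one PCG64 stream: subject i owns
    draws [i*k, (i+1)*k), so the prefix is invariant to n."""
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.random(n * k).reshape(n, k)


def _latency_inverse(config: SimulationConfig, u: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Solve S(t) = u for t, where S(t) = S0(t)^exp(eta)."""
    # PH tilt: S0(T) = u^exp(-eta)
    q = np.exp(np.log(u) * np.exp(-eta))
    if config.latency_family == "exponential":
        return -np.log(q) / config.latency_rate
    return stats.gamma.isf(q, a=config.latency_shape, scale=1.0 / config.latency_rate)


def generate_cure_sample(config: SimulationConfig) -> tuple[SurvivalSample, pd.DataFrame]:
    """Draw one right-censored cohort from the cure model.

    Returns the observable :class:`SurvivalSample` (exposure as the single
    incidence covariate, and as the latency covariate when ``gamma_latency``
    is set) and a latent frame with the test-only columns ``Y`` (susceptible),
    ``t_tilde`` (latent diagnosis time, inf for Y = 0) and ``censor_time``.
    """
    u = _uniforms(config.seed, config.n, 4)
    x = (u[:, 0] < config.exposure_prob).astype(float)
    pi = logistic(config.beta0 + config.beta1 * x)
    y = (u[:, 1] < pi).astype(int)
    eta = config.gamma_latency * x if config.gamma_latency is not None else np.zeros(config.n)
    t_tilde = np.full(config.n, np.inf)
    sus = y == 1
    t_tilde[sus] = _latency_inverse(config, u[sus, 2], eta[sus])
    censor = -np.log(u[:, 3]) / config.censor_rate
    time = np.minimum(t_tilde, censor)
    event = (t_tilde <= censor).astype(int)
    z = x if config.gamma_latency is not None else np.empty((config.n, 0))
    sample = SurvivalSample(
        ids=np.arange(config.n),
        time=time,
        event=event,
        x=x,
        z=z,
        x_names=["exposure"],
        z_names=["exposure"] if config.gamma_latency is not None else [],
    )
    latent = pd.DataFrame({"Y": y, "t_tilde": t_tilde, "censor_time": censor})
    return sample, latent


def generate_two_state_sample(
    config: SimulationConfig, nonsusceptible_rate: float
) -> tuple[SurvivalSample, pd.DataFrame]:
    """Cohort in which nonsusceptibility can also be ascertained.

    Susceptible subjects (Y = 1) acquire diagnosis times with the configured
    latency hazard; nonsusceptible subjects (Y = 0) acquire *ascertainment*
    times with exponential hazard ``nonsusceptible_rate``.  Both compete with
    independent censoring.  The latent frame carries ``D`` = Y when an event
    of either type is observed (δ = 1) and 0 otherwise.
    """
    if nonsusceptible_rate <= 0:
        raise ValidationError("nonsusceptible_rate must be > 0")
    u = _uniforms(config.seed, config.n, 5)
    x = (u[:, 0] < config.exposure_prob).astype(float)
    pi = logistic(config.beta0 + config.beta1 * x)
    y = (u[:, 1] < pi).astype(int)
    eta = config.gamma_latency * x if config.gamma_latency is not None else np.zeros(config.n)
    t_lat = np.where(
        y == 1,
        _latency_inverse(config, u[:, 2], eta),
        -np.log(u[:, 3]) / nonsusceptible_rate,
    )
    censor = -np.log(u[:, 4]) / config.censor_rate
    time = np.minimum(t_lat, censor)
    event = (t_lat <= censor).astype(int)
    d = np.where(event == 1, y, 0)
    sample = SurvivalSample(
        ids=np.arange(config.n),
        time=time,
        event=event,
        x=x,
        z=np.empty((config.n, 0)),
        x_names=["exposure"],
    )
    latent = pd.DataFrame({"Y": y, "D": d, "state_time": t_lat, "censor_time": censor})
    return sample, latent
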