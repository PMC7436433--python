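"""Reproducible simulation experiments and the eight-model comparison.

``run_bias_experiment`` sweeps either the incidence intercept β0 or the
latency hazard rate α over a grid, simulating cure-model cohorts at each
point and fitting the semiparametric cure model, the naive logistic model
and the naive Cox model to every replicate.  The theoretical probability
limit of the naive logistic slope and the expected uncensored fraction are
attached per grid point, independently recomputed from the closed forms.

``run_comparison`` fits the standard battery of eight models to one sample:
logistic, Cox, and the gamma-baseline and semiparametric cure models in
three covariate configurations each (incidence only / both parts / latency
only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import CensoringModel, LatencyModel, expected_surv_at_censoring, plim_logistic_slope
from .data import ValidationError
from .naive import NonConvergenceError, fit_cox_ph, fit_logistic_on_delta
from .parametric import aic, fit_gamma_cure
from .semiparametric import bootstrap_se, fit_em_cure
from .simulate import SimulationConfig, generate_cure_sample, logistic

logger = logging.getLogger(__name__)

__all__ = ["ExperimentGrid", "run_bias_experiment", "run_comparison", "COMPARISON_MODELS"]


@dataclass
class ExperimentGrid:
    """Design of one bias sweep: which parameter varies, over which values,
    with how many simulation replicates per point."""

    vary: str                      # "beta0" | "latency_rate"
    values: np.ndarray
    replicates: int = 20
    base: SimulationConfig = field(default_factory=SimulationConfig)
    root_seed: int = 0

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValidationError("grid must be nonempty")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.vary not in ("beta0", "latency_rate"):
            raise ValidationError("vary must be 'beta0' or 'latency_rate'")


def run_bias_experiment(grid: ExperimentGrid, em_tol: float = 1e-6) -> pd.DataFrame:
    """Simulate and fit over the grid; one tidy row per (grid value, model).

    Columns: grid parameter, model, mean_estimate, sd_estimate, n_ok,
    n_failed, event_fraction (empirical mean), plim (theoretical, logistic).
    Deterministic under ``root_seed``: replicate r at grid index g uses seed
    root_seed + 10000 * g + r.
    """
    records = []
    for g, v in enumerate(grid.values):
        kw = {grid.vary: float(v)}
        estimates = {"semiparametric": [], "logistic": [], "cox": []}
        failures = {k: 0 for k in estimates}
        event_fracs = []
        for r in range(grid.replicates):
            seed = grid.root_seed + 10000 * g + r
            config = grid.base.with_(seed=seed, **kw)
            sample, _ = generate_cure_sample(config)
            event_fracs.append(sample.n_events / sample.n)
            try:
                fit = fit_em_cure(sample, tol=em_tol)
                estimates["semiparametric"].append(
                    float(fit.estimates["incidence:exposure"]))
            except NonConvergenceError as exc:
                failures["semiparametric"] += 1
                logger.warning("EM failed at %s=%.3g seed=%d: %s", grid.vary, v, seed, exc)
            try:
                estimates["logistic"].append(float(fit_logistic_on_delta(sample).coef[1]))
            except NonConvergenceError as exc:
                failures["logistic"] += 1
                logger.warning("logistic failed at %s=%.3g seed=%d: %s", grid.vary, v, seed, exc)
            try:
                cox = fit_cox_ph(sample)
                if cox.diverged:
                    raise NonConvergenceError("monotone likelihood")
                estimates["cox"].append(float(cox.coef[0]))
            except NonConvergenceError as exc:
                failures["cox"] += 1
                logger.warning("cox failed at %s=%.3g seed=%d: %s", grid.vary, v, seed, exc)

        beta0 = float(v) if grid.vary == "beta0" else grid.base.beta0
        rate = float(v) if grid.vary == "latency_rate" else grid.base.latency_rate
        latency = LatencyModel(rate=rate)
        censoring = CensoringModel(rate=grid.base.censor_rate)
        plim = plim_logistic_slope(beta0, grid.base.beta1, latency, censoring)
        for model, vals in estimates.items():
            vals = np.asarray(vals)
            records.append({
                grid.vary: float(v),
                "model": model,
                "mean_estimate": float(vals.mean()) if vals.size else np.nan,
                "sd_estimate": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n_ok": int(vals.size),
                "n_failed": failures[model],
                "event_fraction": float(np.mean(event_fracs)),
                "plim": plim,
                "beta1_true": grid.base.beta1,
            })
    return pd.DataFrame(records)


COMPARISON_MODELS = (
    "logistic", "cox",
    "gamma_1", "gamma_2", "gamma_3",
    "semipara_1", "semipara_2", "semipara_3",
)

# configuration k -> (incidence covariates?, latency covariates?):
# model 1 treats diagnosis times as i.i.d. (covariates in the incidence part
# only), model 2 puts them in both parts, model 3 in the latency part only.
_CONFIGS = {1: (True, False), 2: (True, True), 3: (False, True)}


def run_comparison(sample, bootstrap_B: int = 0, seed: int = 0,
                   em_tol: float = 1e-6) -> pd.DataFrame:
    """Fit the eight-model battery to one sample; tidy rows per term.

    Columns: model, part, term, estimate, se, aic (standard sign, parametric
    cure fits only), converged.  ``bootstrap_B`` > 0 turns on bootstrap SEs
    for the semiparametric fits (costly).  Individual model failures are
    reported as rows with error set and do not abort the battery.
    """
    out = []

    def add(df, model, aic_std=np.nan, converged=True):
        df = df.copy()
        df["aic"] = aic_std
        df["converged"] = converged
        df["error"] = ""
        out.append(df)

    def fail(model, exc):
        out.append(pd.DataFrame([{"model": model, "part": "", "term": "",
                                  "estimate": np.nan, "se": np.nan, "aic": np.nan,
                                  "converged": False, "error": str(exc)}]))
        logger.warning("%s failed: %s", model, exc)

    try:
        add(fit_logistic_on_delta(sample).tidy("logistic"), "logistic")
    except NonConvergenceError as exc:
        fail("logistic", exc)
    try:
        cox = fit_cox_ph(sample)
        add(cox.tidy("cox"), "cox", converged=cox.converged and not cox.diverged)
    except NonConvergenceError as exc:
        fail("cox", exc)

    for k, (inc, lat) in _CONFIGS.items():
        name = f"gamma_{k}"
        try:
            fit = fit_gamma_cure(sample, incidence=inc, latency=lat)
            df = fit.tidy()
            df["model"] = name
            add(df, name, aic_std=aic(fit).standard, converged=fit.converged)
        except NonConvergenceError as exc:
            fail(name, exc)

    for k, (inc, lat) in _CONFIGS.items():
        name = f"semipara_{k}"
        try:
            fit = fit_em_cure(sample, incidence=inc, latency=lat, tol=em_tol)
            df = fit.tidy()
            df["model"] = name
            if bootstrap_B:
                se = bootstrap_se(sample, B=bootstrap_B, seed=seed,
                                  incidence=inc, latency=lat, tol=em_tol)
                df["se"] = se.reindex(fit.estimates.index).to_numpy()
            add(df, name, converged=fit.converged)
        except NonConvergenceError as exc:
            fail(name, exc)

    return pd.concat(out, ignore_index=True)
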