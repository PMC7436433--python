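# Methods

## Model

A subject is born susceptible (Y = 1) with probability π(x'β), logistic in
the gestational covariates x (intercept first in β). Susceptible subjects
acquire a diagnosis time T̃ with proper survival function
S(t | z) = S0(t)^{exp(z'γ)}, proportional hazards in the postnatal
covariates z; nonsusceptible subjects are never diagnosed (T̃ = ∞, i.e. no
false positives). Observation is right-censored: T = min(T̃, C),
δ = 1{T̃ ≤ C}, with C independent of (Y, T̃) given covariates. The
population survival function is S_pop(t) = 1 − π + π S(t), tending to the
cure fraction 1 − π. An observed diagnosis proves Y = 1; a censored record
leaves Y latent.

The observed-data log-likelihood is

    ℓ(β, γ, S0) = Σ_i δ_i [log π_i + log α0(t_i) + z_i'γ + log S_i(t_i)]
                + (1 − δ_i) log(1 − π_i + π_i S_i(t_i)).

## Fitters

**Parametric (gamma baseline).** S0 is the survival function of a
Gamma(a, b) distribution (density (b^a/Γ(a)) t^{a−1} e^{−bt}; a = 1 gives
the exponential special case). ℓ is maximised by BFGS over
(β, γ, log a, log b) — the log scale enforces positivity — with a
Nelder–Mead polish if BFGS reports failure. Starting values: β from the
naive logistic fit on δ, γ = 0, (a, b) by method of moments on the
uncensored event times. Standard errors come from the inverse central-
difference Hessian (delta method back to (a, b)); if the Hessian is not
positive definite the SEs are reported as NaN. Wald 95% intervals
(estimate ± 1.96 SE) are provided and labelled as such. Events at exactly
t = 0 are rejected (the gamma hazard is unbounded or zero there). AIC is
reported in both sign conventions (−2ℓ + 2k, smaller better; and 2ℓ − 2k,
larger better) because both appear in published tables; comparison
utilities use the standard one.

**Semiparametric (EM, step baseline).** The baseline is a step function
with Breslow cumulative-hazard increments at the distinct event times. The
E-step gives censored subjects the posterior susceptibility weight
w = πS/(1 − π + πS) (w = 1 for events); the M-step is a weighted logistic
MLE with w as working response and a fractional-risk-set weighted Cox
partial likelihood (censored subjects enter risk sets with multiplier w)
followed by a weighted Breslow baseline update. Ties share one increment.
Survival is the **product-limit transform** Π(1 − ΔΛ_k) of the increments —
the nonparametric-MLE form, reducing exactly to Kaplan–Meier when all
weights are 1 — rather than exp(−Λ). This matters: the exponential
transform overestimates the baseline tail, and under slow latency hazards
with unbounded censoring that lets the incidence estimates creep along a
nearly flat likelihood ridge (see Limitations). The **zero-tail
constraint** — S0 ≡ 0 strictly beyond the largest observed event time — is
applied at every iteration, which is what identifies the cure fraction
when latency and censoring have overlapping support: subjects censored
past the last event are treated as certainly nonsusceptible (w = 0).
Convergence: maximum absolute change over (β, γ) below 1e−6, at most 500
iterations. The observed-data log-likelihood (discrete form: events carry
the mass S_i(t−) − S_i(t)) is traced per iteration; because the latency
M-step maximises a partial-likelihood approximation, exact EM monotonicity
is not guaranteed, but the trace is nondecreasing on every replicate we
test (tests allow 1e−6 slack). Standard errors are by nonparametric
bootstrap of subjects (default B = 100; replicate r seeded seed ⊕ r);
non-converged replicates are dropped and counted, with a warning above
20% failures.

**Naive comparison fitters.** Logistic regression on δ and Cox regression
on (T, δ) are implemented directly from their estimating equations
(Newton–Raphson with step-halving; Breslow ties and baseline for Cox)
because their behaviour on cure data is itself under study and the same
weighted kernels drive the EM. Convergence requires max |score| < 1e−8 (or
a Newton step that no longer moves the iterate); divergence — complete
separation for the logistic model, monotone partial likelihood for Cox —
is flagged when coefficients escape past 20 (logistic, raised as an error)
or 15 (Cox, flagged on the result).

## Bias theory

For a binary exposure the naive logistic slope converges to
β1 − log[(1 + e^{β0+β1}E)/(1 + e^{β0}E)] with E = E_G[S(C)]; E has the
closed form λ_C/(λ_S + λ_C) for exponential latency and censoring and is
otherwise computed by adaptive quadrature to 1e−8 over G's 1 − 1e−10
quantile range with the analytic tail bound added. The slope is attenuated
toward zero whenever E > 0, vanishing as the latency hazard grows or
β0 → −∞. For the Cox model no closed-form limit exists; the package
exposes the spread max_t |g(1, t) − g(0, t)| of
g(x, t) = e^{β0−A(t)}/(1 + e^{β0+β1x−A(t)}) as the bias diagnostic (small
when β0 is small), and the latency-invariance of the Cox estimate is
verified empirically in the experiment runner.

## Synthetic cohorts

The generator emulates the structure of a registry mother–child cohort
that cannot be redistributed: binary gestational exposure, latent
susceptibility, continuous diagnosis ages, administrative right censoring.
Defaults are the reference simulation design: β0 = 1.2, β1 = 1.5 (so
π = 0.77 unexposed and 0.94 exposed), exposure probability 0.5 (the
balanced choice; the split maximises information), exponential latency
A(t) = t/8, exponential censoring with mean 8 years. A gamma latency
family and a PH latency coefficient on the exposure are available for
recovery and comparison experiments. All draws are inverse-transform from
an (n, k) uniform matrix filled row-major by one seeded PCG64 stream, so
output is reproducible byte-for-byte and growing n appends subjects
without disturbing earlier ones. What the generator does **not** emulate:
confounding structure, covariate-dependent or non-exponential censoring,
calendar-time cohort effects, diagnosis-age clustering beyond what the
latency law implies, and false-positive diagnoses. Passing recovery tests
therefore show correctness of the estimators under the stated model, not
robustness to those real-data features.

## Extensions

**Two-state ascertainment.** When nonsusceptibility can itself be
observed (hazard β(t) for Y = 0, α(t) for Y = 1, D = Y on events),
the likelihood multiplies π_i α e^{−∫α} over D = 1 events,
(1 − π_i) β e^{−∫β} over D = 0 events, and the mixture
π e^{−∫α} + (1 − π)e^{−∫β} over censored records. Hazards are parametric
(exponential or gamma); both ascertainment processes are independently
censored. Fitting is BFGS on (β, log hazard parameters) with
inverse-Hessian SEs; both event types must be present for identification.

**Wiener first-hitting-time.** Z(t) = c0 + μt + σW(t) absorbed at 0;
hitting times are inverse-Gaussian, improper when μ > 0 (drift away from
the barrier — the sign convention is that larger μ and c0 mean *less*
susceptible) with never-hit probability 1 − exp(−2c0μ/σ²). The simulator
is Euler–Maruyama (default step 1e−3) without within-step bridge
correction, so hitting probabilities carry a small positive bias of order
√step; tests size their tolerances accordingly.

## Experiment runners and problem sizes

`run_bias_experiment` sweeps β0 or the latency rate, fitting EM cure,
logistic and Cox per replicate and attaching the independently recomputed
plim and expected event fraction per grid point (defaults: 20 replicates,
5–9 grid points; bootstrap SEs are off inside sweeps, matching what the
point-estimate comparison needs). `run_comparison` fits the eight-model
battery (logistic, Cox, gamma and EM cure each with covariates in the
incidence part only / both parts / latency part only). The shipped
recovery studies use 50 replicates of n = 4000 — spot checks at larger n
and replicate counts gave the same conclusions — and the large-sample plim
checks use single cohorts of n = 10⁶, where the binomial Monte-Carlo error
of the slope is ~0.004.

## Known limitations

- Under the reference design, latency and censoring both have support
  [0, ∞), so semiparametric identifiability rests entirely on the
  zero-tail constraint, which binds only through the handful of subjects
  censored past the last event. The profile likelihood in (β, baseline
  tail) is then nearly flat and the EM estimate of the incidence
  coefficients has a heavy right tail across replicates (occasionally
  diverging replicates are visible as estimates of 3–4); the replicate
  *mean* still tracks the generating value, which is what the recovery
  checks assert. The effect grows with β0 (as π → 1) and with n held at
  moderate sizes; bounded censoring or a parametric baseline removes it.
- No analytic SEs for the EM fit (bootstrap only); no stratified Cox,
  time-varying covariates, left truncation or interval censoring; no
  Weibull/log-normal baselines; no regression structure on c0 in the
  hitting-time model.
- The cohort-summary utilities round half-up to match published tables;
  fitting never uses rounded values.
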