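# curemix

Mixture cure models for perinatal epidemiology, where the scientific outcome
is a **censored binary variable**: a child is born susceptible (Y = 1) or not
(Y = 0) to a condition — the motivating example is ADHD following gestational
exposure to paracetamol — but susceptibility is only revealed if a diagnosis
arrives before follow-up ends. Treating the observed event indicator δ as if
it were Y (logistic regression), or the time to diagnosis as the outcome
(Cox regression), answers a different question and gives biased estimates of
the exposure effect on susceptibility.

## The model

The population survival function is a two-part mixture

    S_pop(t | x, z) = 1 − π(x'β) + π(x'β) · S(t | z),
    π(u) = e^u / (1 + e^u),
    S(t | z) = S0(t)^{exp(z'γ)},

with an **incidence** part (logistic in gestational covariates x, giving the
probability of being born susceptible) and a **latency** part (proportional
hazards in postnatal covariates z, giving the time to diagnosis among the
susceptible). The baseline S0 is either the survival function of a
Gamma(a, b) distribution (full maximum likelihood) or an unspecified step
function fitted by EM with a Breslow baseline and the zero-tail
identifiability constraint (S0 ≡ 0 beyond the largest observed diagnosis
time), with bootstrap standard errors.

The package also provides, in closed form, the probability limit of the
naive logistic slope fitted to cure data with a binary exposure,

    plim β̂1 = β1 − log[(1 + e^{β0+β1} E_G[S(C)]) / (1 + e^{β0} E_G[S(C)])],

where E_G[S(C)] is the mean latency survival at a random censoring time —
the quantity that drives the attenuation — plus the g(x, t) near-constancy
diagnostic explaining when the Cox estimate is trustworthy, a synthetic
cohort generator standing in for access-restricted registry data, a
two-state extension for data in which nonsusceptibility can be ascertained,
and a Wiener first-hitting-time model whose improper inverse-Gaussian
hitting law yields a continuous notion of susceptibility.

## Worked example

```python
import numpy as np
from curemix import (SimulationConfig, generate_cure_sample, fit_em_cure,
                     fit_logistic_on_delta, plim_logistic_slope,
                     LatencyModel, CensoringModel)

cfg = SimulationConfig(n=4000, beta0=1.2, beta1=1.5,
                       latency_rate=1/8, censor_rate=1/8, seed=0)
sample, latent = generate_cure_sample(cfg)
print(sample.n_events / sample.n)                  # 0.4375

cure = fit_em_cure(sample)
print(float(cure.estimates["incidence:exposure"]))  # 1.5597  (truth 1.5)

naive = fit_logistic_on_delta(sample)
print(float(naive.coef[1]))                         # 0.3757  (attenuated)

print(plim_logistic_slope(1.2, 1.5, LatencyModel(rate=1/8),
                          CensoringModel(rate=1/8)))  # 0.34538
```

About 44% of subjects are ever diagnosed, although 77–94% are susceptible:
the censoring hides the rest. The EM cure model recovers the exposure's
log-odds effect on susceptibility (1.56, truth 1.5 — one replicate), while
logistic regression on δ lands near its theoretical limit 0.345 — a
four-fold attenuation exactly predicted by the plim formula.

Short narrative scripts in `examples/` cover each capability: cohort
summaries, sample generation, the naive-model bias sweep, the eight-model
comparison, and the two extension models. The `curemix` command exposes the
same operations from the shell (`curemix --help`).

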