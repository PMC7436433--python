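"""Generate a censored cohort from the cure model and fit all four fitters.

The generating truth puts a log-odds effect of 1.5 on susceptibility and no
effect on the diagnosis times. The cure models estimate that incidence
effect; the naive logistic and Cox fits estimate attenuated quantities.
"""

from curemix import (SimulationConfig, aic, fit_cox_ph, fit_em_cure,
                     fit_gamma_cure, fit_logistic_on_delta,
                     generate_cure_sample)

cfg = SimulationConfig(n=4000, beta0=1.2, beta1=1.5, seed=0)
sample, latent = generate_cure_sample(cfg)
print(f"{sample.n} subjects, {sample.n_events} diagnoses observed, "
      f"{int(latent['Y'].sum())} truly susceptible\n")

em = fit_em_cure(sample)
print("semiparametric cure (EM):")
print(em.tidy().to_string(index=False))

gam = fit_gamma_cure(sample)
print("\ngamma-baseline cure (AIC %.1f):" % aic(gam).standard)
print(gam.tidy().to_string(index=False))

print("\nnaive logistic slope: %.3f   naive Cox coefficient: %.3f"
      % (fit_logistic_on_delta(sample).coef[1], fit_cox_ph(sample).coef[0]))
print("Both cure fits sit near the generating value 1.5; the naive fits "
      "are pulled toward zero by the censored susceptibles.")
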