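"""The eight-model comparison on one synthetic cohort.

Data are generated with the exposure acting on incidence only (its latency
coefficient is zero). The both-parts cure models should therefore put a
positive estimate on the incidence exposure term and ~0 on the latency one.
"""

from curemix import SimulationConfig, generate_cure_sample, run_comparison

cfg = SimulationConfig(n=3000, latency_rate=0.5, gamma_latency=0.0, seed=88)
sample, _ = generate_cure_sample(cfg)
report = run_comparison(sample)
print(report.round(3).to_string(index=False))
print("\nModels *_1 put covariates in the incidence part only, *_2 in both "
      "parts, *_3 in the latency part only. AIC is reported for the "
      "parametric cure fits; note the latency exposure estimates near zero "
      "in gamma_2/semipara_2, matching the generating truth.")
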