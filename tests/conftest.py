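import numpy as np
import pytest

from curemix import SimulationConfig, SurvivalSample, generate_cure_sample


@pytest.fixture(scope="session")
def design_sample():
    """One cohort from the reference simulation design (n=4000, β0=1.2,
    β1=1.5, exponential latency A(t)=t/8, exponential censoring mean 8)."""
    sample, latent = generate_cure_sample(SimulationConfig(n=4000, seed=11))
    return sample, latent


@pytest.fixture(scope="session")
def fast_sample():
    """Well-identified cohort: fast latency hazard, so most susceptible
    subjects are diagnosed and the cure fraction is sharply estimable."""
    cfg = SimulationConfig(n=2000, latency_rate=0.5, seed=3)
    sample, latent = generate_cure_sample(cfg)
    return sample, latent


@pytest.fixture
def toy_sample():
    """Tiny hand-built sample: 8 subjects, one binary covariate in both parts."""
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    return SurvivalSample(
        ids=np.arange(8),
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]),
        event=np.array([1, 1, 1, 0, 1, 0, 1, 0]),
        x=x,
        z=x,
        x_names=["exposure"],
        z_names=["exposure"],
    )


def two_by_two_sample(n0, d0, n1, d1):
    """Sample with binary covariate strata of sizes n0/n1 and event counts
    d0/d1 (times arbitrary but positive)."""
    x = np.concatenate([np.zeros(n0), np.ones(n1)])
    event = np.concatenate(
        [np.ones(d0), np.zeros(n0 - d0), np.ones(d1), np.zeros(n1 - d1)]
    )
    time = np.linspace(1.0, 10.0, n0 + n1)
    return SurvivalSample(ids=np.arange(n0 + n1), time=time, event=event,
                          x=x, z=x, x_names=["exposure"], z_names=["exposure"])
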