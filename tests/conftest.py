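import numpy as np
import pandas as pd
import pytest

from ckdphen.synthetic import SimulationConfig, generate_cohort


def obs_frame(pairs, start="2019-01-01"):
    """Observation table from (hours, value) pairs."""
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(hours=h) for h, _ in pairs],
            "value": [v for _, v in pairs],
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient cohort at default settings, reused across tests."""
    cfg = SimulationConfig(n_patients=200, seed=11)
    bundle, truth = generate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def coding_cohort():
    """A 2000-patient cohort for binomial checks of coding error rates."""
    cfg = SimulationConfig(n_patients=2000, ckd_prevalence=0.3, seed=5)
    bundle, truth = generate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
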