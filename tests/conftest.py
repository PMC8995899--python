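import numpy as np
import pandas as pd
import pytest

from crdcnet import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale cohort used by several stage tests."""
    return SimulationConfig(
        n_genes=300, n_lncrnas=60, n_mirnas=80,
        n_tumor=200, n_adjacent=30, n_cin_high=100, n_cin_low=100,
        n_planted_gain=6, n_planted_loss=6, shared_mirna_overlap=8,
        n_cin_like_genes=40, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the generator's default design (300 samples/CIN stratum)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def survival_300():
    """Null exponential survival, 300 samples, ~30% censoring."""
    rng = np.random.default_rng(5)
    n = 300
    t = rng.exponential(100.0, n)
    c = rng.uniform(0, 300.0, n)
    event = t <= c
    return pd.DataFrame(
        {"time": np.minimum(t, c), "event": event},
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample"),
    )
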