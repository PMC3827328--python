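import numpy as np
import pytest

from clpv.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n = 20,000 applicants, seed 1)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for sampler-heavy tests."""
    return simulate_cohort(SimulationConfig(n_applicants=5000, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20130)
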