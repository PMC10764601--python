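import numpy as np
import pytest

import sepid as sp


@pytest.fixture(scope="session")
def study1_config():
    """Correctly-specified study-1 conditions at a moderate sample size."""
    return sp.make_scenario(1, "i", n=2000, seed=101)


@pytest.fixture(scope="session")
def study1_data(study1_config):
    return sp.simulate_observed_study1(study1_config)


@pytest.fixture(scope="session")
def fitted_nuisances(study1_data):
    return sp.fit_nuisances(study1_data)


@pytest.fixture(scope="session")
def oracle_nuisances(study1_config):
    return sp.true_nuisances(study1_config)


@pytest.fixture(scope="session")
def big_study1_data():
    cfg = sp.make_scenario(1, "i", n=10_000, seed=77)
    return cfg, sp.simulate_observed_study1(cfg)
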