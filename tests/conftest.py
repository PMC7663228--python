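import numpy as np
import pytest

from peerlca import synthetic
from peerlca.config import SimulationConfig, default_config


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=7)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    return synthetic.generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """A 4-school, 140-pupil variant of the default configuration."""
    d = default_config(seed=11).to_dict()
    d["n_schools"] = 4
    d["school_sizes"] = (35, 35, 35, 35)
    return SimulationConfig.from_dict(d)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return synthetic.generate_cohort(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
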