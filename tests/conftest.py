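import datetime as dt

import numpy as np
import pytest

from loopsim import ValueChainModel, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def baseline_run(config):
    """One full-horizon do-nothing run, shared across the session."""
    return ValueChainModel(config).simulate(seed=1)


@pytest.fixture(scope="session")
def short_run(config):
    """A run truncated at the end of the historical evaluation window."""
    return ValueChainModel(config).simulate(seed=1, end_date=dt.date(2018, 8, 25))


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))
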