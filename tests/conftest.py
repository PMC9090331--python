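import numpy as np
import pytest

from osmovol import default_hela_params, solve_steady_state


@pytest.fixture(scope="session")
def hela_params():
    return default_hela_params()


@pytest.fixture(scope="session")
def hela_steady(hela_params):
    return solve_steady_state(hela_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
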