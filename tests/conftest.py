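import numpy as np
import pytest

from nfkbuv import default_parameters, standard_protocols
from nfkbuv.model import relax_to_steady_state


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def protocols():
    return standard_protocols()


@pytest.fixture(scope="session")
def steady_state(params):
    return relax_to_steady_state(params)


@pytest.fixture(scope="session")
def grid16():
    return np.linspace(0.0, 16.0, 241)


@pytest.fixture(scope="session")
def noiseless_data():
    """Standardised datasets generated without noise from the defaults."""
    from nfkbuv.synth import default_design, generate

    datasets, truth = generate(default_design(rel_sd=0.0))
    return datasets, truth


@pytest.fixture(scope="session")
def noisy_data():
    from nfkbuv.synth import default_design, generate

    datasets, truth = generate(default_design(seed=1))
    return datasets, truth
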