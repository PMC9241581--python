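import warnings

import pytest

from nsclc_cea import load_packaged_inputs, run_all
from nsclc_cea.synthetic import gen_inputs

# lifelines emits optimizer RuntimeWarnings on some bootstrap fits; they are
# inspected explicitly where relevant
warnings.filterwarnings("ignore", category=RuntimeWarning, module="lifelines")


@pytest.fixture(scope="session")
def uk_inputs():
    return load_packaged_inputs("uk")


@pytest.fixture(scope="session")
def china_inputs():
    return load_packaged_inputs("china")


@pytest.fixture(scope="session")
def uk_results(uk_inputs):
    return run_all(uk_inputs)


@pytest.fixture(scope="session")
def china_results(china_inputs):
    return run_all(china_inputs)


@pytest.fixture(scope="session")
def small_inputs():
    """Small randomized input set (4 arms, 6-year horizon) for fast tests."""
    return gen_inputs(seed=7, n_arms=4, horizon_weeks=312)
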