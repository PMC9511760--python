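import numpy as np
import pytest

from capecea import default_life_table, default_parameters
from capecea.synthetic_trial import TrialConfig, generate_trial


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def short_params(params):
    """A 72-cycle horizon for tests that loop over cycles by hand."""
    import dataclasses

    return dataclasses.replace(params, horizon=72)


@pytest.fixture(scope="session")
def trial_records():
    return generate_trial(TrialConfig(seed=11))


@pytest.fixture(scope="session")
def base_result(params, life_table):
    from capecea import base_case

    return base_case(params, life_table)
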