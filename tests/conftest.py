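import numpy as np
import pytest

import osteosim as om
from osteosim.fixtures import homogeneous_inputs


@pytest.fixture(scope="session")
def params():
    """The shipped default parameter set."""
    return om.default_parameter_set()


@pytest.fixture(scope="session")
def homog_params():
    """All relative risks 1, mortality off: every risk group identical."""
    return om.build_parameter_set(homogeneous_inputs(no_mortality=True))


@pytest.fixture(scope="session")
def homog_mortal_params():
    """All relative risks 1, life-table mortality on."""
    return om.build_parameter_set(homogeneous_inputs(no_mortality=False))


@pytest.fixture(scope="session")
def small_cohort(params):
    """A 2,000-woman base-case cohort shared across read-only tests."""
    return om.run_cohort(om.BASE_CASE, params, 2_000, seed=11)


@pytest.fixture(scope="session")
def small_costs(params, small_cohort):
    return om.compute_costs(small_cohort, params)
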