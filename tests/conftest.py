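import numpy as np
import pytest

from pedcea.cohort import GroupParams, default_group_params, generate_cohort
from pedcea.daly import DalyParams


@pytest.fixture(scope="session")
def all_cancers_params() -> DalyParams:
    """Published all-cancers inputs: mean age 6.4 y, 5-year OS 73.1%."""
    return DalyParams(age_at_dx=6.4, os5=0.731)


@pytest.fixture(scope="session")
def all_cancers_cost() -> float:
    """Median 3-year treatment cost for all cancers combined (USD 2019)."""
    return 19799.0


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient synthetic registry over three diagnostic groups."""
    groups = [
        GroupParams("alpha", 0.5, 0.80, 20000.0),
        GroupParams("beta", 0.3, 0.60, 30000.0),
        GroupParams("gamma", 0.2, 0.90, 8000.0),
    ]
    return generate_cohort(groups, 600, horizon=8.0, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default registry (n = 8886, seed 1)."""
    return generate_cohort(default_group_params(), 8886, horizon=8.0, seed=1)
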