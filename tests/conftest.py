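import pytest
from hypothesis import settings

import hfdx as H

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return H.default_schema()


@pytest.fixture(scope="session")
def ckm():
    return H.default_hf_ckm()


@pytest.fixture(scope="session")
def small_cohort():
    """Complete (no-Missing) synthetic cohort, n=200."""
    return H.generate_cohort(H.table1_default_spec(n=200, seed=3))


@pytest.fixture(scope="session")
def train_cohort():
    """Standard training cohort: n=600, 10% MCAR missingness."""
    spec = H.table1_default_spec(n=600, seed=11).with_missingness(0.10)
    return H.generate_cohort(spec)


@pytest.fixture(scope="session")
def test_cohort():
    """Standard held-out cohort: n=598, 10% MCAR missingness."""
    spec = H.table1_default_spec(n=598, seed=12).with_missingness(0.10)
    return H.generate_cohort(spec)
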