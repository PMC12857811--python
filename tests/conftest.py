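import numpy as np
import pytest

from saaconcord import load_reference_cohort, reference_rulesets


@pytest.fixture(scope="session")
def reference():
    """Packaged cohort records and published per-lab results."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def records(reference):
    return reference[0]


@pytest.fixture(scope="session")
def results(reference):
    return reference[1]


@pytest.fixture(scope="session")
def rulesets():
    return reference_rulesets()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
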