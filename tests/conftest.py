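import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from varstab import codons, consensus, synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The packaged 52-row missense predictor panel with published labels."""
    return consensus.load_table1()


@pytest.fixture(scope="session")
def table1_results(table1):
    results, report = consensus.classify_table(table1)
    return results, report


@pytest.fixture(scope="session")
def human_adapt():
    """Relative adaptiveness derived from the embedded human usage table."""
    return codons.relative_adaptiveness(codons.load_usage_table())


@pytest.fixture(scope="session")
def helix169():
    return synth.helical_reference(169, atoms="calpha")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
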