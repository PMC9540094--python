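import pytest
from hypothesis import HealthCheck, settings

from congruity.fixtures import bmi_example_fixture
from congruity.lattice import build_lattice

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bmi():
    """The built-in worked example (records, schema, context, instances)."""
    return bmi_example_fixture()


@pytest.fixture(scope="session")
def bmi_lattice(bmi):
    return build_lattice(bmi.context)
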