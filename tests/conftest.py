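import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ba_prioritize.fixtures import load_reference_fixture


@pytest.fixture(scope="session")
def table2():
    """28 published trio variants as (TrioRecord, AnnotatedVariant) pairs."""
    return load_reference_fixture("table2")


@pytest.fixture(scope="session")
def table2_records(table2):
    return [rec for rec, _ in table2]


@pytest.fixture(scope="session")
def table2_annotations(table2):
    return {ann.key: ann for _, ann in table2}


@pytest.fixture(scope="session")
def table3():
    return load_reference_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return load_reference_fixture("table4")
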