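import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The packaged 47-treatment-mean database of added calorimetry studies."""
    from ruminergy import load_table1

    return load_table1()


@pytest.fixture(scope="session")
def table1_derived(table1):
    from ruminergy import with_derived

    return with_derived(table1)
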