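import pytest
from hypothesis import HealthCheck, settings

from cyp2d6star import default_table, reconstruct_karen_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def karen_cohort(table):
    return reconstruct_karen_cohort(table)


@pytest.fixture(scope="session")
def karen_summary(table, karen_cohort):
    from cyp2d6star import call_batch, summarize_cohort

    return summarize_cohort(call_batch(karen_cohort, table), table)
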