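import warnings

import pytest
from hypothesis import HealthCheck, settings

import privcohort as pc
from privcohort import threat

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return pc.default_schema()


@pytest.fixture(scope="session")
def classification(schema):
    return threat.classify(threat.default_profiles(), schema=schema)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-record cohort shared by read-only tests."""
    return pc.generate_cohort(pc.CohortGenConfig(n_records=400, seed=11))


@pytest.fixture(scope="session")
def split_400(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pc.split_cohort(small_cohort, (0.35, 0.35, 0.3), seed=12)
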