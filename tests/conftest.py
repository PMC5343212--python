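import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trial_ledger():
    from minutecost import datasets

    return datasets.load_trial_ledger()


@pytest.fixture(scope="session")
def trial_outcomes():
    from minutecost import datasets

    return datasets.load_trial_outcomes()


@pytest.fixture(scope="session")
def gain_overrides():
    from minutecost import datasets

    return dict(datasets.ACCELEROMETER_GAIN_TOTALS)
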