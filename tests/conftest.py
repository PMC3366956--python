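import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """A short synthetic session shared by I/O and pipeline tests."""
    from hippocode.synthgen import gen_session

    return gen_session(3, trial_duration=60.0, n_pyr=6, n_int=2)
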