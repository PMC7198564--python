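import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bold():
    from mbsim.irf import bold_boynton

    return bold_boynton()


@pytest.fixture(scope="session")
def mion(bold):
    from mbsim.irf import mion_model, splice_smooth_onset

    return splice_smooth_onset(mion_model(), bold)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
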