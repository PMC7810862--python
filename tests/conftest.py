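import numpy as np
import pytest
from hypothesis import settings

import tworate as tw

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    """The standard 64/160/16/48 paradigm."""
    return tw.build_schedule()


@pytest.fixture(scope="session")
def pause_params():
    return tw.GROUP_PARAMS["pause"]


@pytest.fixture(scope="session")
def nocursor_params():
    return tw.GROUP_PARAMS["nocursor"]


@pytest.fixture(scope="session")
def pause_trajectory(schedule, pause_params):
    return tw.simulate_two_rate(pause_params, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
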