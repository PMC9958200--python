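import numpy as np
import pytest

import hillmuscle as hm


@pytest.fixture(scope="session")
def params():
    """Control (young plantar-flexor) parameter set."""
    return hm.MuscleParams()


@pytest.fixture(scope="session")
def twitch_record_10(params):
    """Control twitch simulated from an initial CE length of 1.0 L0."""
    return hm.simulate_fixed_end(params, hm.twitch(params), initial_l_ce=1.0)


@pytest.fixture(scope="session")
def twitch_record_123(params):
    """Control twitch simulated from an initial CE length of 1.23 L0."""
    return hm.simulate_fixed_end(params, hm.twitch(params), initial_l_ce=1.23)


@pytest.fixture(scope="session")
def control_metrics_123(twitch_record_123):
    return hm.twitch_metrics(twitch_record_123)


@pytest.fixture(scope="session")
def control_metrics_10(twitch_record_10):
    return hm.twitch_metrics(twitch_record_10)


def pct_change(new, old):
    return 100.0 * (new - old) / old
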