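import numpy as np
import pytest
from hypothesis import settings

import icuflow as f

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_log():
    """Two-year synthetic admission log at the default study conditions."""
    return f.generate_log(f.SyntheticSpec())


@pytest.fixture(scope="session")
def models(default_log):
    """Arrival and LOS models calibrated on the default synthetic log."""
    arrival = f.fit_arrival_model(default_log)
    los = f.fit_los_model(default_log)
    return arrival, los


@pytest.fixture
def rng():
    return np.random.default_rng(20240605)
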