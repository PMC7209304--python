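import pytest

import heartbrain as hb
from heartbrain.signal_io import session_windows


#: Reduced problem size used throughout the suite: 256 Hz keeps every filter
#: corner (including the 100-Hz low-pass) below Nyquist while quartering the
#: sample count of the full 512-Hz acquisition rate.
TEST_RATE = 256.0


@pytest.fixture(scope="session")
def small_windows():
    """Quarter-duration session windows (B/H1 900 s, D1 2700 s, D2 900 s)."""
    return session_windows(0.25)


@pytest.fixture(scope="session")
def tiny_windows():
    """Very short windows for cheap structural tests (60-s epochs still fit)."""
    return session_windows(0.05)


@pytest.fixture(scope="session")
def experimental_preset():
    return hb.make_preset("experimental")


@pytest.fixture(scope="session")
def control_preset():
    return hb.make_preset("control")
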