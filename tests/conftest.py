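import pytest

from rbcgas import hb_kinetics as hk


@pytest.fixture(scope="session")
def plain_scheme():
    """Cooperativity-free scheme: first-step = ensemble = 20 s^-1."""
    return hk.build_scheme(20.0, 20.0)


@pytest.fixture(scope="session")
def coop_scheme():
    """Cooperative scheme under the 23 C experiment conditions."""
    return hk.scheme_for_kd(25.0, solubility=1.6)


@pytest.fixture(scope="session")
def fast_scheme():
    """Near-instant reaction (ensemble 1000 s^-1): diffusion-limited regime."""
    return hk.build_scheme(300.0, 1000.0, solubility=1.6)
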