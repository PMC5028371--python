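import pytest

from peepsim import make_default_config, simulate


@pytest.fixture(scope="session")
def two_lung_config():
    return make_default_config(2, "normal")


@pytest.fixture(scope="session")
def steady_zeep_run(two_lung_config):
    """15 breaths at ZEEP (periodic steady state reached well before the end)."""
    return simulate(two_lung_config, [(0.0, 15)])


@pytest.fixture(scope="session")
def step_run_0_8_0(two_lung_config):
    """The canonical 0-8.4-0 paired PEEP step on the two-lung normal arm."""
    return simulate(two_lung_config, [(0.0, 25), (8.4, 25), (0.0, 25)])
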