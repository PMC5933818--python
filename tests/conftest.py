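import pytest

from switchdyn import fixtures


@pytest.fixture
def toggle():
    return fixtures.toggle_switch()


@pytest.fixture
def start():
    return fixtures.start_network()


@pytest.fixture
def template():
    return fixtures.e2f_rb_template()


@pytest.fixture
def top3():
    """Top-ranked 3-node restriction-point subnetwork."""
    return fixtures.e2f_rb_top()


@pytest.fixture
def fifth3():
    """Fifth-ranked 3-node restriction-point subnetwork."""
    return fixtures.e2f_rb_fifth()
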