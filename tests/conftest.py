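import pytest

from ebopipe import simulate


@pytest.fixture(scope="session")
def panel():
    """The full synthetic marker panel (A-F core plus the G accessory)."""
    return simulate.default_panel()


@pytest.fixture(scope="session")
def panel_af(panel):
    """The six-family core panel without the G accessory variant."""
    return [f for f in panel if f.code != "G"]
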