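import pytest

from hemecat import ElectrochemConstants


@pytest.fixture(scope="session")
def constants() -> ElectrochemConstants:
    """Default cell parameters: 0.096 cm^2 disc in air-saturated buffer."""
    return ElectrochemConstants()
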