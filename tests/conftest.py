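import pytest

from hipplane import DeviceSetup, StandardModel


@pytest.fixture(scope="session")
def device() -> DeviceSetup:
    """Standard device: 1150 mm source-detector distance, 12.5 mm marker radius."""
    return DeviceSetup(1150.0, 12.5)


@pytest.fixture(scope="session")
def standard_model() -> StandardModel:
    return StandardModel()
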