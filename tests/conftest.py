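import pytest

from apneasim.runio import load_reference_fixture
from apneasim.synth import BreathingProtocol, NoiseModel, SensorModel


@pytest.fixture(scope="session")
def reference_tallies():
    return load_reference_fixture()


@pytest.fixture
def sensor():
    # 1 kHz keeps test simulations fast; well above the 10 Hz damping band
    return SensorModel(sample_rate_hz=1000.0)


@pytest.fixture
def quiet_noise():
    return NoiseModel(strike_rate_hz=0.0)


@pytest.fixture
def short_protocol():
    return BreathingProtocol(amplitude_um=1000.0, rate_bpm=40.0, n_breaths=10)
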