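import numpy as np
import pytest

from mdrgait import GaitProfile, IQSignal, RadarConfig


@pytest.fixture
def radar() -> RadarConfig:
    return RadarConfig()


@pytest.fixture
def quiet_radar() -> RadarConfig:
    """Noise-free radar settings for deterministic spectral checks."""
    return RadarConfig(noise_power=0.0)


@pytest.fixture
def walk_profile() -> GaitProfile:
    return GaitProfile(
        label="faller",
        body_speed=1.0,
        cadence=105.0,
        swing_peak_ratio=2.5,
        torso_oscillation_amplitude=0.1,
        stride_variability=0.0,
    )


def make_tone(freq_hz: float, fs: float = 600.0, duration: float = 4.0, amp: float = 1.0) -> IQSignal:
    """Complex exponential test tone."""
    t = np.arange(int(round(duration * fs))) / fs
    return IQSignal(samples=amp * np.exp(2j * np.pi * freq_hz * t), sampling_frequency=fs)


@pytest.fixture
def tone_factory():
    return make_tone
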