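"""Radar configuration and reference calibration statistics.

The module-level constants collect the measurement settings of the target
24 GHz continuous-wave sensor (carrier, sampling rate) and the per-group
gait-parameter statistics used to calibrate the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SPEED_OF_LIGHT",
    "FALLER",
    "NON_FALLER",
    "GROUPS",
    "REFERENCE_GROUP_STATS",
    "RadarConfig",
]

#: Propagation speed used for Doppler-to-velocity conversion (m/s).
SPEED_OF_LIGHT = 2.998e8

FALLER = "faller"
NON_FALLER = "non-faller"
GROUPS = (FALLER, NON_FALLER)

#: Per-group (mean, SD) of the four gait parameters, in m/s, measured on the
#: reference elderly cohorts (14 fallers / 19 non-fallers).  These numbers are
#: the calibration targets of :mod:`mdrgait.simulate`: a large synthetic
#: cohort pushed through the full pipeline should recover the group means.
REFERENCE_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    FALLER: {
        "v_m_mean": (0.787, 0.281),
        "v_u_mean": (1.66, 0.578),
        "v_u_std": (0.605, 0.170),
        "v_l_std": (0.144, 0.0817),
    },
    NON_FALLER: {
        "v_m_mean": (0.982, 0.293),
        "v_u_mean": (2.19, 0.581),
        "v_u_std": (0.647, 0.178),
        "v_l_std": (0.210, 0.0854),
    },
}


@dataclass(frozen=True)
class RadarConfig:
    """Continuous-wave radar measurement settings.

    Parameters
    ----------
    carrier_frequency : float
        Transmit carrier frequency in Hz (default 24 GHz).
    sampling_frequency : float
        Complex-baseband sampling rate of the demodulated signal in Hz.
    wave_speed : float
        Propagation speed in m/s.
    noise_power : float
        Power of the circular complex Gaussian receiver noise, relative to a
        unit-amplitude scatterer.
    duration : float
        Record length in seconds.
    initial_range : float
        Subject-to-radar distance at t = 0 in metres.  Must exceed the total
        distance walked during ``duration``.
    """

    carrier_frequency: float = 24e9
    sampling_frequency: float = 600.0
    wave_speed: float = SPEED_OF_LIGHT
    noise_power: float = 0.01
    duration: float = 6.0
    initial_range: float = 14.0

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise ValueError("carrier_frequency must be positive")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")
        if self.wave_speed <= 0:
            raise ValueError("wave_speed must be positive")
        if self.noise_power < 0:
            raise ValueError("noise_power must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.initial_range <= 0:
            raise ValueError("initial_range must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_frequency))

    def with_(self, **kwargs) -> "RadarConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
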