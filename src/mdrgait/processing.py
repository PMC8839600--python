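"""High-pass filtering, STFT spectrograms, and Doppler/velocity conversion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hamming

from .config import SPEED_OF_LIGHT, RadarConfig
from .iq import IQSignal

__all__ = ["Spectrogram", "doppler_to_velocity", "highpass_filter", "stft_spectrogram"]


def doppler_to_velocity(f_d, f_0: float, wave_speed: float = SPEED_OF_LIGHT):
    """Convert Doppler frequency (Hz) to radial velocity (m/s): v = c*f_d/(2*f_0)."""
    if f_0 <= 0:
        raise ValueError("carrier frequency f_0 must be positive")
    return wave_speed * np.asarray(f_d, dtype=float) / (2.0 * f_0)


def highpass_filter(signal: IQSignal, cutoff: float = 20.0, order: int = 4) -> IQSignal:
    """Zero-phase Butterworth high-pass removing static-clutter (near-DC) echoes.

    The filter is applied forward-backward, so the effective power gain is the
    squared magnitude response of the underlying Butterworth design.
    """
    fs = signal.sampling_frequency
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, {fs / 2}) Hz, got {cutoff}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    if len(signal) <= 3 * max(len(sos) * 6, order):
        raise ValueError("signal too short for zero-phase filtering")
    filtered = sosfiltfilt(sos, signal.samples)
    return signal.with_samples(filtered)


@dataclass
class Spectrogram:
    """Time x Doppler-frequency power map with an attached velocity axis.

    ``power`` has shape (n_frames, n_bins) in linear units; the frequency axis
    is strictly increasing.  Under the default ``positive`` convention the
    bins span [0, f_s), i.e. velocities 0..3.75 m/s at 600 Hz / 24 GHz — the
    subject approaches the sensor, so all physical Doppler content is
    positive and the full sampling bandwidth is unambiguous.
    """

    power: np.ndarray
    frame_times: np.ndarray
    doppler_frequencies: np.ndarray
    doppler_velocities: np.ndarray
    window_descriptor: dict = field(
        default_factory=lambda: {"shape": "hamming", "length": 128, "overlap": 127}
    )
    carrier_frequency: float = 24e9

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.doppler_frequencies = np.asarray(self.doppler_frequencies, dtype=float)
        self.doppler_velocities = np.asarray(self.doppler_velocities, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("power must be 2-D (frames x bins)")
        if self.power.shape != (len(self.frame_times), len(self.doppler_frequencies)):
            raise ValueError("axis lengths inconsistent with power shape")
        if len(self.doppler_velocities) != len(self.doppler_frequencies):
            raise ValueError("velocity and frequency axes must share length")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.doppler_velocities) <= 0):
            raise ValueError("velocity axis must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]


def stft_spectrogram(
    signal: IQSignal,
    window_length: int = 128,
    overlap: int = 127,
    carrier_frequency: float = 24e9,
    wave_speed: float = SPEED_OF_LIGHT,
    frequency_convention: str = "positive",
) -> Spectrogram:
    """Hamming-window STFT power spectrogram of a complex baseband record.

    Frames are taken every ``window_length - overlap`` samples (default hop:
    one sample); only full windows produce frames.  The FFT length equals the
    window length and frame timestamps are window centres.

    ``frequency_convention`` selects the bin ordering: ``"positive"`` maps
    bins onto [0, f_s) and ``"two_sided"`` onto [-f_s/2, f_s/2).
    """
    if not 0 <= overlap < window_length:
        raise ValueError("require 0 <= overlap < window_length")
    if window_length > len(signal):
        raise ValueError(
            f"signal length {len(signal)} shorter than window {window_length}"
        )
    if frequency_convention not in ("positive", "two_sided"):
        raise ValueError("frequency_convention must be 'positive' or 'two_sided'")
    fs = signal.sampling_frequency
    hop = window_length - overlap

    frames = sliding_window_view(signal.samples, window_length)[::hop]
    window = hamming(window_length, sym=False)
    spectra = np.fft.fft(frames * window, axis=1)

    freqs = np.fft.fftfreq(window_length, d=1.0 / fs)
    if frequency_convention == "positive":
        freqs = np.mod(freqs, fs)
    order = np.argsort(freqs)
    freqs = freqs[order]

    power = np.abs(spectra[:, order]) ** 2
    starts = np.arange(frames.shape[0]) * hop
    frame_times = (starts + (window_length - 1) / 2.0) / fs
    velocities = doppler_to_velocity(freqs, carrier_frequency, wave_speed)
    return Spectrogram(
        power=power,
        frame_times=frame_times,
        doppler_frequencies=freqs,
        doppler_velocities=velocities,
        window_descriptor={
            "shape": "hamming",
            "length": window_length,
            "overlap": overlap,
        },
        carrier_frequency=carrier_frequency,
    )
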