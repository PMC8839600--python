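"""Complex-baseband I/Q time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["IQSignal"]


@dataclass
class IQSignal:
    """A demodulated continuous-wave radar record.

    ``samples`` holds the complex baseband signal; its instantaneous
    frequency content is the set of Doppler shifts of the illuminated
    scatterers.
    """

    samples: np.ndarray
    sampling_frequency: float
    subject_id: str = ""
    label: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_frequency

    def time_grid(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_frequency

    def with_samples(self, samples: np.ndarray) -> "IQSignal":
        return replace(self, samples=samples)
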