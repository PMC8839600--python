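"""Upper / lower / power-weighted-mean velocity envelopes of a spectrogram.

Per frame, bins at or above a frame-relative power threshold (default
-20 dB below the frame maximum) and at or above a minimum velocity floor
are "significant".  The upper envelope is the largest significant velocity
(leg-forward motion), the lower envelope the smallest (legs near floor
contact), and the mean envelope the power-weighted mean velocity (bulk
body motion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .processing import Spectrogram

__all__ = ["EnvelopeSet", "extract_envelopes"]


@dataclass
class EnvelopeSet:
    """The three velocity envelopes on the spectrogram's frame-time grid."""

    frame_times: np.ndarray
    v_u: np.ndarray
    v_l: np.ndarray
    v_m: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.v_u = np.asarray(self.v_u, dtype=float)
        self.v_l = np.asarray(self.v_l, dtype=float)
        self.v_m = np.asarray(self.v_m, dtype=float)
        n = len(self.frame_times)
        if not (len(self.v_u) == len(self.v_l) == len(self.v_m) == n):
            raise ValueError("all envelopes must share the frame-time grid")
        if np.any(self.v_l > self.v_m + 1e-12) or np.any(self.v_m > self.v_u + 1e-12):
            raise ValueError("envelope ordering v_l <= v_m <= v_u violated")

    def __len__(self) -> int:
        return len(self.frame_times)

    def sliced(self, mask: np.ndarray) -> "EnvelopeSet":
        return EnvelopeSet(
            frame_times=self.frame_times[mask],
            v_u=self.v_u[mask],
            v_l=self.v_l[mask],
            v_m=self.v_m[mask],
        )


def extract_envelopes(
    spec: Spectrogram,
    threshold_db: float = -20.0,
    min_velocity: float = 0.125,
) -> EnvelopeSet:
    """Extract the three envelopes from a spectrogram.

    Bins below ``min_velocity`` (default the velocity matching the 20 Hz
    high-pass cutoff) are ignored so the lower envelope is not pinned to the
    filter edge.  Frames whose restricted power is identically zero are
    flagged as gaps and linearly interpolated from their neighbours;
    leading/trailing gaps are dropped.
    """
    if spec.power.size == 0:
        raise ValueError("empty spectrogram")
    if threshold_db >= 0:
        raise ValueError("threshold_db must be negative")

    vmask = spec.doppler_velocities >= min_velocity
    if not np.any(vmask):
        raise ValueError("no spectrogram bins above min_velocity")
    v = spec.doppler_velocities[vmask]
    P = spec.power[:, vmask]

    frame_max = P.max(axis=1)
    gap = frame_max <= 0.0
    if np.all(gap):
        raise ValueError("no frame contains power above the velocity floor")

    thr = frame_max * 10.0 ** (threshold_db / 10.0)
    significant = P >= thr[:, None]
    significant[gap, :] = False

    v_u = np.where(significant, v[None, :], -np.inf).max(axis=1)
    v_l = np.where(significant, v[None, :], np.inf).min(axis=1)
    weights = np.where(significant, P, 0.0)
    wsum = weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_m = (weights * v[None, :]).sum(axis=1) / wsum

    valid = ~gap
    idx = np.flatnonzero(valid)
    first, last = idx[0], idx[-1]
    sl = slice(first, last + 1)
    t = spec.frame_times[sl]
    inner_valid = valid[sl]
    if not np.all(inner_valid):
        t_valid = t[inner_valid]
        v_u = np.interp(t, t_valid, v_u[sl][inner_valid])
        v_l = np.interp(t, t_valid, v_l[sl][inner_valid])
        v_m = np.interp(t, t_valid, v_m[sl][inner_valid])
    else:
        v_u, v_l, v_m = v_u[sl], v_l[sl], v_m[sl]

    return EnvelopeSet(frame_times=t, v_u=v_u, v_l=v_l, v_m=v_m)
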