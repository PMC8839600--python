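"""Fall-risk gait parameters computed from velocity envelopes.

Four scalars summarize a walk: the time means of the mean and upper
envelopes (body speed and leg-forward speed) and the time standard
deviations of the upper and lower envelopes (variation of leg speeds in
swing and stance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .envelopes import EnvelopeSet

__all__ = [
    "GaitParameters",
    "FEATURE_COLUMNS",
    "steady_state_window",
    "compute_parameters",
    "welch_t_test",
]

FEATURE_COLUMNS = ["v_m_mean", "v_u_mean", "v_u_std", "v_l_std"]


@dataclass
class GaitParameters:
    """The four per-subject gait scalars (m/s)."""

    v_m_mean: float
    v_u_mean: float
    v_u_std: float
    v_l_std: float
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        vals = (self.v_m_mean, self.v_u_mean, self.v_u_std, self.v_l_std)
        if not all(np.isfinite(vals)):
            raise ValueError("gait parameters must be finite")
        if self.v_u_std < 0 or self.v_l_std < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.v_u_mean < self.v_m_mean:
            warnings.warn(
                "v_u_mean < v_m_mean: envelope statistics look physically "
                "implausible for walking gait",
                stacklevel=2,
            )

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "label": self.label,
            "v_m_mean": self.v_m_mean,
            "v_u_mean": self.v_u_mean,
            "v_u_std": self.v_u_std,
            "v_l_std": self.v_l_std,
        }


def steady_state_window(env: EnvelopeSet, trim_seconds: float = 1.0) -> EnvelopeSet:
    """Trim ``trim_seconds`` from each end of the record.

    Discards the acceleration/deceleration transients at the start and end of
    the walk so that statistics describe steady-state gait.
    """
    if trim_seconds < 0:
        raise ValueError("trim_seconds must be non-negative")
    if trim_seconds == 0:
        return env
    t = env.frame_times
    span = t[-1] - t[0]
    if span <= 2 * trim_seconds:
        raise ValueError(
            f"record spans {span:.3f} s; need more than {2 * trim_seconds} s "
            "to trim both ends"
        )
    mask = (t >= t[0] + trim_seconds) & (t <= t[-1] - trim_seconds)
    return env.sliced(mask)


def compute_parameters(
    env: EnvelopeSet, subject_id: str = "", label: str | None = None
) -> GaitParameters:
    """Means and sample (n-1) standard deviations of the envelope series."""
    if len(env) < 2:
        raise ValueError("need at least 2 frames to compute standard deviations")
    return GaitParameters(
        v_m_mean=float(np.mean(env.v_m)),
        v_u_mean=float(np.mean(env.v_u)),
        v_u_std=float(np.std(env.v_u, ddof=1)),
        v_l_std=float(np.std(env.v_l, ddof=1)),
        subject_id=subject_id,
        label=label,
    )


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance; t statistic undefined")
    res = _stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
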