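"""Plain-text file formats: I/Q CSV + JSON sidecar, manifests, tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .envelopes import EnvelopeSet
from .iq import IQSignal

__all__ = [
    "write_signal",
    "read_signal",
    "write_manifest",
    "read_manifest",
    "write_envelopes",
    "read_envelopes",
    "write_feature_table",
    "read_feature_table",
]

_FLOAT_FMT = "%.12g"


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_signal(signal: IQSignal, csv_path: str | Path, carrier_frequency: float = 24e9) -> Path:
    """Write a signal as a ``t,i,q`` CSV with a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "t": signal.time_grid(),
            "i": signal.samples.real,
            "q": signal.samples.imag,
        }
    )
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "subject_id": signal.subject_id,
        "label": signal.label,
        "f0_hz": carrier_frequency,
        "fs_hz": signal.sampling_frequency,
        "seed": signal.seed,
    }
    _sidecar_path(csv_path).write_text(json.dumps(meta, sort_keys=True, indent=2))
    return csv_path


def read_signal(csv_path: str | Path) -> tuple[IQSignal, dict]:
    """Read a ``t,i,q`` CSV and its sidecar; returns (signal, metadata)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("t", "i", "q"):
        if col not in df.columns:
            raise ValueError(f"signal CSV missing column {col!r}")
    sidecar = _sidecar_path(csv_path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if "fs_hz" in meta:
        fs = float(meta["fs_hz"])
    else:
        dt = np.diff(df["t"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    signal = IQSignal(
        samples=df["i"].to_numpy() + 1j * df["q"].to_numpy(),
        sampling_frequency=fs,
        subject_id=str(meta.get("subject_id", csv_path.stem)),
        label=meta.get("label"),
        seed=meta.get("seed"),
    )
    return signal, meta


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=["subject_id", "label", "path"]).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_envelopes(env: EnvelopeSet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"t": env.frame_times, "v_u": env.v_u, "v_l": env.v_l, "v_m": env.v_m}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_envelopes(path: str | Path) -> EnvelopeSet:
    df = pd.read_csv(path)
    return EnvelopeSet(
        frame_times=df["t"].to_numpy(),
        v_u=df["v_u"].to_numpy(),
        v_l=df["v_l"].to_numpy(),
        v_m=df["v_m"].to_numpy(),
    )


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
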