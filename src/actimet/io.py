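"""Plain-text I/O: raw-recording CSV, cohort CSV and YAML study configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accelerometry import RawRecording, RecordingError

RAW_COLUMNS = ["time_s", "x_g", "y_g", "z_g"]


def write_raw_csv(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as ``time_s,x_g,y_g,z_g`` (one row per sample)."""
    df = pd.DataFrame(rec.xyz.astype(np.float64), columns=RAW_COLUMNS[1:])
    df.insert(0, "time_s", rec.times())
    df.to_csv(path, index=False, float_format="%.6f")


def read_raw_csv(
    path: str | Path,
    sampling_rate_hz: float | None = None,
    start_weekday: int = 0,
    participant_id: str | None = None,
) -> RawRecording:
    """Read a ``time_s,x_g,y_g,z_g`` table; infer the rate when not given."""
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingError(f"raw CSV {path} lacks columns {missing}")
    t = df["time_s"].to_numpy(dtype=np.float64)
    if len(t) < 2:
        raise RecordingError("raw CSV must contain at least two samples")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise RecordingError("timestamps must be strictly increasing")
    if sampling_rate_hz is None:
        sampling_rate_hz = 1.0 / float(np.median(dt))
    xyz = df[RAW_COLUMNS[1:]].to_numpy(dtype=np.float32)
    return RawRecording(xyz, sampling_rate_hz, float(t[0]), start_weekday,
                        participant_id)


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data
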