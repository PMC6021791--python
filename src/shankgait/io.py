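"""Readers and writers for the pipeline's file formats.

Gyro recordings travel as UTF-8 CSV with a required header
``time_s,gyro_x_dps,gyro_y_dps,gyro_z_dps`` (columns matched by name,
decimal point, strictly increasing time).  Ground truth rides in a
JSON sidecar; events, parameters and cohort tables are tidy CSVs;
statistical reports and model summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GyroRecording

__all__ = ["read_gyro_csv", "write_gyro_csv", "GyroCsvError"]

GYRO_COLUMNS = ("time_s", "gyro_x_dps", "gyro_y_dps", "gyro_z_dps")
#: Decimal places written: lossless round-trip at 1e-6 deg/s.
PRECISION = 6


class GyroCsvError(ValueError):
    """A gyro CSV violated the dialect; the message names the defect."""


def write_gyro_csv(recording: GyroRecording, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": recording.t,
            "gyro_x_dps": recording.omega_x,
            "gyro_y_dps": recording.omega_y,
            "gyro_z_dps": recording.omega_z,
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{PRECISION}f")


def read_gyro_csv(path, subject_id: str | None = None, side: str = "right") -> GyroRecording:
    """Parse a gyro CSV into a :class:`GyroRecording`.

    Columns are matched by header name, so column order is free.
    Raises :class:`GyroCsvError` with a distinct diagnostic for a
    missing column, a non-numeric cell or a time regression (naming
    the offending data row).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise GyroCsvError(f"{path.name}: cannot parse CSV ({exc})") from exc
    missing = [c for c in GYRO_COLUMNS if c not in df.columns]
    if missing:
        raise GyroCsvError(f"{path.name}: missing column(s) {', '.join(missing)}")
    for c in GYRO_COLUMNS:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index[0]
            raise GyroCsvError(
                f"{path.name}: non-numeric value in column {c!r} at data row {bad + 1}"
            ) from None
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise GyroCsvError(f"{path.name}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2  # 1-based data row of the regression
        raise GyroCsvError(
            f"{path.name}: time not strictly increasing at data row {row}"
        )
    fs = 1.0 / float(np.median(dt))
    return GyroRecording(
        subject_id=subject_id or path.stem,
        side=side,
        fs=fs,
        t=t,
        omega_x=df["gyro_x_dps"].to_numpy(dtype=float),
        omega_y=df["gyro_y_dps"].to_numpy(dtype=float),
        omega_z=df["gyro_z_dps"].to_numpy(dtype=float),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
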