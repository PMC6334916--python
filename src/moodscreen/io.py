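"""File round-tripping: raw IMU CSV, event JSON, feature tables, XLSX.

The feature-table CSV is the interchange hub between the signal half
and the statistics half of the pipeline: one row per subject × phase
with the 174 named feature columns and the binary diagnosis, so a
deposited subject-level feature table can substitute for raw
recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import ImuRecording

IMU_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps")


class IoError(ValueError):
    pass


# ---------------------------------------------------------------------------
# raw IMU CSV + event JSON
# ---------------------------------------------------------------------------

def read_imu_csv(path, sample_rate_hz: float | None = None,
                 accel_units: str = "g") -> ImuRecording:
    """Read a delimited IMU recording (header required, columns
    time_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps).  If the nominal
    rate is not given it is estimated from the median timestep."""
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise IoError(f"{path}: missing IMU columns {missing}")
    t = df["time_s"].to_numpy(float)
    if sample_rate_hz is None:
        if len(t) < 2:
            raise IoError(f"{path}: cannot infer sample rate from <2 samples")
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return ImuRecording(
        time=t,
        accel=df[["ax_g", "ay_g", "az_g"]].to_numpy(float),
        gyro=df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(float),
        sample_rate_hz=sample_rate_hz,
        accel_units=accel_units,
    )


def write_imu_csv(path, rec: ImuRecording) -> None:
    acc = rec.accel_g()
    df = pd.DataFrame({
        "time_s": rec.time,
        "ax_g": acc[:, 0], "ay_g": acc[:, 1], "az_g": acc[:, 2],
        "gx_dps": rec.gyro[:, 0], "gy_dps": rec.gyro[:, 1],
        "gz_dps": rec.gyro[:, 2],
    })
    df.to_csv(path, index=False)


def read_event_json(path) -> float:
    with open(path) as fh:
        data = json.load(fh)
    if "startle_time_s" not in data:
        raise IoError(f"{path}: missing 'startle_time_s'")
    return float(data["startle_time_s"])


def write_event_json(path, startle_time_s: float) -> None:
    with open(path, "w") as fh:
        json.dump({"startle_time_s": startle_time_s}, fh)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_csv(path, tables: dict[str, pd.DataFrame],
                      labels: pd.Series) -> None:
    """Long-format CSV: subject_id, phase, 174 feature columns, diagnosis."""
    frames = []
    for phase, X in tables.items():
        df = X.copy()
        df.insert(0, "phase", phase)
        df.insert(0, "subject_id", X.index)
        df["diagnosis"] = labels.reindex(X.index).to_numpy()
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_feature_csv(path, phase: str | None = None
                     ) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Inverse of :func:`write_feature_csv`; optionally restricted to
    one phase.  Returns (tables, labels)."""
    df = pd.read_csv(path)
    for col in ("subject_id", "phase", "diagnosis"):
        if col not in df.columns:
            raise IoError(f"{path}: missing column {col!r}")
    feat_cols = [c for c in df.columns
                 if c not in ("subject_id", "phase", "diagnosis")]
    phases = [phase] if phase is not None else sorted(df["phase"].unique())
    tables: dict[str, pd.DataFrame] = {}
    labels: pd.Series | None = None
    for ph in phases:
        sub = df[df["phase"] == ph]
        if sub.empty:
            raise IoError(f"{path}: no rows for phase {ph!r}")
        X = sub.set_index("subject_id")[feat_cols]
        tables[ph] = X
        y = sub.set_index("subject_id")["diagnosis"].astype(int)
        if labels is None:
            labels = y
        elif not labels.reindex(y.index).equals(y):
            raise IoError(f"{path}: inconsistent diagnosis labels across phases")
    assert labels is not None
    return tables, labels


# ---------------------------------------------------------------------------
# subject-level XLSX reader (deposited supplementary layout)
# ---------------------------------------------------------------------------

def read_subject_xlsx(
    path,
    sheet: str | int = 0,
    column_map: dict[str, str] | None = None,
    diagnosis_column: str = "diagnosis",
    subject_column: str | None = None,
) -> pd.DataFrame:
    """Read a subject-level XLSX table (features, CBCL scales and the
    diagnosis label).  ``column_map`` renames source columns to the
    package's names; layouts vary, so the mapping lives in the run
    config rather than in code."""
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    if column_map:
        df = df.rename(columns=column_map)
    if diagnosis_column not in df.columns:
        raise IoError(
            f"{path}: no diagnosis column {diagnosis_column!r}; "
            "set a column_map in the config"
        )
    if subject_column and subject_column in df.columns:
        df = df.set_index(subject_column)
    return df


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
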