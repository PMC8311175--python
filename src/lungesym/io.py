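"""CSV interchange formats and study configuration.

Two table schemas travel between pipeline stages:

* **Sensor trace CSV** (one file per landmark): columns ``t, ax, ay, az,
  roll, pitch, yaw`` — time (s), tri-axial sensor acceleration (m/s²) and
  orientation Euler angles (degrees).  The landmark is taken from the file
  stem (``poll.csv`` etc.).
* **Condition table CSV**: one row per horse x surface x speed x direction
  with the 11 asymmetry parameters (mm), stride time (ms) and stride count;
  the normalized variant is long-form with ``parameter``/``value`` columns
  plus ``direction`` (straight/inside/outside/average), ``side_label`` and
  ``inverted``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .kinematics import LANDMARKS, SensorTrace
from .synth import DIRECTIONS, PARAMETERS, SPEEDS, SURFACES

TRACE_COLUMNS = ["t", "ax", "ay", "az", "roll", "pitch", "yaw"]
CONDITION_COLUMNS = ["horse", "surface", "speed", "direction", *PARAMETERS,
                     "stride_time", "n_strides"]
NORMALIZED_DIRECTIONS = ("straight", "inside", "outside", "average")


@dataclass
class StudyConfig:
    """Declarative configuration of a pipeline run.

    CLI flags override values loaded from a YAML file, which override the
    defaults below.
    """

    sample_rate: float = 100.0  # Hz
    min_strides: int = 15
    head_threshold: float = 6.0  # mm
    pelvis_threshold: float = 3.0  # mm
    circle_radius: float = 7.5  # m
    lean_gain: float = 0.8  # mm per degree of body lean
    slow_speed: float = 3.0  # m/s
    fast_speed: float = 4.0  # m/s
    n_horses: int = 5  # horses simulated by the signal-level demo pipeline
    stride_time: float = 0.75  # s, generator baseline
    duration: float = 24.0  # s per simulated condition
    noise_sd: float = 2.0  # mm
    reml: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.min_strides < 2:
            raise ValueError("min_strides must be at least 2")
        if self.circle_radius <= 0:
            raise ValueError("circle_radius must be positive")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "StudyConfig":
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def write_sensor_trace(trace: SensorTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t": trace.time,
            "ax": trace.acceleration[:, 0],
            "ay": trace.acceleration[:, 1],
            "az": trace.acceleration[:, 2],
            "roll": trace.orientation[:, 0],
            "pitch": trace.orientation[:, 1],
            "yaw": trace.orientation[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_sensor_trace(path: str | Path, sample_rate: float | None = None) -> SensorTrace:
    """Read one landmark's trace CSV; the landmark comes from the file stem."""
    path = Path(path)
    landmark = path.stem
    if landmark not in LANDMARKS:
        raise ValueError(
            f"cannot infer landmark from file name {path.name!r}; "
            f"expected one of {', '.join(LANDMARKS)}"
        )
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns: {', '.join(missing)}")
    if len(df) < 2:
        raise ValueError(f"{path.name}: insufficient data ({len(df)} rows)")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0) or (dt.max() - dt.min()) > 0.01 * dt.mean():
        raise ValueError(f"{path.name}: irregular sampling beyond 1% tolerance")
    fs = 1.0 / dt.mean()
    if sample_rate is not None and abs(fs - sample_rate) > 0.01 * sample_rate:
        raise ValueError(
            f"{path.name}: sampling rate {fs:.2f} Hz does not match configured "
            f"{sample_rate:.2f} Hz"
        )
    return SensorTrace(
        landmark=landmark,
        time=t,
        acceleration=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        orientation=df[["roll", "pitch", "yaw"]].to_numpy(dtype=float),
        sample_rate=fs,
        meta={"path": str(path)},
    )


def read_sensor_traces(directory: str | Path,
                       sample_rate: float | None = None) -> dict[str, SensorTrace]:
    """Read the five-landmark trace set of one assessment condition."""
    directory = Path(directory)
    traces = {}
    for lm in LANDMARKS:
        f = directory / f"{lm}.csv"
        if not f.exists():
            raise ValueError(f"missing trace file {f.name} in {directory}")
        traces[lm] = read_sensor_trace(f, sample_rate=sample_rate)
    return traces


def write_condition_table(records: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CONDITION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"condition table missing columns: {', '.join(missing)}")
    records[CONDITION_COLUMNS].to_csv(path, index=False)


def read_condition_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a wide condition table (lossless round trip)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty condition table")
    missing = [c for c in CONDITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {', '.join(missing)}")
    _validate_levels(df, "direction", DIRECTIONS)
    _validate_levels(df, "surface", SURFACES)
    _validate_levels(df, "speed", SPEEDS)
    return df


def _validate_levels(df: pd.DataFrame, column: str, allowed) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"row {i}: unknown {column} level {df[column].iloc[i]!r} "
            f"(allowed: {', '.join(allowed)})"
        )


def write_normalized_table(records: pd.DataFrame, path: str | Path) -> None:
    cols = ["horse", "surface", "speed", "rein", "direction", "parameter",
            "value", "side_label", "inverted"]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"normalized table missing columns: {', '.join(missing)}")
    records[cols].to_csv(path, index=False)


def read_normalized_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty normalized table")
    _validate_levels(df, "direction", NORMALIZED_DIRECTIONS)
    bad = ~df["parameter"].isin(PARAMETERS)
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"row {i}: unknown parameter {df['parameter'].iloc[i]!r}")
    return df


def write_truth_sidecar(truth, path: str | Path) -> None:
    """Ground-truth side-car of a simulated condition, as JSON-ish YAML."""
    payload = {
        "stride_starts_s": [float(x) for x in truth.stride_starts_s],
        "stride_durations_s": [float(x) for x in truth.stride_durations_s],
        "injected": {k: float(v) for k, v in truth.injected.items()},
        "stance_labels": "".join("L" if s == "left" else "R" for s in truth.stance_labels),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def read_truth_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["stance_labels"] = np.array(
        ["left" if c == "L" else "right" for c in payload["stance_labels"]], dtype=object
    )
    return payload
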