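"""Trace CSV and truth-sidecar I/O.

CSV files store rig-native units for human inspection — seconds, N·m,
degrees, millimetres, header exactly ``time_s,torque_Nm,rotation_deg,
position_mm`` — and are converted to internal units (N·mm, rad) in exactly
one place: here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .signal import TorqueTrace
from .simulate import GroundTruth

__all__ = ["TRACE_COLUMNS", "read_trace_csv", "write_trace_csv",
           "write_truth_json", "read_truth_json"]

TRACE_COLUMNS = ["time_s", "torque_Nm", "rotation_deg", "position_mm"]


def read_trace_csv(path: str | Path) -> TorqueTrace:
    """Read a trace CSV and convert to internal units.

    Validates the exact header, numeric rows, strictly increasing time and a
    uniform grid (1 ppm); the sample rate is recorded from the grid.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ConfigError(f"{path}: cannot parse CSV ({exc})") from exc
    if list(df.columns) != TRACE_COLUMNS:
        raise ConfigError(
            f"{path}: header must be exactly {','.join(TRACE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}")
    for col in TRACE_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
            raise ConfigError(f"{path}: non-numeric value in {col} "
                              f"(data row {bad + 1})")
        if df[col].isna().any():
            bad = int(df[col].isna().idxmax())
            raise ConfigError(f"{path}: missing value in {col} "
                              f"(data row {bad + 1})")
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) < 2:
        raise ConfigError(f"{path}: need at least 2 rows")
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise ConfigError(f"{path}: time not strictly increasing "
                          f"(data row {bad + 2})")
    mean_dt = float(dt.mean())
    dev = np.abs(dt - mean_dt)
    if dev.max() > 1e-6 * mean_dt:
        bad = int(np.argmax(dev))
        raise ConfigError(f"{path}: non-uniform sampling beyond 1 ppm "
                          f"(data row {bad + 2})")
    return TorqueTrace(
        time=time,
        torque=df["torque_Nm"].to_numpy(dtype=float) * 1000.0,
        rotation=np.radians(df["rotation_deg"].to_numpy(dtype=float)),
        position=df["position_mm"].to_numpy(dtype=float),
        sample_rate=1.0 / mean_dt,
    )


def write_trace_csv(trace: TorqueTrace, path: str | Path) -> None:
    """Write a trace in rig-native units with the canonical header."""
    df = pd.DataFrame({
        "time_s": trace.time,
        "torque_Nm": trace.torque / 1000.0,
        "rotation_deg": np.degrees(trace.rotation),
        "position_mm": trace.position,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """Sidecar with the generator's ground truth for one trace."""
    payload = {
        "material": truth.material,
        "sigma_ucs_true_MPa": truth.sigma_ucs_true,
        "tau_strip_true_Nmm": truth.tau_strip_true,
        "onset_time_s": truth.onset_time,
        "strip_time_s": truth.strip_time,
        "seed": truth.seed,
        "clipped": truth.clipped,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_json(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    try:
        return GroundTruth(
            material=data["material"],
            sigma_ucs_true=float(data["sigma_ucs_true_MPa"]),
            tau_strip_true=float(data["tau_strip_true_Nmm"]),
            onset_time=float(data["onset_time_s"]),
            strip_time=float(data["strip_time_s"]),
            seed=int(data["seed"]),
            clipped=bool(data.get("clipped", False)),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing truth key {exc}") from exc
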