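"""File formats: trace CSV + JSON sidecar, tables, pulse sets, configs.

Traces are stored as two-column CSV (``time_s,voltage_v``) with a JSON
sidecar carrying acquisition metadata (sampling rate, counter role, flow
rates, seed); an optional compact binary container (``.npz``) holds the
same named fields for long traces.  Tables are plain CSV.  All numeric
round-trips are lossless at full precision (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError, RawTrace
from .detection import PulseSet

__all__ = [
    "write_trace",
    "read_trace",
    "write_table",
    "read_table",
    "write_pulses",
    "read_config",
    "write_json_report",
]

TRACE_COLUMNS = ["time_s", "voltage_v"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: RawTrace, path: str | Path, binary: bool = False) -> Path:
    """Write a trace and its JSON sidecar; returns the data path."""
    path = Path(path)
    sidecar = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "counter_role": trace.counter_role,
        "metadata": _jsonable(trace.metadata),
    }
    if binary:
        np.savez_compressed(path, voltage_v=trace.samples)
    else:
        pd.DataFrame(
            {"time_s": trace.times, "voltage_v": trace.samples}
        ).to_csv(path, index=False, float_format="%.17g")
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace(path: str | Path) -> RawTrace:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ConfigurationError(f"missing trace sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    fs = sidecar.get("sampling_rate_hz")
    if not isinstance(fs, (int, float)) or fs <= 0:
        raise ConfigurationError("sidecar sampling_rate_hz must be a positive number")

    if path.suffix == ".npz":
        samples = np.load(path)["voltage_v"]
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"trace CSV missing columns: {missing}")
        samples = frame["voltage_v"].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ConfigurationError("trace file contains non-finite voltages")
    return RawTrace(
        samples=samples,
        sampling_rate_hz=float(fs),
        counter_role=sidecar.get("counter_role", "entrance"),
        metadata=sidecar.get("metadata", {}),
    )


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path, required_columns=None) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    if required_columns:
        missing = [c for c in required_columns if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"table {path} missing columns: {missing}")
    return frame


def write_pulses(pulses: PulseSet, path: str | Path) -> Path:
    """Pulse table CSV plus a JSON sidecar with the detection context."""
    path = Path(path)
    pulses.to_frame().to_csv(path, index=False, float_format="%.17g")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "threshold_v": pulses.threshold_v,
                "baseline_sd_v": pulses.baseline_sd_v,
                "source": _jsonable(pulses.source),
            },
            indent=1,
        )
    )
    return path


def read_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must contain a mapping")
    return data


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
    return path
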