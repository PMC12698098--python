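"""File I/O: pulse traces (CSV), pulse series (HDF5 or CSV directory), configs.

CSV is the inspectable interchange default; HDF5 holds full-rate series.
All columns carry unit-bearing names.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import pydantic
import yaml

from .errors import ConfigurationError, EmptyInputError, GridMismatchError
from .fitting import FitConfig
from .ridge_stack import StackConfig
from .signal import PulseSeries, PulseTrace
from .synthetic_data import OcclusionScenario

__all__ = [
    "RunConfig",
    "read_pulse_trace",
    "write_pulse_trace",
    "read_pulse_series",
    "write_pulse_series",
    "load_run_config",
]


class RunConfig(pydantic.BaseModel):
    """Top-level configuration: stack, fit and scenario sections plus run options."""

    model_config = pydantic.ConfigDict(extra="forbid")

    stack: StackConfig = pydantic.Field(default_factory=StackConfig)
    fit: FitConfig = pydantic.Field(default_factory=FitConfig)
    scenario: OcclusionScenario = pydantic.Field(default_factory=OcclusionScenario)
    seed: int = 0
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    """Load a JSON or YAML run configuration (YAML is a JSON superset here)."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    try:
        return RunConfig(**data)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def write_pulse_trace(trace: PulseTrace, path) -> None:
    pd.DataFrame({"time_ps": trace.times_ps, "amplitude_mV": trace.amplitude_mv}).to_csv(
        path, index=False
    )


def read_pulse_trace(path) -> PulseTrace:
    df = pd.read_csv(path)
    for col in ("time_ps", "amplitude_mV"):
        if col not in df.columns:
            raise EmptyInputError(f"{path}: missing column {col!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: no samples")
    return PulseTrace(df["time_ps"].to_numpy(), df["amplitude_mV"].to_numpy())


def write_pulse_series(series: PulseSeries, path) -> None:
    """Write a series as HDF5 (suffix .h5/.hdf5) or as a CSV directory."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("taus", data=series.taus_s)
            fh.create_dataset("time_ps", data=series.times_ps)
            fh.create_dataset("amplitudes", data=series.amplitudes_mv)
            fh["taus"].attrs["units"] = "s"
            fh["time_ps"].attrs["units"] = "ps"
            fh["amplitudes"].attrs["units"] = "mV"
    else:
        path.mkdir(parents=True, exist_ok=True)
        names = []
        for i in range(len(series)):
            name = f"pulse_{i:05d}.csv"
            write_pulse_trace(series.trace(i), path / name)
            names.append(name)
        pd.DataFrame({"filename": names, "tau_s": series.taus_s}).to_csv(
            path / "taus.csv", index=False
        )


def read_pulse_series(path) -> PulseSeries:
    path = Path(path)
    if path.is_file():
        with h5py.File(path, "r") as fh:
            return PulseSeries(fh["taus"][...], fh["time_ps"][...], fh["amplitudes"][...])
    index = path / "taus.csv"
    if not index.exists():
        raise EmptyInputError(f"{path}: no taus.csv index found")
    idx = pd.read_csv(index)
    if idx.empty:
        raise EmptyInputError(f"{path}: empty series index")
    times = None
    amps = []
    for name in idx["filename"]:
        trace = read_pulse_trace(path / name)
        if times is None:
            times = trace.times_ps
        elif not np.allclose(times, trace.times_ps, rtol=1e-9, atol=1e-12):
            raise GridMismatchError(f"{name}: time grid differs from the first trace")
        amps.append(trace.amplitude_mv)
    return PulseSeries(idx["tau_s"].to_numpy(), times, np.vstack(amps))


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
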