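"""Readers/writers and pipeline configuration.

Signals travel in an HDF5 container (datasets ``/samples`` float32 µV,
``/fs``, ``/t0``, ``/labels``); all tabular exchange (events, trial tables,
[ΔDA] traces, recovery tables) is CSV.  The pipeline configuration is a YAML
file with sections mirroring each stage's config dataclass; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from ecpkit.artifact_removal import ArtifactEvents, DetectorConfig, LineNoiseConfig
from ecpkit.recording import Recording
from ecpkit.spike_extraction import SpikeConfig
from ecpkit.synthdata import ArtifactSpec, NoiseModel
from ecpkit.task_alignment import EVENT_COLUMNS, TrialTable


class FormatError(ValueError):
    """Raised when a container is missing required fields."""


def write_recording(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("t0", data=float(rec.t0))
        f.create_dataset(
            "labels", data=np.asarray(rec.channel_labels, dtype=object),
            dtype=h5py.string_dtype(),
        )


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        for key in ("samples", "fs", "t0", "labels"):
            if key not in f:
                raise FormatError(f"recording container missing field {key!r}")
        samples = f["samples"][()].astype(np.float64)
        fs = float(f["fs"][()])
        t0 = float(f["t0"][()])
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]
    return Recording(samples, fs=fs, t0=t0, channel_labels=labels)


def write_artifact_events(events: list[ArtifactEvents], path: str | Path) -> None:
    rows = []
    for ev in events:
        for t, ins in zip(ev.peak_times, ev.inserted_flags):
            rows.append({"time_s": t, "inserted": bool(ins), "kind": ev.kind})
    pd.DataFrame(rows, columns=["time_s", "inserted", "kind"]).to_csv(path, index=False)


def read_artifact_events(path: str | Path) -> list[ArtifactEvents]:
    df = pd.read_csv(path)
    out = []
    for kind, grp in df.groupby("kind", sort=False):
        out.append(
            ArtifactEvents(
                grp["time_s"].to_numpy(float),
                grp["inserted"].to_numpy(bool),
                kind=str(kind),
            )
        )
    return out


def write_trials(trials: TrialTable, path: str | Path) -> None:
    trials.df.to_csv(path, index=False)


def read_trials(path: str | Path, time_offset_s: float = 0.0) -> TrialTable:
    """Read a trial table CSV; ``time_offset_s`` shifts all event times,
    supporting alignment of the FSCV and electrophysiology clocks via shared
    trial-start codes."""
    df = pd.read_csv(path)
    if df.empty and not set(EVENT_COLUMNS) <= set(df.columns):
        raise FormatError("trial CSV missing event columns")
    for col in EVENT_COLUMNS:
        if col in df.columns:
            df[col] = df[col] + time_offset_s
    return TrialTable(df)


def write_da_trace(trace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "delta_da_nM": trace.delta_da,
            "null_reason": trace.null_reason,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulateConfig:
    duration_s: float = 60.0
    n_channels: int = 5
    fs: float = 30_000.0
    spike_rate_hz: float = 5.0
    spike_amplitude_uv: float = 150.0
    artifact_kind: str = "R"
    artifact_amplitude_uv: float = 500.0


@dataclass
class PipelineConfig:
    """Full pipeline configuration with sections per stage."""

    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    clean: DetectorConfig = field(default_factory=DetectorConfig)
    line_noise: LineNoiseConfig = field(default_factory=LineNoiseConfig)
    sort: SpikeConfig = field(default_factory=SpikeConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "simulate": SimulateConfig,
        "clean": DetectorConfig,
        "line_noise": LineNoiseConfig,
        "sort": SpikeConfig,
    }
    kwargs: dict = {}
    for key, val in raw.items():
        if key in sections:
            kwargs[key] = _build(sections[key], val or {})
        elif key in ("seed", "log_level"):
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config section {key!r}")
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
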