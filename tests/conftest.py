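"""Shared fixtures: synthetic recordings and the pooled validation run.

All fixtures are deterministic (fixed seeds chosen up front); the heavier
simulations are session-scoped so several tests can share one computation.
"""

from __future__ import annotations

import collections

import numpy as np
import pytest

from ecpkit import synthdata as sd
from ecpkit.artifact_removal import DetectorConfig, clean
from ecpkit.cli import artifact_spec_for, default_standards, validation_recording
from ecpkit.validation import run_validation


@pytest.fixture(scope="session")
def noise_recording():
    """Artifact-free background noise, 5 channels, 30 s."""
    rec, _ = sd.render_recording(
        None, 5, noise=sd.NoiseModel(), duration=30.0, seed=101
    )
    return rec


@pytest.fixture(scope="session")
def spiking_recording():
    """One 5 Hz Poisson unit per channel on 4 channels, 60 s, with noise."""
    return validation_recording(duration=60.0, n_channels=4, rate_hz=5.0, seed=202)


@pytest.fixture(scope="session")
def injected_r(spiking_recording):
    """The spiking recording with default R-type scan artifacts injected."""
    spec = artifact_spec_for("R")
    injected, times = sd.inject_artifacts(spiking_recording, spec)
    return injected, times, spec


@pytest.fixture(scope="session")
def cleaned_r(injected_r):
    injected, _, _ = injected_r
    return clean(injected, DetectorConfig())


@pytest.fixture(scope="session")
def validation_tables():
    """Pooled validation: 3 synthetic sessions x 5 channels x 45 s, all three
    artifact morphologies, mirroring the published validation design."""
    per_kind = collections.defaultdict(list)
    all_results = []
    for session_seed in (11, 12, 13):
        rec = validation_recording(
            duration=45.0, n_channels=5, rate_hz=5.0, seed=session_seed
        )
        results = run_validation(
            rec,
            [artifact_spec_for(k) for k in ("R", "RC", "RAIL")],
            label=f"s{session_seed}",
        )
        all_results.extend(results)
        for r in results:
            per_kind[r.artifact_kind].append(r.recovery_pct)
    means = {k: float(np.mean(v)) for k, v in per_kind.items()}
    return all_results, means


@pytest.fixture(scope="session")
def standards_library():
    v = sd.cv_voltage_axis()
    return default_standards(v, seed=303), v
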