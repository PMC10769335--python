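"""Continuous multi-channel voltage recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Multi-channel extracellular voltage time series.

    Parameters
    ----------
    samples
        Channels x time voltage matrix in microvolts (float32 on disk).
    fs
        Sampling rate in Hz (default acquisition rate is 30 kHz).
    t0
        Time of the first sample, in seconds.
    channel_labels
        Free-form electrode site labels; the convention in the source
        recordings is ``c``/``p`` prefixes for caudate and putamen sites
        (e.g. ``c34``, ``p15``).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (t0 + i/fs)."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def time_to_index(self, t: float | np.ndarray) -> np.ndarray:
        """Nearest sample index for a time in seconds (0-based)."""
        return np.rint((np.asarray(t) - self.t0) * self.fs).astype(np.int64)

    def index_to_time(self, i: int | np.ndarray) -> np.ndarray:
        return self.t0 + np.asarray(i) / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(), self.fs, self.t0, list(self.channel_labels)
        )
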