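"""Synthetic ECP data: ground-truth spike trains, noise, scan artifacts, CV streams.

This module stands in for raw combined electrochemistry/electrophysiology
recordings.  It generates

* inhomogeneous-Poisson spike trains with MSN (sparse, bursting) or TAN
  (tonic, pausing) character,
* multi-channel voltage recordings (spike templates + white/pink/line noise),
* FSCV scan-artifact templates of three morphologies — resistive (R, a brief
  triangular pulse), resistive-capacitive (RC, same pulse with an exponential
  tail) and rail (amplifier-saturating, widest, with a recovery segment) —
  injected periodically at the 10 Hz scan rate,
* synthetic cyclic-voltammogram streams with known dopamine transients.

Every generator is deterministic given its seed; all draws flow through
``numpy.random.default_rng`` seeded per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from ecpkit.recording import Recording

DEFAULT_FS = 30_000.0  # Hz, acquisition rate of the electrophysiology system
SCAN_RATE_HZ = 10.0  # FSCV scans per second
SCAN_WIDTH_MS = 8.5  # triangular −0.4→1.3→−0.4 V sweep at 400 V/s


# ---------------------------------------------------------------------------
# domain types


@dataclass
class NoiseModel:
    """Background noise: white + 1/f ("pink") + line interference.

    Amplitudes are standard deviations (white/pink) or peak amplitude (line)
    in microvolts.  ``line_harmonics`` lists ``(harmonic_index, relative_amp)``
    pairs added on top of the fundamental; ``line_waveform`` may be ``"sine"``
    or ``"sawtooth"`` (a sawtooth carries energy above 300 Hz and is what the
    line-noise detector is designed to catch).
    """

    white_sd: float = 15.0
    pink_sd: float = 10.0
    line_amp: float = 0.0
    line_freq: float = 60.0
    line_harmonics: list[tuple[int, float]] = field(default_factory=list)
    line_waveform: str = "sine"

    def __post_init__(self) -> None:
        for name in ("white_sd", "pink_sd", "line_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for k, _ in self.line_harmonics:
            if k < 2:
                raise ValueError("harmonic indices must be >= 2")


@dataclass
class ArtifactSpec:
    """Shape parameters of one FSCV scan-artifact morphology.

    ``kind`` is ``"R"`` (resistive: symmetric triangular pulse spanning the
    scan), ``"RC"`` (the same pulse convolved with an exponential of time
    constant ``rc_tau``) or ``"RAIL"`` (pulse clipped at the amplifier input
    range ``clip_level`` with an exponential recovery segment of time constant
    ``recovery_tau`` appended after the scan).
    """

    kind: str = "R"
    amplitude: float = 500.0  # µV; for RAIL, pre-clip amplitude
    rc_tau: float = 2.0  # ms
    clip_level: float = 1000.0  # µV, amplifier input range is ±1 mV
    recovery_tau: float = 2.0  # ms
    recovery_ring_hz: float = 1200.0  # settle ringing of the saturated amplifier
    scan_rate_hz: float = SCAN_RATE_HZ
    scan_width_ms: float = SCAN_WIDTH_MS
    phase_s: float = 0.05  # time of the first scan

    def __post_init__(self) -> None:
        if self.kind not in ("R", "RC", "RAIL"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.scan_rate_hz <= 0:
            raise ValueError("scan_rate_hz must be positive")
        if not 0 < self.scan_width_ms < 1000.0 / self.scan_rate_hz:
            raise ValueError("scan_width_ms must fit inside one scan period")


@dataclass
class EventModulation:
    """Multiplicative rate modulation locked to a behavioural event.

    ``gain`` < 1 produces a pause, > 1 a burst; the modulation applies over
    ``[latency_s, latency_s + duration_s]`` after each event time.
    """

    event: str
    gain: float
    latency_s: float = 0.0
    duration_s: float = 0.1


@dataclass
class CellModel:
    """Firing statistics and waveform template of one striatal unit type.

    MSNs (medium spiny projection neurons) fire sparsely (< 1 Hz) with
    event-locked bursts and a narrow waveform; TANs (tonically active,
    putative cholinergic interneurons) fire tonically at 2–12 Hz with
    cue-locked pause-then-rebound responses and a broader waveform
    (longer after-hyperpolarization).
    """

    cell_type: str = "MSN"
    baseline_rate: float = 0.5  # Hz
    event_modulation: list[EventModulation] = field(default_factory=list)
    waveform_template: np.ndarray | None = None
    template_width_ms: float = 0.25  # trough-to-peak

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.waveform_template is None:
            self.waveform_template = spike_template(
                trough_to_peak_ms=self.template_width_ms
            )


@dataclass
class GroundTruth:
    """Known truth paired with a rendered recording."""

    spike_times_per_unit: list[np.ndarray] = field(default_factory=list)
    unit_channels: list[int] = field(default_factory=list)
    artifact_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    line_noise_phase: float = 0.0
    da_transients: list[tuple[float, float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# spike templates and trains


def spike_template(
    fs: float = DEFAULT_FS,
    support_ms: float = 1.6,
    trough_to_peak_ms: float = 0.25,
    trough_frac: float = 0.25,
) -> np.ndarray:
    """Biphasic, trough-dominant extracellular spike template, peak-normalised.

    The trough (negative phase) sits at ``trough_frac`` of the support; the
    after-hyperpolarization peak follows ``trough_to_peak_ms`` later with 40%
    of the trough amplitude.  Returned with unit trough amplitude (multiply by
    the desired µV amplitude when rendering).
    """
    n = int(round(support_ms * fs / 1000.0))
    t = np.arange(n) / fs * 1000.0  # ms
    t_trough = support_ms * trough_frac
    t_peak = t_trough + trough_to_peak_ms
    w_neg = max(trough_to_peak_ms * 0.45, 0.08)
    w_pos = max(trough_to_peak_ms * 0.9, 0.16)
    tpl = -np.exp(-0.5 * ((t - t_trough) / w_neg) ** 2)
    tpl += 0.4 * np.exp(-0.5 * ((t - t_peak) / w_pos) ** 2)
    # taper the ends so insertion causes no step discontinuities
    taper = np.hanning(2 * max(n // 8, 2))
    k = taper.size // 2
    tpl[:k] *= taper[:k]
    tpl[-k:] *= taper[k:]
    return tpl / np.abs(tpl).max()


def msn_cell(events_label: str = "C") -> CellModel:
    """Default sparse-bursty MSN: 0.3 Hz baseline, 60 ms bursts after cues."""
    return CellModel(
        cell_type="MSN",
        baseline_rate=0.3,
        event_modulation=[EventModulation(events_label, gain=200.0, latency_s=0.15, duration_s=0.06)],
        template_width_ms=0.25,
    )


def tan_cell(events_label: str = "C") -> CellModel:
    """Default tonic TAN: 5 Hz baseline, cue-locked pause then rebound."""
    return CellModel(
        cell_type="TAN",
        baseline_rate=5.0,
        event_modulation=[
            EventModulation(events_label, gain=0.02, latency_s=0.05, duration_s=0.2),
            EventModulation(events_label, gain=1.8, latency_s=0.25, duration_s=0.2),
        ],
        template_width_ms=0.55,
    )


def _event_times(events, label: str) -> np.ndarray:
    """Extract event times for a label from a TrialTable-like object or array."""
    if events is None:
        return np.empty(0)
    if hasattr(events, "event_times"):
        return np.asarray(events.event_times(label), dtype=float)
    return np.asarray(events, dtype=float)


def rate_function(cell: CellModel, t: np.ndarray, events=None) -> np.ndarray:
    """Instantaneous firing rate (Hz) of the cell at times ``t``."""
    rate = np.full(t.shape, cell.baseline_rate, dtype=float)
    for mod in cell.event_modulation:
        for ev in _event_times(events, mod.event):
            lo, hi = ev + mod.latency_s, ev + mod.latency_s + mod.duration_s
            rate[(t >= lo) & (t < hi)] *= mod.gain
    return rate


def gen_spike_train(
    cell: CellModel,
    duration: float,
    events=None,
    seed: int | np.random.Generator = 0,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Draw an inhomogeneous-Poisson spike train for one unit.

    Uses thinning against the cell's piecewise rate function, then censors
    inter-spike intervals shorter than ``refractory_ms``.  Deterministic for a
    given integer seed.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rng = np.random.default_rng(seed)
    max_gain = max((m.gain for m in cell.event_modulation), default=1.0)
    lam_max = cell.baseline_rate * max(max_gain, 1.0)
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    keep = rng.uniform(0.0, lam_max, n_cand) < rate_function(cell, cand, events)
    times = cand[keep]
    if times.size == 0:
        return times
    # refractory censoring: drop any spike within refractory_ms of the last kept
    censor = refractory_ms / 1000.0
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= censor:
            kept.append(t)
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# noise and rendering


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def line_noise_waveform(
    noise: NoiseModel, n: int, fs: float, phase: float = 0.0
) -> np.ndarray:
    """Render the line-interference component of a NoiseModel."""
    if noise.line_amp == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    arg = 2 * np.pi * noise.line_freq * t + phase
    if noise.line_waveform == "sawtooth":
        out = noise.line_amp * sps.sawtooth(arg)
    else:
        out = noise.line_amp * np.sin(arg)
        for k, rel in noise.line_harmonics:
            out += noise.line_amp * rel * np.sin(k * arg)
    return out


def render_recording(
    units: Sequence[tuple[CellModel, np.ndarray]] | None,
    n_channels: int,
    fs: float = DEFAULT_FS,
    noise: NoiseModel | None = None,
    duration: float = 60.0,
    seed: int = 0,
    spike_amplitude_uv: float = 150.0,
    channel_labels: list[str] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Render unit spike trains plus noise into a voltage recording.

    ``units`` is a sequence of ``(CellModel, spike_times)``; unit *i* is
    placed on channel ``i % n_channels`` with its template trough aligned to
    each spike time.  Noise is drawn independently per channel.  Returns the
    recording and the paired ground truth.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    samples = np.zeros((n_channels, n))
    gt = GroundTruth()
    units = units or []
    for i, (cell, times) in enumerate(units):
        tpl = np.asarray(cell.waveform_template) * spike_amplitude_uv
        if tpl.size > n:
            raise ValueError("template longer than recording")
        ch = i % n_channels
        trough = int(np.argmin(tpl))
        for t in times:
            k = int(round(t * fs)) - trough
            lo, hi = max(k, 0), min(k + tpl.size, n)
            if hi <= lo:
                continue
            samples[ch, lo:hi] += tpl[lo - k : hi - k]
        gt.spike_times_per_unit.append(np.asarray(times, dtype=float))
        gt.unit_channels.append(ch)
    if noise is not None:
        phase = rng.uniform(0, 2 * np.pi) if noise.line_amp else 0.0
        gt.line_noise_phase = phase
        for ch in range(n_channels):
            if noise.white_sd:
                samples[ch] += noise.white_sd * rng.standard_normal(n)
            if noise.pink_sd:
                samples[ch] += noise.pink_sd * _pink_noise(n, rng)
            if noise.line_amp:
                samples[ch] += line_noise_waveform(noise, n, fs, phase)
    rec = Recording(samples, fs=fs, channel_labels=channel_labels)
    return rec, gt


# ---------------------------------------------------------------------------
# scan artifacts


def gen_artifact_template(spec: ArtifactSpec, fs: float = DEFAULT_FS) -> np.ndarray:
    """Voltage template (µV) of one scan artifact, starting at scan onset.

    R: symmetric triangular pulse spanning the scan width, scaled to
    ``amplitude``.  RC: the same pulse convolved with a causal exponential of
    time constant ``rc_tau`` (truncated at 4τ), renormalised to ``amplitude``
    — a longer decaying tail.  RAIL: the pulse scaled to ``amplitude`` and
    clipped at ±``clip_level``, with an exponential amplifier-recovery
    undershoot appended after the scan (decaying to exactly zero over
    4.5×recovery_tau).  Supports are strictly ordered R < RC < RAIL: the
    saturating artifact outlasts the scan by the amplifier recovery time.
    """
    n_scan = max(int(round(spec.scan_width_ms * fs / 1000.0)), 3)
    tri = sps.windows.triang(n_scan)
    if spec.amplitude == 0:
        return np.zeros(n_scan)
    if spec.kind == "R":
        return spec.amplitude * tri
    if spec.kind == "RC":
        n_k = max(int(round(4.0 * spec.rc_tau * fs / 1000.0)), 2)
        kern = np.exp(-np.arange(n_k) / (spec.rc_tau * fs / 1000.0))
        out = np.convolve(tri, kern)
        return spec.amplitude * out / out.max()
    # RAIL: clip, then append recovery from the rail back to baseline
    pulse = np.clip(spec.amplitude * tri, -spec.clip_level, spec.clip_level)
    t_rec = 4.5 * spec.recovery_tau
    n_rec = max(int(round(t_rec * fs / 1000.0)), 2)
    t = np.arange(1, n_rec + 1) / fs * 1000.0  # ms
    decay = np.exp(-t / spec.recovery_tau)
    # normalise so the segment ends at exactly 0 (no step back to baseline)
    decay = (decay - decay[-1]) / (1.0 - decay[-1])
    # amplifier settle: the released input slams toward the opposite rail and
    # rings back to baseline — saturation recovery is underdamped, so the
    # settle carries spike-band energy well past the scan itself
    ring = np.cos(2 * np.pi * spec.recovery_ring_hz * t / 1000.0)
    rec_seg = -spec.clip_level * decay * ring
    return np.concatenate([pulse, rec_seg])


def inject_artifacts(
    rec: Recording,
    spec: ArtifactSpec,
    channel_gains: Sequence[float] | None = None,
) -> tuple[Recording, np.ndarray]:
    """Add the periodic scan-artifact template to every channel.

    The template is added with its onset at ``phase_s, phase_s + period, ...``
    on all channels (scan artifacts are coherent across the array; per-channel
    ``channel_gains`` scale the common template).  For the RAIL kind the sum
    is re-clipped at ±clip_level, mimicking amplifier saturation.  Samples
    outside the artifact supports are bit-identical to the input.  Returns the
    new recording and the template *onset* times.
    """
    period = 1.0 / spec.scan_rate_hz
    if rec.duration < period:
        raise ValueError("recording shorter than one scan period")
    tpl = gen_artifact_template(spec, rec.fs)
    out = rec.copy()
    times = np.arange(spec.phase_s, rec.duration, period)
    gains = np.ones(rec.n_channels) if channel_gains is None else np.asarray(channel_gains)
    onsets = np.rint(times * rec.fs).astype(int)
    for k in onsets:
        lo, hi = k, min(k + tpl.size, rec.n_samples)
        if hi <= lo:
            continue
        seg = tpl[: hi - lo]
        for ch in range(rec.n_channels):
            out.samples[ch, lo:hi] += gains[ch] * seg
            if spec.kind == "RAIL" and spec.amplitude > 0:
                np.clip(
                    out.samples[ch, lo:hi],
                    -spec.clip_level,
                    spec.clip_level,
                    out=out.samples[ch, lo:hi],
                )
    return out, times


def detection_latency(spec: ArtifactSpec, fs: float, cfg=None) -> float:
    """Deterministic lag (s) between template onset and its detected peak.

    The artifact detector reports the local maximum of the rectified
    bandpassed signal, which for a given pulse shape sits a fixed interval
    after the template onset.  Computed by running the detection filter chain
    on the isolated template padded with silence; used to compare detected
    peak times against injected onset times.
    """
    from ecpkit.artifact_removal import DetectorConfig, _detection_signal

    cfg = cfg or DetectorConfig()
    tpl = gen_artifact_template(spec, fs)
    pad = int(round(0.5 * fs))
    x = np.zeros(2 * pad + tpl.size)
    x[pad : pad + tpl.size] = tpl
    det = _detection_signal(x[np.newaxis, :], fs, cfg.band_low, cfg.band_high)
    return (int(np.argmax(det)) - pad) / fs


# ---------------------------------------------------------------------------
# cyclic voltammogram streams


def cv_voltage_axis(points_per_scan: int = 850) -> np.ndarray:
    """Triangular applied-voltage axis: −0.4 V up to 1.3 V and back, in volts."""
    half = points_per_scan // 2
    up = np.linspace(-0.4, 1.3, half, endpoint=False)
    down = np.linspace(1.3, -0.4, points_per_scan - half)
    return np.concatenate([up, down])


def _sweep_peak(v: np.ndarray, center: float, width: float, anodic: bool) -> np.ndarray:
    """Gaussian redox peak restricted to one sweep direction."""
    half = v.size // 2
    mask = np.zeros(v.size)
    sl = slice(0, half) if anodic else slice(half, None)
    mask[sl] = 1.0
    return mask * np.exp(-0.5 * ((v - center) / width) ** 2)


def da_standard_shape(voltage_axis: np.ndarray) -> np.ndarray:
    """Unit dopamine background-subtracted CV: oxidation near +0.6 V on the
    anodic sweep, reduction near −0.2 V on the cathodic sweep."""
    ox = _sweep_peak(voltage_axis, 0.6, 0.15, anodic=True)
    red = -0.6 * _sweep_peak(voltage_axis, -0.2, 0.12, anodic=False)
    shape = ox + red
    return shape / np.abs(shape).max()


def ph_standard_shape(voltage_axis: np.ndarray) -> np.ndarray:
    """Unit basic-pH-shift CV: broad features distinct from dopamine."""
    a = -_sweep_peak(voltage_axis, 0.2, 0.35, anodic=True)
    b = _sweep_peak(voltage_axis, 1.0, 0.25, anodic=True)
    c = 0.5 * _sweep_peak(voltage_axis, 0.4, 0.4, anodic=False)
    shape = a + b + c
    return shape / np.abs(shape).max()


def movement_standard_shape(voltage_axis: np.ndarray, variant: int = 0) -> np.ndarray:
    """Unit movement-artifact CV: slow broadband drift across the scan, not
    tied to redox potentials."""
    n = voltage_axis.size
    x = np.linspace(0, 1, n)
    if variant == 0:
        shape = np.sin(np.pi * x) * (1 - 0.5 * x)
    else:
        shape = x - 0.5 * x**2 + 0.3 * np.sin(2 * np.pi * x)
    return shape / np.abs(shape).max()


def background_cv(voltage_axis: np.ndarray, scale_na: float = 400.0) -> np.ndarray:
    """Large capacitive background current: proportional to sweep direction
    (charging current ~ C·dV/dt) with mild voltage dependence."""
    half = voltage_axis.size // 2
    direction = np.ones(voltage_axis.size)
    direction[half:] = -1.0
    return scale_na * direction * (1.0 + 0.15 * voltage_axis)


DA_SENSITIVITY_NA_PER_NM = 0.02  # carbon-fiber electrode sensitivity


@dataclass
class CVStreamTruth:
    """Ground-truth per-scan concentrations for a synthetic CV stream."""

    da_nm: np.ndarray
    movement_na: np.ndarray


def gen_cv_stream(
    transients: list[tuple[float, float, float]] | None = None,
    n_scans: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    points_per_scan: int = 850,
    movement_events: list[tuple[float, float]] | None = None,
    sensitivity: float = DA_SENSITIVITY_NA_PER_NM,
):
    """Generate a synthetic CV stream with known dopamine transients.

    ``transients`` are ``(onset_s, amplitude_nM, decay_s)`` tuples: the
    dopamine concentration steps to ``amplitude`` at onset and decays
    exponentially.  ``movement_events`` are ``(scan_time_s, amplitude_nA)``
    single-scan movement artifacts.  Frames are background + analyte
    contributions + white noise; frame timestamps at 100 ms spacing.

    Returns ``(CVStream, CVStreamTruth)``.
    """
    from ecpkit.fscv_chemometrics import CVStream

    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    rng = np.random.default_rng(seed)
    v = cv_voltage_axis(points_per_scan)
    da_shape = da_standard_shape(v)
    mv_shape = movement_standard_shape(v)
    bg = background_cv(v)
    scan_times = np.arange(n_scans) * 0.1
    da_nm = np.zeros(n_scans)
    for onset, amp, decay in transients or []:
        after = scan_times >= onset
        da_nm[after] += amp * np.exp(-(scan_times[after] - onset) / decay)
    mv_na = np.zeros(n_scans)
    for t_ev, amp in movement_events or []:
        mv_na[int(round(t_ev / 0.1))] += amp
    frames = np.tile(bg, (n_scans, 1))
    frames += np.outer(da_nm * sensitivity, da_shape)
    frames += np.outer(mv_na, mv_shape)
    if noise_sd > 0:
        frames += noise_sd * rng.standard_normal(frames.shape)
    stream = CVStream(frames=frames, voltage_axis=v, scan_times=scan_times)
    return stream, CVStreamTruth(da_nm=da_nm, movement_na=mv_na)
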