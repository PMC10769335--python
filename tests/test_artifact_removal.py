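"""Scan-artifact detection, periodicity repair, interpolation, 60 Hz variant."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecpkit import synthdata as sd
from ecpkit.artifact_removal import (
    ArtifactEvents,
    DetectorConfig,
    LineNoiseConfig,
    _detection_signal,
    _peaks_after_crossings,
    altered_fraction,
    clean,
    detect_scan_artifacts,
    enforce_periodicity,
    interpolate_segments,
    remove_line_harmonics,
)
from ecpkit.recording import Recording


def periodic_grid_oracle(times, period, tol):
    """Brute-force periodicity repair: try every peak as the grid anchor,
    snap peaks to their nearest grid slot (one per slot, within tol), keep
    the anchor retaining the most peaks, and fill interior empty slots."""
    times = np.asarray(times, dtype=float)
    best = (-1, None)
    for anchor in times:
        slots = {}
        for t in times:
            k = round((t - anchor) / period)
            if abs(t - (anchor + k * period)) <= tol and k not in slots:
                slots[k] = t
        if len(slots) > best[0]:
            best = (len(slots), (anchor, slots))
    anchor, slots = best[1]
    ks = sorted(slots)
    out = []
    for k in range(ks[0], ks[-1] + 1):
        if k in slots:
            out.append((slots[k], False))
        else:
            # predict from the flanking retained peaks (local periodicity)
            ka = max(j for j in ks if j < k)
            kb = min(j for j in ks if j > k)
            t = slots[ka] + (k - ka) * (slots[kb] - slots[ka]) / (kb - ka)
            out.append((t, True))
    return out


class TestDetection:
    def test_all_zero_recording_empty_events(self):
        rec = Recording(np.zeros((5, 90_000)), fs=30_000.0)
        assert len(detect_scan_artifacts(rec)) == 0

    def test_threshold_is_1p75_times_sd(self):
        """Detection threshold equals 1.75x the SD of the rectified
        bandpassed signal: a peak at 1.6 SD is ignored, one at 2 SD found."""
        det = np.abs(np.random.default_rng(0).standard_normal(10_000))
        sdv = det.std()
        peaks_lo = _peaks_after_crossings(det, 1.75 * sdv)
        # every excursion above the exact threshold is found, none below
        assert (det[peaks_lo] > 1.75 * sdv).all()

    def test_too_short_recording_rejected(self):
        rec = Recording(np.zeros((2, 3000)), fs=30_000.0)
        with pytest.raises(ValueError):
            detect_scan_artifacts(rec)

    def test_injected_artifacts_detected_within_1ms(self, injected_r):
        """≥ 99% of injected scans detected within ±1 ms (after removing the
        template's deterministic detection latency)."""
        injected, times, spec = injected_r
        cfg = DetectorConfig()
        raw = detect_scan_artifacts(injected, cfg)
        events = enforce_periodicity(raw, cfg, injected)
        lat = sd.detection_latency(spec, injected.fs, cfg)
        detected = events.peak_times[~events.inserted_flags]
        err = np.abs((times[:, None] + lat) - detected[None, :]).min(axis=1)
        assert (err < 1e-3).mean() >= 0.99


class TestPeriodicity:
    def test_perfectly_periodic_unchanged(self):
        raw = ArtifactEvents(np.array([0.100, 0.200, 0.300]))
        out = enforce_periodicity(raw, DetectorConfig())
        assert np.allclose(out.peak_times, [0.100, 0.200, 0.300])
        assert not out.inserted_flags.any()

    def test_worked_example_drop_and_insert(self):
        """{0.100, 0.200, 0.353, 0.400}: 0.353 dropped, peak inserted near
        0.300; agrees with the brute-force periodic-grid oracle."""
        raw = ArtifactEvents(np.array([0.100, 0.200, 0.353, 0.400]))
        out = enforce_periodicity(raw, DetectorConfig())
        assert len(out) == 4
        assert np.allclose(out.peak_times, [0.100, 0.200, 0.300, 0.400], atol=1e-9)
        assert out.inserted_flags.tolist() == [False, False, True, False]
        oracle = periodic_grid_oracle(raw.peak_times, 0.1, 0.005)
        assert np.allclose([t for t, _ in oracle], out.peak_times)
        assert [f for _, f in oracle] == out.inserted_flags.tolist()

    def test_fewer_than_two_peaks_warns_unchanged(self):
        raw = ArtifactEvents(np.array([0.25]))
        with pytest.warns(UserWarning):
            out = enforce_periodicity(raw, DetectorConfig())
        assert np.allclose(out.peak_times, [0.25])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 49), min_size=3, max_size=20, unique=True))
    def test_matches_grid_oracle_on_jittered_grids(self, slots):
        """On any subset of a periodic grid (with small jitter), the retained
        + inserted peaks agree with the brute-force oracle."""
        rng = np.random.default_rng(sum(slots))
        times = np.sort(0.05 + np.array(sorted(slots)) * 0.1
                        + rng.uniform(-0.002, 0.002, len(slots)))
        cfg = DetectorConfig()
        out = enforce_periodicity(ArtifactEvents(times), cfg)
        oracle = periodic_grid_oracle(times, cfg.period_s, 0.005)
        assert np.allclose(out.peak_times, [t for t, _ in oracle], atol=1e-9)

    def test_spacings_within_tolerance_after_enforcement(self):
        rng = np.random.default_rng(5)
        times = np.sort(np.concatenate([
            0.05 + np.arange(30) * 0.1 + rng.uniform(-0.003, 0.003, 30),
            rng.uniform(0, 3, 10),  # aperiodic contaminants
        ]))
        out = enforce_periodicity(ArtifactEvents(times), DetectorConfig())
        spacing = np.diff(out.peak_times)
        assert (np.abs(spacing - 0.1) <= 0.011).all()  # tol on both endpoints

    def test_subthreshold_artifact_recovered_by_insertion(self, spiking_recording):
        """An artifact suppressed below threshold is still captured: the
        inserted peak lies within ±2 ms of the true artifact time."""
        rec = spiking_recording.copy()
        spec = sd.ArtifactSpec(kind="R", amplitude=500.0)
        injected, times = sd.inject_artifacts(rec, spec)
        # suppress scan #10 completely
        k = int(round(times[10] * rec.fs))
        tpl = sd.gen_artifact_template(spec, rec.fs)
        injected.samples[:, k : k + tpl.size] -= tpl
        cfg = DetectorConfig()
        events = enforce_periodicity(detect_scan_artifacts(injected, cfg), cfg, injected)
        lat = sd.detection_latency(spec, rec.fs, cfg)
        inserted = events.peak_times[events.inserted_flags]
        assert inserted.size >= 1
        assert np.abs(inserted - (times[10] + lat)).min() < 2e-3


class TestInterpolation:
    def test_empty_events_identity(self, noise_recording):
        out = interpolate_segments(noise_recording, ArtifactEvents(np.empty(0)))
        assert np.array_equal(out.samples, noise_recording.samples)

    def test_window_samples_on_exact_line(self):
        """Single peak at sample p, 30 kHz: samples p−150…p+210 lie exactly
        on the line through (p−151, x[p−151]) and (p+211, x[p+211])."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 30_000))
        rec = Recording(x.copy(), fs=30_000.0)
        p = 15_000
        out = interpolate_segments(rec, ArtifactEvents(np.array([p / 30_000.0])))
        a, b = p - 151, p + 211
        line = x[0, a] + (x[0, b] - x[0, a]) * (np.arange(a + 1, b) - a) / (b - a)
        assert np.allclose(out.samples[0, a + 1 : b], line)
        # locality: everything else untouched
        assert np.array_equal(out.samples[0, :a + 1], x[0, :a + 1])
        assert np.array_equal(out.samples[0, b:], x[0, b:])

    def test_interpolated_runs_are_straight(self, cleaned_r, injected_r):
        """Linearity of fill: zero second difference over every altered run."""
        injected, _, _ = injected_r
        cleaned, events = cleaned_r
        changed = np.flatnonzero((cleaned.samples != injected.samples).any(axis=0))
        runs = np.split(changed, np.flatnonzero(np.diff(changed) > 1) + 1)
        for run in runs:
            seg = cleaned.samples[0, run[0] - 1 : run[-1] + 2]
            assert np.abs(np.diff(seg, 2)).max() < 1e-6

    def test_altered_fraction_near_12_percent(self, cleaned_r, injected_r):
        """10 Hz scans with the default −5..+7 ms window alter ~12% of
        samples (361-sample closed windows; exact up to edge effects)."""
        injected, times, _ = injected_r
        cleaned, events = cleaned_r
        frac = (cleaned.samples != injected.samples).any(axis=0).mean()
        assert frac * 100 == pytest.approx(12.0, abs=0.1)
        # closed-window accounting: 361 samples per scan
        expect = times.size * 361 / injected.n_samples
        assert frac == pytest.approx(expect, abs=2 * 361 / injected.n_samples)

    def test_overlapping_windows_merged(self):
        rec = Recording(np.random.default_rng(1).standard_normal((1, 9000)), fs=30_000.0)
        ev = ArtifactEvents(np.array([0.1, 0.105]))  # windows overlap
        out = interpolate_segments(rec, ev)
        changed = np.flatnonzero(out.samples[0] != rec.samples[0])
        assert np.diff(changed).max() == 1  # one contiguous run
        seg = out.samples[0, changed[0] - 1 : changed[-1] + 2]
        assert np.abs(np.diff(seg, 2)).max() < 1e-9


class TestLineNoise:
    def test_threshold_uses_8x_mean(self):
        """Rectified signal with mean 2 µV thresholds at 16 µV: excursions
        to 15 µV are ignored, excursions to 17 µV are found."""
        det = np.full(10_000, 2.0)
        det[1000:1010] = 15.0
        det[5000:5010] = 17.0
        det /= det.mean() / 2.0  # renormalise mean to exactly 2 µV
        thr = LineNoiseConfig().threshold_mult_mean * det.mean()
        peaks = _peaks_after_crossings(det, thr)
        assert peaks.size == 1 and 5000 <= peaks[0] < 5010

    def test_sawtooth_line_noise_detected_at_60hz(self):
        """60 Hz sawtooth (content above 300 Hz): detected peaks spaced
        1/60 s ± 0.5 ms."""
        noise = sd.NoiseModel(white_sd=10.0, pink_sd=0.0, line_amp=150.0,
                              line_waveform="sawtooth")
        rec, _ = sd.render_recording(None, 3, noise=noise, duration=5.0, seed=7)
        cleaned, events = remove_line_harmonics(rec)
        assert len(events) > 200
        spacings = np.diff(np.sort(events.peak_times[~events.inserted_flags]))
        spacings = spacings[spacings < 0.05]  # consecutive cycles
        assert np.abs(spacings - 1 / 60.0).max() < 5e-4

    def test_no_line_contamination_alters_little(self, noise_recording):
        cleaned, events = remove_line_harmonics(noise_recording)
        frac = (cleaned.samples != noise_recording.samples).any(axis=0).mean()
        assert frac < 0.01


class TestClean:
    def test_artifact_free_input_untouched(self, noise_recording):
        """False-positive control: < 1% of samples altered on pure noise."""
        cleaned, _ = clean(noise_recording)
        frac = (cleaned.samples != noise_recording.samples).any(axis=0).mean()
        assert frac < 0.01

    def test_idempotence(self, cleaned_r):
        """clean(clean(x)) alters < 0.5% additional samples."""
        once, _ = cleaned_r
        twice, _ = clean(once)
        frac = (twice.samples != once.samples).any(axis=0).mean()
        assert frac < 0.005

    def test_both_contaminants_removed(self):
        """Scan artifacts + sawtooth line noise: downstream spike detection
        false positives at scan times < 1 per 100 scans."""
        from ecpkit.spike_extraction import SpikeConfig, detect_spikes, highpass

        noise = sd.NoiseModel(line_amp=120.0, line_waveform="sawtooth")
        rec, _ = sd.render_recording(None, 4, noise=noise, duration=20.0, seed=8)
        injected, times = sd.inject_artifacts(rec, sd.ArtifactSpec(kind="R", amplitude=500.0))
        cleaned, _ = clean(injected, DetectorConfig(), LineNoiseConfig())
        spikes = detect_spikes(highpass(cleaned), SpikeConfig())
        hits = 0
        for ch in range(4):
            for t in spikes[ch]:
                if np.abs(times + 0.00425 - t).min() < 0.006:  # near scan centers
                    hits += 1
        assert hits / times.size < 0.01 * 4  # < 1 per 100 scans per channel
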