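"""Spike filtering, detection, waveforms, features, clustering, cell typing."""

import numpy as np
import pytest
from scipy import signal as sps

from ecpkit import synthdata as sd
from ecpkit.recording import Recording
from ecpkit.spike_extraction import (
    SpikeConfig,
    auto_invalidate_and_cluster,
    build_spikeset,
    classify_cell_type,
    compute_features,
    detect_spikes,
    extract_waveforms,
    highpass,
    robust_sd,
    sort_channel,
    summarize_unit,
)

FS = 30_000.0


def sine_recording(freq, fs=FS, dur=2.0):
    t = np.arange(int(dur * fs)) / fs
    return Recording(np.sin(2 * np.pi * freq * t)[None, :], fs=fs)


class TestHighpass:
    def test_dc_rejection(self):
        rec = Recording(np.full((1, 60_000), 100.0), fs=FS)
        out = highpass(rec)
        assert np.abs(out.samples[0, 30_000:]).max() < 1e-3

    @pytest.mark.parametrize(
        "freq,check",
        [(10.0, "stop"), (1000.0, "pass")],
        ids=["10Hz_stopband", "1kHz_passband"],
    )
    def test_frequency_response_matches_4pole_design(self, freq, check):
        """Attenuation agrees with the analytic 4-pole Butterworth response:
        ≥ 40 dB down at 10 Hz, < 3 dB down at 1 kHz."""
        cfg = SpikeConfig()
        out = highpass(sine_recording(freq), cfg)
        gain = np.abs(out.samples[0, 30_000:]).max()  # after settling
        sos = sps.butter(4, cfg.hp_cutoff / (FS / 2), "highpass", output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq / (FS / 2) * np.pi])
        assert gain == pytest.approx(np.abs(h[0]), rel=0.05, abs=1e-4)
        if check == "stop":
            assert 20 * np.log10(gain) < -40
        else:
            assert 20 * np.log10(gain) > -3

    def test_causal_filter_truncation_equivalence(self):
        """Forward-only contract: output at t depends only on inputs ≤ t."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 30_000))
        full = highpass(Recording(x, fs=FS)).samples[0]
        half = highpass(Recording(x[:, :15_000], fs=FS)).samples[0]
        assert np.array_equal(full[:15_000], half)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(Recording(np.zeros((1, 1000)), fs=400.0), SpikeConfig())


class TestDetection:
    def test_all_zero_no_spikes(self):
        rec = Recording(np.zeros((2, 30_000)), fs=FS)
        assert all(t.size == 0 for t in detect_spikes(rec))

    def test_known_templates_all_detected(self):
        """50 spikes at known times, SNR 10: all detected within ±0.2 ms."""
        cell = sd.CellModel(baseline_rate=1.0)
        truth = np.sort(np.random.default_rng(1).uniform(1, 59, 50))
        noise = sd.NoiseModel(white_sd=15.0, pink_sd=0.0)
        rec, _ = sd.render_recording(
            [(cell, truth)], 1, noise=noise, duration=60.0, seed=2,
            spike_amplitude_uv=150.0,
        )
        found = detect_spikes(highpass(rec))[0]
        err = np.abs(truth[:, None] - found[None, :]).min(axis=1)
        assert (err < 2e-4).all()

    def test_refractory_censor_keeps_one_of_two(self):
        """Two crossings 0.4 ms apart: one event retained."""
        x = np.zeros((1, 30_000))
        x[0, 1000] = -200.0
        x[0, 1012] = -200.0  # 0.4 ms later
        rec = Recording(x, fs=FS)
        cfg = SpikeConfig()
        # bypass filtering: feed the "filtered" signal directly
        times = detect_spikes(rec, cfg)[0]
        assert times.size == 1

    def test_threshold_is_robust_sd_multiple(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100_000)
        assert robust_sd(x) == pytest.approx(1.0, rel=0.02)


class TestWaveforms:
    def test_window_arithmetic(self):
        """Event at sample 1000 yields samples 992…1039 (48 total, 8 pre)."""
        x = np.arange(60_000, dtype=float)[None, :]
        rec = Recording(x, fs=FS)
        wfs, kept = extract_waveforms(rec, np.array([1000 / FS]))
        assert wfs.shape == (1, 48)
        assert wfs[0, 0] == 992 and wfs[0, -1] == 1039

    def test_window_counts_match_sampling_arithmetic(self):
        cfg = SpikeConfig()
        assert cfg.waveform_len == round(1.6e-3 * FS)
        assert cfg.pre_samples == round(0.267e-3 * FS)

    def test_event_too_early_skipped(self):
        rec = Recording(np.zeros((1, 1000)), fs=FS)
        wfs, kept = extract_waveforms(rec, np.array([3 / FS]))
        assert len(wfs) == 0 and kept.size == 0

    def test_extracted_mean_matches_template(self):
        """Injected-template events: mean waveform correlates r > 0.99."""
        cell = sd.CellModel(baseline_rate=1.0)
        truth = np.arange(1.0, 50.0, 1.0)
        rec, _ = sd.render_recording(
            [(cell, truth)], 1, noise=sd.NoiseModel(white_sd=15.0, pink_sd=0.0),
            duration=55.0, seed=4,
        )
        from ecpkit.spike_extraction import _subsample_align

        filt = highpass(rec)
        times = detect_spikes(filt)[0]
        wfs, _ = extract_waveforms(filt, times)
        mean_wf = _subsample_align(wfs).mean(axis=0)
        tpl_filt = highpass(
            Recording(np.pad(cell.waveform_template * 150.0, (500, 500))[None, :], fs=FS)
        ).samples[0]
        k = np.argmin(tpl_filt)
        # one-sample alignment ambiguity between noisy trough sampling and
        # the template grid is inherent; compare at the best integer shift
        r = max(
            np.corrcoef(mean_wf, tpl_filt[k - 8 + s : k + 40 + s])[0, 1]
            for s in (-1, 0, 1)
        )
        assert r > 0.99


class TestFeatures:
    def test_zero_waveform_zero_features(self):
        e, nle, _ = compute_features(np.zeros((3, 48)))
        assert not e.any() and not nle.any()

    def test_energy_quadratic_scaling(self):
        w = np.random.default_rng(5).standard_normal((4, 48))
        e1, _, _ = compute_features(w)
        e2, _, _ = compute_features(2 * w)
        assert np.allclose(e2, 4 * e1)

    def test_single_waveform_no_pc_scores(self):
        _, _, scores = compute_features(np.ones((1, 48)))
        assert scores is None

    def test_two_templates_separable_in_pc_space(self):
        """Two well-separated units: silhouette of the true labels > 0.5 in
        PC1–PC2."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(6)
        t1 = sd.spike_template(trough_to_peak_ms=0.25) * 150
        t2 = sd.spike_template(trough_to_peak_ms=0.6) * 260
        W = np.vstack([
            t1 + 5 * rng.standard_normal((60, t1.size)),
            t2 + 5 * rng.standard_normal((60, t2.size)),
        ])
        _, _, scores = compute_features(W)
        labels = np.repeat([0, 1], 60)
        assert silhouette_score(scores[:, :2], labels) > 0.5


class TestInvalidationAndClustering:
    def test_single_template_single_cluster(self, spiking_recording):
        """No outliers, one template per channel: ≥ 95% of events in one
        cluster."""
        spikes = sort_channel(spiking_recording, 0)
        labels, counts = np.unique(
            spikes.unit_labels[spikes.unit_labels > 0], return_counts=True
        )
        assert counts.max() / len(spikes) >= 0.95

    def test_glitches_flagged_invalid(self):
        """Events with ~20x template energy are all flagged invalid."""
        cell = sd.CellModel(baseline_rate=2.0)
        truth = np.arange(1.0, 50.0, 0.5)
        rec, _ = sd.render_recording(
            [(cell, truth)], 1, noise=sd.NoiseModel(white_sd=8.0, pink_sd=0.0),
            duration=55.0, seed=7,
        )
        glitch_times = np.array([10.05, 20.05, 30.05])
        for g in glitch_times:
            k = int(g * FS)
            rec.samples[0, k : k + 20] = -700.0  # electrostatic-style glitch
        spikes = sort_channel(rec, 0)
        for g in glitch_times:
            idx = np.abs(spikes.times - g).argmin()
            if abs(spikes.times[idx] - g) < 2e-3:
                assert spikes.unit_labels[idx] == 0

    def test_events_near_artifact_times_excluded(self):
        rng = np.random.default_rng(8)
        cell = sd.CellModel(baseline_rate=2.0)
        truth = np.sort(rng.uniform(1, 29, 60))
        rec, _ = sd.render_recording(
            [(cell, truth)], 1, noise=sd.NoiseModel(white_sd=8.0, pink_sd=0.0),
            duration=30.0, seed=9,
        )
        spikes = sort_channel(rec, 0, artifact_times=truth[:5])
        for t in truth[:5]:
            sel = np.abs(spikes.times - t) <= 1e-3
            assert (spikes.unit_labels[sel] == 0).all()


class TestSummaries:
    def test_isi_histogram_and_rate(self):
        """Spikes at 0, 0.1, 0.2 s: all ISI mass at 100 ms, rate ~10 Hz."""
        summ = summarize_unit(times=np.array([0.0, 0.1, 0.2]), bin_ms=2)
        assert summ.mean_rate == pytest.approx(10.0)
        assert summ.isi_histogram.sum() == 2
        filled = np.flatnonzero(summ.isi_histogram)
        assert len(filled) == 1
        assert summ.isi_bin_edges_ms[filled[0]] == pytest.approx(100.0)

    def test_isi_conservation(self):
        rng = np.random.default_rng(10)
        times = np.sort(rng.uniform(0, 100, 500))
        summ = summarize_unit(times=times, bin_ms=1)
        assert summ.isi_histogram.sum() == times.size - 1

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            summarize_unit(times=np.array([0.0, 1.0]), bin_ms=5)

    @pytest.mark.parametrize(
        "rate,width,burst,expect",
        [
            (0.5, 0.25, 0.3, "MSN"),
            (5.0, 0.55, 0.02, "TAN"),
            (30.0, 0.3, 0.5, "other"),
            (0.5, 0.3, 0.01, "other"),  # sparse but not bursty
        ],
    )
    def test_classification_rule(self, rate, width, burst, expect):
        assert classify_cell_type(rate, width, burst) == expect

    def test_synthetic_msn_and_tan_classified(self):
        """Synthetic MSN (sparse, bursty, narrow) and TAN (tonic, pausing,
        broad) land in their own classes."""
        from ecpkit.task_alignment import gen_trials

        trials = gen_trials(60, seed=11)
        dur = float(trials.df.RW_time.max() + 5)
        for factory, expect in ((sd.msn_cell, "MSN"), (sd.tan_cell, "TAN")):
            cell = factory()
            times = sd.gen_spike_train(cell, dur, trials, seed=12)
            wfs = np.tile(cell.waveform_template * 150, (times.size, 1))
            summ = summarize_unit(times=times, waveforms=wfs, fs=FS, span_s=dur)
            assert summ.putative_type == expect
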