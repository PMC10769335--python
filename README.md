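# ecpkit

Spike and dopamine signal extraction from concurrent electrochemical (FSCV)
and electrophysiological recordings.

## The problem

Fast-scan cyclic voltammetry (FSCV) measures dopamine by sweeping the
potential at a carbon-fiber electrode from −0.4 V up to 1.3 V and back at
400 V/s, ten times per second.  When FSCV runs next to extracellular
voltage electrodes — the combined "ECP" configuration used to record
dopamine and striatal spiking simultaneously — every 8.5 ms scan couples a
large transient into the electrophysiology channels.  These scan artifacts
are routinely mistaken for action potentials by threshold-based spike
detectors, so they must be removed before any spike analysis.  `ecpkit`
implements the whole desk-side pipeline for such recordings:

* **artifact removal** — automatic detection of the 10 Hz scan artifacts
  (no hardware clock needed) and their removal by temporal linear
  interpolation, plus a variant for 60 Hz line noise and its harmonics;
* **spike extraction** — 250 Hz causal high-pass, negative-threshold
  detection, 48-sample waveforms, energy / nonlinear-energy / PCA features,
  clustering, ISI histograms and an MSN/TAN cell-type heuristic;
* **dopamine chemometrics** — background-subtracted cyclic voltammograms
  projected onto principal components of dopamine / pH / movement standards,
  with Q-residual and movement-correlation nulling, yielding [ΔDA] in nM;
* **task alignment** — peri-event rasters and condition-split trial
  averages (reward size, target direction) for spikes and [ΔDA];
* **synthetic data + validation** — a ground-truth simulator for all of the
  above and a harness that scores spike recovery after artifact injection.

## The core algorithm

Scan artifacts are found from their periodicity alone:

1. average the channels (artifacts are coherent across the array);
2. bandpass the average at 10–100 Hz and rectify: `d(t) = |BPF(x̄(t))|`;
3. threshold at `1.75 × SD(d)`; after each positive-going crossing keep the
   first local maximum of `d`;
4. retain only peaks whose spacing matches the 100 ms scan period
   (tolerance 5 ms) and insert predicted peaks into gaps, so scans that dip
   below threshold are still caught;
5. per channel, replace the samples in a −5…+7 ms window around each peak
   with the straight line between the window's boundary samples.

With 10 Hz scans the 12 ms window removes 12% of the recording, so the spike
recovery rate after cleaning is bounded near 88% for uniformly timed spikes.
The 60 Hz variant swaps step 2 for a 300 Hz high-pass, thresholds at 8× the
rectified signal's mean, and interpolates ±0.5 ms around each peak.

Dopamine concentration change is estimated per 100 ms frame by principal
component regression: background-subtracted currents ΔI are projected onto
the orthonormal union of per-analyte principal subspaces, the dopamine score
maps to nM through a calibration regression, and frames are nulled when
their residual exceeds Q_α (leave-one-out 95th percentile of the standards'
residuals) or when they correlate with a movement-artifact template at
r > 0.8.

## Worked example

```python
import ecpkit.synthdata as sd
from ecpkit.artifact_removal import clean
from ecpkit.spike_extraction import sort_channel, summarize_unit
from ecpkit.validation import run_validation, table_report
from ecpkit.cli import validation_recording, artifact_spec_for

# a 30 s, 4-channel synthetic session: one 5 Hz unit per channel + noise
rec = validation_recording(duration=30.0, n_channels=4, rate_hz=5.0, seed=0)

# inject resistive (R-type) scan artifacts, then remove them
injected, scan_times = sd.inject_artifacts(rec, artifact_spec_for("R"))
cleaned, events = clean(injected)
print(len(scan_times), len(events[0]))          # 300 300  (all scans found)
frac = (cleaned.samples != injected.samples).any(axis=0).mean()
print(f"{100*frac:.2f}%")                       # 12.03%  (interpolated share)

# extract spikes from the cleaned recording
spikes = sort_channel(cleaned, 0)
summ = summarize_unit(spikes, unit=1, bin_ms=1)
print(f"{summ.mean_rate:.2f} Hz")               # 4.58 Hz

# artifact-injection validation across all three morphologies
results = run_validation(rec, [artifact_spec_for(k) for k in ("R", "RC", "RAIL")])
print(table_report(results).round(1))
```

The recovery table for this small session:

```
kind     R  RAIL    RC  grand_mean
ch0   88.1  86.0  86.7         NaN
ch1   85.4  79.5  85.4         NaN
ch2   80.1  77.9  80.1         NaN
ch3   84.5  77.4  84.5         NaN
mean  84.5  80.2  84.2        83.0
```

Each cell is the percent of reference spikes (sorted on the clean recording)
that are recovered — matched within 0.5 ms with an undistorted waveform —
after injecting that artifact type and running the removal pipeline.
Saturating (rail) artifacts recover worst: their amplifier-recovery tail
outlasts the interpolation window.

A command-line interface covers the same pipeline
(`ecpkit simulate | clean | sort | fscv | validate | align | all`);
`ecpkit all --seed 7` reproduces a full synthetic run end to end.

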