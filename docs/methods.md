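# Methods

This note documents the models, parameter choices and numerical conventions
behind `ecpkit`, and what its synthetic-data validation does and does not
establish about real recordings.

## Scan-artifact removal

**Model.** FSCV applies a triangular −0.4 → 1.3 → −0.4 V sweep at 400 V/s
(8.5 ms) every 100 ms.  The coupled artifact on the electrophysiology
channels is treated as an unknown-shape, strictly periodic transient that is
coherent across channels.  No artifact template is assumed — template
subtraction fails here because artifact shape varies with electrode distance
and the nonlinear electrode–tissue interface — and no hardware clock is
required: timing is recovered from the data's own periodicity.

**Detection path.** Channel mean → 4th-order Butterworth bandpass
10–100 Hz → absolute value → threshold at 1.75 × SD of that signal → first
local maximum after each positive-going crossing (bounded at the next
down-crossing, so one peak per excursion).  The detection filters are
applied zero-phase (forward–backward) so peak times carry no group delay;
this choice affects only detection — the data path is never filtered, which
preserves the full spike bandwidth for sorting.  The SD is computed over the
whole rectified record; a chunked option would suit nonstationary data but
is not needed for the stationary synthetic conditions.

**Periodicity enforcement.** Peaks are chained greedily: a peak is retained
when its spacing to the previously retained peak is within 5 ms of an
integer number of 100 ms periods.  The chain is anchored at the raw peak
that maximises the retained count, so one early spurious peak cannot poison
the chain.  Gaps of k periods receive k−1 inserted peaks at locally
predicted times (even spacing between the flanking retained peaks), refined
to the local maximum of the rectified bandpassed mean within ± tolerance;
a refinement landing on the search-window edge falls back to the
prediction.  The 5 ms tolerance is half the scan width: wide enough for
peak-shape jitter, narrow enough to reject spikes.

**Plausibility guard.** The printed detection rule fires frequently on
artifact-free noise (the rectified bandpassed noise crosses 1.75 × its SD
often), and accidental near-periodic chains survive enforcement.  Because
FSCV scans, when present, run continuously, `clean` interpolates only when
(a) detected (non-inserted) peaks cover at least half the expected scan
slots and (b) their RMS deviation from a best-fit periodic grid is below
1 ms — scan clocks are sub-millisecond stable, whereas noise chains jitter
by milliseconds inside the tolerance.  On artifact-free synthetic noise
this guard reduces altered samples to zero; it would mask genuinely
intermittent scanning, which is outside the intended conditions.

**Interpolation.** Windows are closed sample intervals
`[peak − round(5 ms·fs), peak + round(7 ms·fs)]` (at 30 kHz: 361 samples,
12.03 ms), merged when overlapping, replaced per channel by the straight
line through the last sample before and the first sample after the window.
Edge windows clamp to the record; a window missing one boundary uses the
other side's value as a constant fill.  The −5/+7 ms asymmetry covers
amplifier recovery and tissue low-pass broadening after the scan; at 10 Hz
it consumes 12% of the recording, which bounds spike recovery near 88%.

**60 Hz variant.** Line interference in shared-ground rigs carries content
above 300 Hz (it is far from sinusoidal), so the bandpass is replaced by a
300 Hz high-pass and the threshold by 8 × the rectified signal's mean; the
mean is used because harmonic-rich noise inflates the SD itself.
Rectification is retained (the noise is bipolar), periodicity is enforced at
1/60 s with a 2 ms tolerance, and interpolation spans ±0.5 ms — wide enough
for the narrow harmonic transients, only 6% of samples at 60 events/s.
Pure sinusoidal hum below 300 Hz is invisible to this variant by design; it
targets the sharp-edged contamination that masquerades as spikes.

## Spike extraction

Filtering is a 250 Hz, 4-pole Butterworth applied forward-only: causal
filtering matches online detection behaviour and is verified by truncation
equivalence (output at t depends only on samples ≤ t).  Detection uses a
negative threshold at −5 × the robust noise SD (median |x| / 0.6745).  A
4 × multiplier is common practice but produces multi-hertz false-positive
rates on Gaussian-like background at 30 kHz bandwidth; 5 × keeps false
positives below 0.02 Hz on the synthetic background while retaining ~100%
sensitivity at SNR ≥ 8.  The multiplier is configurable.  Events align to
the trough within 1 ms after the crossing and are censored within 1 ms.

Waveforms are 48 samples with 8 prethreshold samples (1.6 ms / 0.267 ms at
30 kHz).  Features are energy (Σx²), nonlinear (Teager–Kaiser) energy, and
principal-component scores.  Automated invalidation replaces manual
curation: events whose energy or nonlinear energy exceed the median +
5 × IQR, or which fall within ±1 ms of a known artifact peak, are labelled
invalid (unit 0).  Principal components are recomputed on the surviving
waveforms after sub-sample trough alignment (parabolic fit + linear
resampling) — without this, ±0.5-sample phase jitter dominates the PC space
of narrow waveforms and fragments single units.  k-means with k ∈ 1..4 is
selected by silhouette, accepting a multi-cluster solution only above 0.5.

Cell-type heuristic: TAN if the mean rate lies in 2–12 Hz and the
trough-to-peak width exceeds 0.4 ms (tonically active neurons are broad and
regular); MSN if the rate is below 1 Hz and more than 10% of ISIs are under
10 ms (sparse, bursting); otherwise "other".  These thresholds are
heuristics for the qualitative firing descriptions, exposed in the API.

## Dopamine chemometrics

Frames are background-subtracted against a reference scan (typically an
alignment event).  The standards model is uncentered principal-component
regression: per analyte class (dopamine, pH, movement artifact) an
uncentered SVD retains components to 99% of class variance, and the class
subspaces are merged into one orthonormal basis.  Per-class retention
matters because movement artifacts dwarf dopamine currents — a pooled PCA
reaches 99% variance before the dopamine direction is included.  Uncentered
projection makes a zero ΔI frame read exactly 0 nM with zero residual.  The
calibration regresses known dopamine concentration on the scores over all
standards through the origin; interferent rows enter at 0 nM, which
orthogonalises the readout against pH and movement score directions
(cross-talk on a pure pH frame is below 1%).

Nulling: Q is the squared residual outside the basis; Q_α defaults to the
95th percentile of leave-one-out training residuals (each standard projected
onto the subspace fit without it), because in-sample residuals are overfit
and understate out-of-sample noise.  A small positive floor keeps Q_α valid
for exactly-spanned training sets.  Frames correlating with any stored
movement template at Pearson r > 0.8 are nulled with reason
`movement_corr` (checked before Q, since movement shapes lie inside the
basis).  Nulled frames propagate as explicit missing values (NaN) through
trial averaging — never as zeros.

The within-scan digitisation is 850 points per 8.5 ms frame (an assumed
100 kHz sampling of the sweep), configurable.  The synthetic dopamine
standard places oxidation near +0.6 V on the anodic sweep and reduction near
−0.2 V on the cathodic sweep, with a nominal carbon-fiber sensitivity of
0.02 nA/nM.

## Synthetic data

The generator defines the study conditions for every validation claim.
Background noise is white (15 µV SD) plus spectrally-shaped 1/f pink noise
(10 µV SD) — plausible extracellular magnitudes; line noise is optional
(sine + harmonics, or sawtooth for the 60 Hz-removal tests).  Spike
templates are biphasic and trough-dominant over 1.6 ms, trough-to-peak
0.25 ms (MSN) vs 0.55 ms (TAN), amplitude 150 µV by default.  Spike trains
are inhomogeneous-Poisson draws (thinning) against piecewise-constant rate
functions with 1 ms refractory censoring: MSN defaults are 0.3 Hz with
~60 ms event-locked bursts; TAN defaults are 5 Hz with a 200 ms cue pause
followed by a 200 ms rebound.

Artifact morphologies:

* **R** — symmetric triangle spanning the 8.5 ms scan (amplitude 500 µV
  default);
* **RC** — the triangle convolved with a causal exponential,
  τ = 2 ms, truncated at 4τ (support ≈ 16.5 ms) — the decaying tail of
  resistive-capacitive coupling;
* **RAIL** — the triangle scaled to saturate and clipped at the ±1 mV
  input range, followed by an amplifier-recovery segment: an underdamped
  settle modelled as a 1.2 kHz ring decaying with τ = 2 ms over 4.5τ
  (support ≈ 17.5 ms).  Saturation recovery is modelled as ringing because
  a released, slew-limited input does not settle smoothly; this places
  genuine spike-band energy beyond any fixed interpolation window, which is
  the stated reason rail artifacts recover worst.

Supports are strictly ordered R < RC < RAIL.  Injection adds the same
template to every channel (coherence is what step 1 of the detector
exploits; per-channel gains are configurable) and re-clips the sum at the
rail for RAIL.

## Validation design

Reference spikes come from running the spike pipeline on the clean
recording (the published design), with a ground-truth mode for synthetic
inputs.  After injection and cleaning, a reference spike counts as
recovered if a test event matches within 0.5 ms (greedy one-to-one nearest
matching, verified equal to optimal assignment on small instances) *and*
its raw voltage snippet correlates with the same spike's pre-injection
snippet at r ≥ 0.98.  The fidelity screen is the automated analogue of a
manual sorter rejecting artifact-distorted waveforms; it is exact rather
than statistical because samples outside the interpolated windows are
bit-identical after cleaning (r = 1 exactly), so only spikes genuinely
touched by interpolation boundaries or residual artifact tails fail.

Across morphologies the comparison is paired: each kind's scan phase is
offset by its template's deterministic detection latency (computed by
running the detection chain on the isolated template) so the interpolated
windows coincide, and per-kind differences isolate residual-artifact
physics rather than which random subset of spikes each kind's windows
happened to cover.

Default experiment: three sessions × five channels × 45 s of 5 Hz Poisson
spiking (≈ 3300 reference spikes), sized so binomial uncertainty on each
per-kind mean is ≈ 0.5 percentage points.  Typical measured recoveries are
≈ 87% (R), ≈ 87% (RC) and ≈ 83% (rail), grand mean ≈ 86% — the R value
sits at the 100 − 12% interpolation bound, and the ordering
rail ≤ RC ≤ R is reproduced.

**What the synthetic validation does not show.**  The generator's spikes
are stationary Poisson with fixed templates; real recordings add drift,
bursting non-stationarity, overlapping units and artifact shape variability
across scans.  Recovery percentages on real data therefore need not match
the synthetic values — the synthetic experiment establishes the pipeline's
mechanics (geometry of the interpolation budget, completeness of detection,
morphology ordering), not an in-vivo performance claim.

## Task alignment

Synthetic trials follow the eye-movement reward task: central cue (C),
1.6 s fixation, peripheral target (T) left or right, 4 s fixation, reward
(RW) large or small, with the direction↔size mapping switched every 20–30
trials.  Spike alignment bins at 50 ms (a conventional peri-event
resolution; [ΔDA] is inherently 100 ms-binned).  Averages report mean ± SE
across trials; nulled dopamine scans are excluded from the mean's
denominator.  Statistical testing is limited to two-sided permutation tests
on window means — the minimal assumption-free test for condition
differences.

## Numerical conventions

Times are seconds from `t0`; sample indices are 0-based; interpolation
windows are closed on both ends in sample space; samples are float32 µV on
disk (float64 in memory); all random draws flow from explicit integer seeds
through `numpy.random.default_rng`, and multi-part experiments split seeds
via `numpy.random.SeedSequence`.  Known limitations: single-channel spike
sorting only (no probe-geometry template matching or drift correction), no
electrochemical physics beyond linear analyte superposition, and no reader
for proprietary acquisition formats (the HDF5/CSV container is the exchange
surface).
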