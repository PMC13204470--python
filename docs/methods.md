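# Methods

This note documents the models implemented in `scgpipe`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical conventions. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic seismocardiogram generator (`synth`)

**Beat model.** There is no accepted closed-form equation for an SCG
beat; the generator uses a Gabor-wavelet superposition because it is
band-limited by construction, lives naturally in the 1–25 Hz range where
SCG energy concentrates, and makes every fiducial event's latency and
signed amplitude exact ground truth. Each event contributes
`A·exp(−(t−L)²/2w²)·cos(2πf(t−L))`; the cosine phase is locked to the
envelope peak so the trace passes through `A` exactly at `L`.

**Default morphology.** The six events span 0.06–0.41 s after beat
onset with AO (aortic valve opening) the dominant positive systolic
peak, IM and IC flanking it as troughs, and a smaller AC/MO diastolic
complex — the canonical ordering of sternal SCG recordings. Carrier
frequencies (8–13 Hz) and envelope widths (16–20 ms) were chosen
together so that (a) ≳90% of a session's spectral energy falls inside
1–20 Hz and (b) each wavelet's largest carrier side-lobe stays below 6%
of its main lobe, which keeps peak/trough-based fiducial detection
unambiguous. All latencies, amplitudes, widths and frequencies are
overridable per event.

**Sessions.** Beats are placed at onsets with RR = 60/HR plus Gaussian
jitter clipped at ±3 SD and floored at RR ≥ 0.3 s. Respiration
multiplies beat amplitudes by `1 + depth·sin(2π f_resp t)` with
defaults 0.25 Hz and depth 0.2; breath-hold forces depth 0. Heart-rate
defaults follow the two observed cycle lengths: 60 bpm for breath-hold
(≈1 s cycles) and 75 bpm at rest (≈0.8 s cycles). Office artifacts are
synthesized directly in the 0.5–2 Hz Fourier band (energy confined to
the band by construction); walking adds a Gaussian step-transient train
(σ = 80 ms) at 2 steps/s, mean-removed so the fundamental dominates.

**Planted blood-pressure mapping.** The real label source (a cuff
sphygmomanometer) is a black box, so the generator plants a documented,
learnable relation instead: the SBP class scales the AO wavelet
amplitude (factors 0.75/1.0/1.25 for classes 0/1/2) and the DBP class
scales the mean heart rate (factors 0.85/1.0/1.15). The AO-specific
amplitude effect is deliberate: per-window normalization removes any
global gain, so only a *relative* morphology change is recoverable
downstream — planting the effect on one event keeps the mapping
learnable under normalization. SBP/DBP values are drawn from truncated
normals confined to the clinical bins. Both effect sizes are
configurable; zero-effect mappings give the exact null (sessions
unchanged). Sessions carrying their protocol are regenerated with the
planted parameters; detached waveforms fall back to global amplitude
scaling plus uniform time compression.

**Seeding.** One master integer seed; per-session and per-record
sub-streams are derived with `np.random.default_rng([seed, index])`, so
datasets are reproducible element-wise and insensitive to generation
order.

## Sensor and front-end digital twin (`forward_model`)

**Static response.** Piecewise sensitivity with slope 3.76 V/N on
0–0.2 N and 0.10 V/N above 0.6 N; only the two end slopes are known, so
the 0.2–0.6 N knee interpolates the *slope* linearly (voltage is
quadratic there), giving a C¹, monotone map.

**Dynamics.** An asymmetric first-order tracker whose rise and fall
time constants are set from the calibrated 10–90% step times via
τ = t/ln 9 (0.02 s rise, 0.06 s fall). Only the step times are known,
not the underlying order; first-order is the minimal model reproducing
both. A consequence worth stating: a first-order system with a 20 ms
rise time has ≈17.5 Hz bandwidth, so the dynamic model cannot
simultaneously be flat to 25 Hz — the sensor's nominal 0.5–25 Hz band
and its step times are mutually inconsistent for any first-order model,
and the step times (directly measured quantities) take precedence here.
In-band flatness is asserted for the analog chain instead.

**Operating point.** The chest strap preloads the sensor; the forward
simulation adds a 0.15 N static preload (middle of the high-sensitivity
range) to the signed vibration trace and saturates at zero force (loss
of contact). The sensor is modeled as a voltage source followed by the
transimpedance stage's single pole (796 Hz from 10 MΩ ∥ 20 pF) — a
phenomenological stand-in for the contact-separation charge cycle that
avoids an unknowable electrostatic model.

**Analog chain.** Causal discrete-time stages in hardware order:
optional additive 50 Hz mains pickup, transimpedance pole, third-order
Butterworth low-pass at 33.9 Hz, gain, 50 Hz notch, first-order
high-pass at 0.8 Hz, mid-scale offset. Each stage is pre-settled to its
DC steady state for the input's first sample (a worn, powered-on device
has no power-up transient). Unstated hardware values were fixed as:
gain 0.4 (a 0.2 N static beat peak lands near 60% of full scale), notch
quality factor 10 (narrow enough to spare the 1–20 Hz band), ADC full
scale 3.0 V (a 12-bit converter quoted at 0.732 mV/code implies
0.732 mV × 4096 = 3.0 V; the 3.3 V logic rail is the documented
alternative, giving 0.806 mV). When the chain runs at 1000 Hz the
796 Hz transimpedance pole lies above Nyquist and is skipped — its
in-band effect is below 0.01 dB.

**ADC.** Anti-aliased polyphase resampling to 1000 Hz, clipping to the
representable range [0, (2¹²−1)·LSB] and rounding to the nearest code,
so quantization error is ≤ LSB/2 everywhere; clipped-sample counts are
metadata, not errors.

**Characterization.** Filter corners and notch center are measured the
way a bench engineer would: swept sines, steady-state amplitude by
single-bin DFT over whole periods, −3 dB crossings interpolated in
(log f, dB). Simulated at 4 kHz so the 33.9 Hz corner and step times
are resolved well below their tolerances.

## Beat pipeline (`beat_pipeline`)

All offline filtering is zero-phase (forward–backward), unlike the
causal front end: the analysis stage works on recorded windows and
should not add group delay to fiducial timings.

- **Enhancement band 5–25 Hz** (4th-order Butterworth): inside the SCG
  energy band while rejecting respiration and posture drift.
- **RMS window 100 ms**: merges intra-beat oscillations into one energy
  lobe per beat yet separates beats at 100 bpm. Centered, reflective
  edges.
- **Peak detection**: minimum RR 0.4 s (≤150 bpm); height threshold
  0.3 × the median height of *major* candidate peaks (those above 20%
  of the envelope maximum). The restriction to major peaks matters at
  low heart rates, where inter-beat ripple peaks outnumber beat peaks
  and a plain median would collapse to the ripple level.
- **Segmentation window [−0.1, +0.5] s** around the envelope-peak
  anchor; out-of-bounds beats are dropped and counted; windows wider
  than the shortest RR warn (overlap) rather than fail.
- **Template**: one alignment pass against the provisional mean
  (cross-correlation, shift search ±30 ms), then average with
  per-sample SD.
- **Fiducial rules** (a documented convention — the literature fixes
  the event order, not a detection algorithm): AO = largest positive
  peak in the systolic search window, IM = most negative preceding
  trough, MC = nearest preceding positive peak, IC = first following
  trough, AC = largest positive peak in the diastolic window, MO =
  first trough after AC. Extrema below 10% of the template's absolute
  maximum are treated as ripple. Default search windows (0–0.25 s and
  0.25–0.5 s) assume an onset-anchored template; envelope-anchored
  templates center AO near zero and need shifted windows (see
  `examples/03_beat_detection.py`). Unfound events are flagged, never
  zeroed, and the returned set always satisfies the strict MC < IM <
  AO < IC < AC < MO ordering.

## Quality screening and features (`quality_features`)

Windows are the exact 45 s preceding each cuff measurement. The SQI is
a reconstruction (its original definition is not public): the equally
weighted geometric mean of (i) mean beat-vs-template Pearson
correlation (clipped to [0, 1]), (ii) RR regularity `exp(−CV(RR)/c)`,
and (iii) amplitude stability `exp(−CV(p2p)/c)`, with c = 0.5. The
geometric mean makes any collapsed sub-score decisive; c = 0.5 places a
clean jittered resting window (CV(RR) ≈ 0.025, respiration-driven
CV(p2p) ≈ 0.14) comfortably above the 0.7 threshold while unstructured
noise falls below it. Fewer than three detected beats yields SQI 0.
The threshold itself stays at 0.7.

Per-beat features (RMS, peak-to-peak, maximum upstroke slope computed
on the band-passed segments) enter the fixed-length vector as mean and
SD; template amplitudes are linearly interpolated at 0.1/0.2/0.3/0.4 s
after the beat anchor. Normalization (zero mean, unit SD per window)
precedes beat detection by default; both orderings are supported via
`PipelineConfig.normalize_first`.

## Blood-pressure classifier (`bp_classifier`)

From-scratch multinomial logistic regression: L2-regularized multinomial
cross-entropy minimized by full-batch gradient descent from zero
initialization (deterministic), with the step size halved whenever a
step would increase the objective — so the loss history is
non-increasing by construction. Defaults: λ = 10⁻³, learning rate 0.1,
≤5000 iterations, loss-change tolerance 10⁻⁸. Features are standardized
on the training partition only (the parameters travel with the model) to
avoid leakage. The split is stratified by class — "random" alone could
drop a class from one partition at these sample sizes. Bin edges at
exactly 120/135 (SBP) and 80/85 mmHg (DBP) are assigned to the middle
class; the printed bins are ambiguous at the edges and this convention
is applied consistently in the generator and the classifier. ROC curves
are one-vs-rest threshold sweeps with trapezoid AUC.

## What the synthetic data does not show

The generator emulates timing structure, morphology, respiration
modulation, activity artifacts and a documented label mapping. It does
not emulate inter-subject morphology variability, sensor placement and
coupling differences, posture changes, arrhythmias, or any physiological
BP–SCG relation — the planted mapping is an engineered stand-in. Pipeline
and classifier results on synthetic data therefore validate the
*implementation* (each stage recovers what the generator planted at
realistic noise levels); they are explicitly not a reproduction of
accuracies measured on human recordings, which depend on data that is
not public.

## Problem sizes and numerical conventions

Sessions used in tests and the acceptance script are 40–60 s at
1000 Hz; swept-sine characterizations run at 4 kHz; the default
synthetic BP study uses 300 sessions of 55 s with a stratified 30%
test split. Time is float seconds throughout; artifacts are plain CSV
and JSON so every output can be inspected and round-trips losslessly
through its reader. Filters are SOS cascades (numerically robust at
1000 Hz for sub-hertz corners); the quantizer rounds half away from
zero via `np.round`; degenerate inputs (constant windows, flat
templates, zero-variance correlations, <2 beats) raise or flag rather
than propagate NaNs.
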