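# Methods

This note records the models, parameter choices and numerical decisions
behind `lfpclean`, and what the synthetic-data tests do and do not show
about real recordings.

## Signal model

A contaminated LFP channel is modeled as

    y(t) = s(t) + q(t) + a(t) + e(t)

where `s` is the neural signal (aperiodic background plus narrowband
oscillations), `q` a quasi-periodic cardiac QRS artifact train, `a`
occasional high-amplitude transients, and `e` digitization noise.  The
pipeline removes `q` in the time domain, excises the spectral footprint of
`a` by window rejection, and separates the aperiodic part of `s` by model
fitting.  The stage order is fixed: a transient's spectral footprint is
broadband, so time-domain removal must precede any transform, and
transient-bearing windows must be rejected before the aperiodic fit, which
is an average-based estimator that a single high-power window can skew.

## ECG template subtraction

* **Detection band 5–30 Hz**, 4th-order Butterworth applied
  forward–backward.  Zero-phase filtering is essential: the apex found on
  the filtered trace must line up (within a sample or two) with the apex
  in the raw trace where subtraction happens.
* **Dynamic threshold** 2.5 × SD of the filtered segment (whole-segment
  SD, not a sliding window or a robust scale — the plain SD tracks the
  segment's overall amplitude, which is the intent of a dynamic
  threshold).  Minimum peak spacing `60/max_heart_rate` seconds with a
  120 bpm default.  Peaks within one minimum-spacing of either trace edge
  are discarded (their prominence neighborhoods are incomplete).
* **Polarity** is decided by running detection on the trace and its
  negation and keeping the polarity whose detected peaks have the larger
  *mean prominence* (ties → positive).  Event count does not work as a
  criterion: a biphasic complex yields one above-threshold peak per beat
  in either polarity (the apex, or the opposite-signed Q/S lobes), so
  counts are a coin flip, while the true apex's prominence towers over the
  lobes' in both the upright and the inverted case.
* **Artifact-presence gate.**  Band-limited Gaussian background alone
  produces ~80 above-threshold detections per minute (oscillatory noise
  peaks are prominent), and subtracting their peak-triggered average would
  bias the 5–30 Hz spectrum downward.  A QRS train, being a spike process,
  makes the bandpassed amplitude distribution leptokurtic; removal
  therefore only engages when the sample kurtosis of the bandpassed trace
  is ≥ 3.65.  Measured on the generator's study conditions: artifact-free
  noise ≤ 3.13, residue after a successful subtraction ≤ 3.59, QRS at 4 ×
  the background SD ≥ 3.77.  The gate also makes cleaning idempotent.  On
  real data the gate plays the role of the visual "is a QRS observable?"
  judgment; heavy-tailed non-cardiac artifacts could open it, which is why
  it is a parameter (`kurtosis_min`).
* **Template**: mean of raw-signal windows, 36 samples on each side of the
  apex (minimum 18 before / 36 after to capture Q and S; the symmetric
  choice keeps the Hanning taper from attenuating the R wave
  asymmetrically).  At least 10 usable events are required — below that
  the average does not meaningfully suppress background.  Boundary events
  are skipped, never truncated: a truncated taper would not end at zero.
  The taper leaves ~12 % of the Q/S lobes in place (the Hanning window is
  below 1 there); this residue is visible as a small leftover kurtosis but
  is spectrally negligible.
* **Bilateral transfer**: events from the channel with the larger mean
  detected prominence are re-used on both channels (cardiac artifacts are
  time-locked across hemispheres); each channel averages its *own* windows
  at those times, so no cross-channel amplitude assumption is made.
  Events are not re-aligned per channel.  With mixed stimulation
  annotation, events are split by state and a template is built per state,
  since artifact amplitude can differ between stimulation on and off.

## Spectral estimation

* Resolution arithmetic is exposed directly: `min_frequency = fs/N`,
  `fft_resolution = fs/nfft`, `hanning_halfbandwidth = 2·fs/nfft`,
  `n_tapers = floor(2·T·W) − 1`.
* `nfft` defaults to the next power of two ≥ the window length.  Zero
  padding is magnitude-neutral (padding placement shifts phase only), so
  the Welch implementation delegates to `scipy.signal.welch`.
* The multitaper estimator averages per-taper periodograms with equal
  weights (no adaptive weighting), and per-segment estimates with the same
  segmentation as Welch, so with rejection disabled the spectrogram mean
  equals the plain multitaper PSD exactly.
* Default multitaper half-bandwidth: the Hanning half-bandwidth of the
  same window, floored at 1 Hz.  For long windows the Hanning smoothing
  falls below 1 Hz, which neural spectra rarely warrant; holding W at 1 Hz
  converts the extra length into tapers, i.e. variance reduction.
* dB is `10·log10(power)`; all model fitting happens in log10-power units
  and dB is display-only.  The DC bin is kept in every grid but excluded
  from fits.

## Window rejection

* Working configuration: 2 s windows, 50 % overlap, W = 1 Hz → 3 tapers.
* Correlation filter: each window's mean Pearson correlation (dB scale,
  4–75 Hz) with the other windows, **Fisher z-transformed** before
  z-scoring.  Correlations near 1 are strongly left-skewed; without
  `arctanh` the Grubbs family-wise false-alarm rate on clean data measured
  ~0.20 instead of the designed ~0.05.  The transform is monotone, so
  which window is most extreme never changes.
* Power filter: mean dB power over 0–5.3 Hz, two-sided (both "too quiet"
  and "too loud" windows are suspect).
* Both filters are single-pass (one threshold application, no iterative
  re-testing) and are combined by the union of their rejection sets,
  each computed on the full window set.  z-scores use the sample SD
  (ddof = 1), matching the Grubbs critical-value derivation; the t
  critical value is the upper-tail quantile at `α/(2N)`, `g = t²`.
* Known limitation (inherent to single-pass Grubbs): masking.  When a
  quarter or more of the windows are contaminated, the outliers inflate
  the scale estimate and the statistic saturates below threshold.  The
  guarantees are therefore stated for a contaminated *minority* (1–3 of
  30 windows).
* Survivors are averaged in **linear power** (an average of power
  estimates is itself a power estimate; dB averaging would bias low) and
  converted to dB for display.
* PCA background: windows' dB spectra over 4–75 Hz are centered by their
  own means, and the first right-singular vector of the resulting matrix
  — **uncentered** across windows — is the background estimate, sign-
  oriented to correlate positively with the mean spectrum and
  least-squares mapped (scale + shift) onto it.  Uncentered PCA is the
  point: every window carries the common background shape coherently, so
  it dominates the second moment, while contamination confined to a few
  windows falls into later components.  Centering across windows would
  promote exactly those deviations to PC1.  Bins outside the band are
  filled from the mean spectrum.

## Aperiodic detrending

* Model: `model(f) = b − log10(k + f^x)` in log10-power units; bounded
  least squares with `k ∈ [0, 10³]`, `x ∈ [0, 10]`, initialized at
  `x = 1, k = 0, b = median(log10 power)`.
* Two passes: the broadband (4–75 Hz) fit is pulled upward by periodic
  peaks; the second pass re-fits on 55–75 Hz (above the slow-gamma band,
  inside the broadband range) plus ±1-bin neighborhoods of the initial
  residual's minima.
* The minima search engages only when the lightly smoothed initial
  residual rises ≥ 0.15 log10 units (1.5 dB) above the fit somewhere in
  band — evidence that there are peaks to correct for.  On a peak-free
  stochastic spectrum the residual's troughs are estimation noise, and
  the heavy left tail of log chi-square power makes some of them
  arbitrarily "prominent"; anchoring to those below-average bins would
  drag the second pass low.  With no minima the refined pass falls back
  to the initial fit (nothing to correct, and the high band alone cannot
  identify the knee: for `k ≤ 10` its influence at 55–75 Hz is ~10⁻³
  log10 units).
* Identifiability: `k` is weakly identified when the knee frequency
  `k^(1/x)` sits near or below the low edge of the fit band, and estimator
  smoothing at the knee biases it low; parameter-recovery guarantees are
  therefore ±15 % for `x` and `b` but only ±50 % for `k`.  Fine-resolution
  estimators (e.g. 8 s windows) recover `k = 5` to a few percent where 2 s
  multitaper smoothing leaves a ~12 % bias.
* Only the aperiodic component is parameterized; the residual *is* the
  periodic estimate (no Gaussian peak modeling, no knee/fixed model
  selection).

## Synthetic-data generator

The generator defines the study conditions all guarantees are stated
under: 250 Hz sampling, 60 s records, a background with knee 2, exponent
1.5 and offset 1.0 log10(µV²/Hz) (broadband SD ≈ 4.4 µV — a plausible
thalamic bipolar magnitude), one 20 Hz beta oscillation of 2 µV RMS, and a
QRS train at 70 bpm with ±3 % uniform inter-beat jitter, amplitude 20 µV
at the apex, hemispheric scales (1.0, 0.3).

* Background synthesis is frequency-domain amplitude shaping: the target
  one-sided density `10^(b − log10(k + f^x))` imposed on uniform random
  phases, DC forced to zero.  This gives *direct* control of the aperiodic
  parameters for recovery tests (an AR approximation would add its own
  model error).  An `offset = −inf` is the guarded zero-amplitude case.
* Oscillations are band-filtered Gaussian noise scaled to a requested RMS
  — deliberately not sinusoids, which would make PSD-peak tests trivially
  easy.
* The QRS complex is three Gaussian-windowed deflections (Q −0.22, R +1,
  S −0.32 of the apex, widths 12/11/14 ms) spanning ~55 samples at
  250 Hz, i.e. filling the detection stage's minimum capture window; any
  biphasic spike with a dominant apex would do for testing
  detection/subtraction.  Events are time-locked across channels; per-
  channel scale, polarity, and an optional stimulation-state scale apply.
* Transients: "ied" is a sharp spike plus slow wave, Hanning-gated;
  "stim_edge" is an exponentially decaying step.  Both are low-frequency-
  heavy, which is what the 0–5.3 Hz filter targets.  Transients are
  shared across channels.
* Quantization is round-to-nearest with step 0 (off) by default; the
  recordings this mimics are already hardware-quantized and the effect on
  every stage is far below the other noise terms.
* Everything is seeded (`numpy` `SeedSequence` spawning per component);
  the contaminated trace equals the sum of the annotated components
  exactly, pre-quantization.

**What the synthetic tests do not show.**  The background is Gaussian and
stationary; real LFPs drift, contain line interference, and have
non-Gaussian neural transients that could open the kurtosis gate or evade
the low-frequency filter.  QRS morphology is fixed per recording, so the
tests do not probe beat-to-beat morphology variation (ectopy), and the
P/T waves — unreliable to extract even visually on this kind of data —
are not synthesized or removed.  Guarantees about detection
(recall/precision ≥ 0.95) hold for apexes at ≥ 4 × the background's
broadband SD; weaker artifacts are still reduced via bilateral transfer
but their detection is not guaranteed.

## Problem sizes used in the test suite

Tests run at the smallest sizes at which the statistical claims are
meaningful: 31–60 s records for detection/rejection properties
(30–59 spectrogram windows), 100 Monte-Carlo replicates for probability
bounds, 300 s records for aperiodic parameter recovery (where knee
identifiability needs a long, finely resolved spectrum), and 2–20 seeds
for seed-averaged quantities.
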