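# Methods

## Encoding model and deconvolution

The package models continuous-stimulus EEG as the output of a linear
time-invariant system whose input is a nonlinearly transformed stimulus
(the regressor) and whose impulse response is the evoked response.  With
per-trial FFTs `X_n` (regressor) and `Y_n` (EEG), the estimator is

    response = IFFT( Σ_n b_n X_n* Y_n  /  (1/N) Σ_n X_n* X_n )

with inverse-variance weights `b_n = (1/σ_n²)/Σ_m(1/σ_m²)`.  The weighted
numerator over an *unweighted* mean denominator is implemented exactly in
that form (a fully weighted least-squares form would also be defensible;
fidelity to the estimator as stated wins).  σ_n² is the variance of the
filtered single-channel trial over its full duration, computed after all
subcortical filtering.

The FFT length equals the trial length — no padding — so the estimate is
circular: lags near the trial end are negative lags.  `unwrap_circular`
re-indexes the axis to [−T/2, T/2) and crops to the analysis window
(default [−200, 600] ms).  With uniform weights and a single (or
equal-variance) trial set, the estimator coincides with circular
least-squares; the test suite checks this against a brute-force circulant
design matrix at trial lengths ≤ 256 samples to 1e−8.  With unequal
inverse-variance weights the weighted-numerator/unweighted-denominator
form is slightly biased per bin, which is visible only at very high SNR.

Near-null regressor spectrum bins (half-wave-rectified audio has little
very-low-frequency energy) are floored at 1e−10 of the maximum denominator
bin; a warning is raised when more than 1% of bins hit the floor.

Two regressor polarities (original and sign-inverted stimulus) are
deconvolved separately and averaged.  In real recordings this cancels the
electrical stimulus artifact, which flips with polarity while the neural
response does not.  The periphery model's intrinsic latency is measured as
the cross-correlation peak between a click and the summed model output and
the deconvolved response is shifted right by that lag.

## Regressors

**HWR.**  `max(x, 0)` and `max(−x, 0)`, each anti-alias downsampled to the
EEG rate (10 kHz).  Polyphase resampling can ring slightly below zero;
outputs are clipped at 0.

**ANM.**  The stimulus is upsampled to the model rate (100 kHz default),
scaled so its RMS corresponds to the target sound level (65 dB SPL ⇒ RMS =
20 µPa · 10^(65/20) ≈ 35.6 mPa), run through the periphery model at each
characteristic frequency (CF) of a 1/6-octave grid from 125 Hz to 16 kHz
(both endpoints included, 43 CFs), summed over CFs without fiber-count
weighting, and downsampled.  The periphery backend is a pluggable
contract:

* `ZilanyPeriphery` adapts the published Zilany et al. model when its
  Python port (`cochlea`) is importable, high-spontaneous-rate fibers only.
* `SimplePeriphery` is this package's own phenomenological model, used by
  default: a 4th-order all-pole gammatone filterbank (Glasberg–Moore ERB
  bandwidths × 1.019), a rectifying compressive transduction
  `log1p(c·max(v,0))` (rate saturation), a 2nd-order 3 kHz low-pass (IHC
  membrane), divisive adaptation (drive divided by `1 + k·s` with `s` the
  drive smoothed over 60 ms; onset overshoot and post-onset suppression),
  a 0.7 ms synaptic delay and a 50 sp/s spontaneous floor.

The built-in model reproduces the *qualitative* nonlinearities that matter
for the paradigm (tuning, compression, adaptation, synchrony) but not the
reference model's exact latency structure: its summed click response peaks
near 1.7 ms, whereas the full published model — with its chirp filters and
detailed synapse — measures 2.75 ms.  Analyses that depend on the absolute
lag value should use the reference backend.

## Stimulus preparation

* Stereo is averaged to mono; resampling is polyphase and anti-aliased.
* Music-like material is flattened by its slow envelope:
  `x / (e + 0.1·σ_e)` where `e` is the 0.1 Hz-low-passed magnitude of the
  analytic signal (the envelope extractor is this package's choice) and
  the `0.1·σ_e` term guards against division by near-zeros.  The guard
  makes the operation idempotent only up to a scale and a residual of the
  order of the modulation depth squared.
* Silent stretches strictly longer than 0.5 s are excised.  The amplitude
  criterion (not dictated by the recipe itself) is an envelope — the 40 Hz
  smoothed absolute waveform — below 1% of the trial RMS; configurable.
* Spectral matching splits each trial into third-octave bands (6th-order
  Butterworth, applied zero-phase so that the band sum reconstructs the
  input), then rescales band k of trial n by `sqrt(P̄_k / P_{n,k})`.
  Bands at less than 1e−8 of the trial's strongest band are refused — the
  rescale would amplify noise by > 10^4.
* Band construction: the range [fmin, fmax] rarely spans an integer number
  of third-octaves, so the geometric ladder of interior edges (exact ratio
  2^(1/3)) is centred in the range and the leftover bandwidth is split
  equally between two truncated end bands.  The count is
  `floor(3·log2(fmax/fmin)) + 2` (or exactly `3·log2(fmax/fmin)` when that
  is an integer): 28 bands for 50–22,050 Hz, 3 for one octave.
* Envelope statistics: the broadband envelope is the 40 Hz-low-passed
  half-wave-rectified waveform; its marginal density is a normalized
  histogram.  Speech-like material puts the mode at zero (silences);
  music-like material puts it strictly above zero.

## EEG preprocessing

Subcortical path (causal throughout, so early latencies are not smeared
backwards): clock-drift correction, 1 Hz first-order Butterworth
high-pass, second-order IIR notches at 60, 120 and 300 Hz with 5 Hz −3 dB
width (exactly those three, not every multiple), then averaging of the two
earlobe-referenced channels.  Clock drift is estimated from two triggers:
the true sampling rate is the sample count between the start trigger and a
drift trigger stamped 20 ms before stimulus end, divided by the known
offset (11.98 s for a 12 s stimulus); the trial is then resampled to the
nominal rate.

Cortical TRF path: 0.5–30 Hz band-pass with a zero-phase Hamming-window
FIR (order ≈ 3.3/Δf at a transition width of half the high-pass corner —
the source recipe does not state the FIR design; symmetric taps applied
once centre-aligned, which is exactly zero phase), downsampling to 125 Hz,
first second of each epoch dropped.  Cortical deconvolution path: same
filters as subcortical but with a 0.1 Hz high-pass, no downsampling, so
brainstem and cortical components share one lag axis.

## Temporal response function

Per channel, EEG is regressed on lagged copies of the regressor (lags
[−50, 400] ms rounded outward to whole samples at 125 Hz, zero-padded at
epoch edges) with an L2 penalty.  The penalty is selected from a
logarithmic grid 1e−2…1e6 by out-of-fold prediction correlation, averaged
over channels, in a 10-fold split over trials; the model is refit on all
trials at the winner.  The source recipe mentions both "leave-one-out" and
"10 folds"; this implementation uses k-fold over trials with k = 10 by
default and leaves the discrepancy visible here rather than resolving it
silently.  At λ = 0 the solution equals the normal equations (tested);
prediction correlation is invariant to channel-wise scaling, so no
channel normalization is applied.

## Synthetic data

`simulate_eeg` drives every channel with the circular convolution of a
planted kernel and the per-trial regressor, plus independent 1/f noise
(exponent 1) with per-trial variance drawn uniformly from 1–10 (µV)², plus
a common mains component at 60/120/300 Hz (1/0.3/0.1 µV).  The planted
kernel is a sum of Gaussian bumps near 3.5, 5.5 and 8 ms plus slow
deflections near 50/100/150 ms — fixtures echoing typical component
latencies, not physiological claims.  The clean-signal RMS default is 5 µV,
calibrated once so that the full pipeline recovers the planted kernel at
r ≈ 0.96 from 40 twelve-second trials; the corresponding response SNR
(~10 dB) is in the range reported for real continuous-stimulus ABRs,
though per-trial SNR is considerably more favourable than raw EEG.

Recovery is always measured against the planted kernel *passed through the
same preprocessing filters*: the notches remove kernel content at the
mains bins from the data, so that content is unrecoverable by construction
and comparing against the raw kernel would conflate filter design with
estimator quality.  The synthetic EEG is driven by the positive-polarity
regressor only and deconvolved with the same regressor; the two-polarity
averaging step is exercised separately on constructed responses, because a
single-kernel forward model driven by one polarity is not faithfully
inverted by the average of both.

Stimulus surrogates: "music-like" is a three-partial harmonic complex with
slow sinusoidal amplitude modulation (depth 0.3) over weak noise;
"speech-like" is Hanning-gated Gaussian noise bursts (80–250 ms) at a
syllabic rate with hard gaps and occasional pauses longer than 0.5 s, with
gamma-distributed burst amplitudes.  These reproduce the envelope-density
contrast (non-zero vs zero mode) and first-order temporal statistics, but
none of the harmonic structure, co-modulation, or long-range dependencies
of real music and speech — so passing tests demonstrate correctness of the
estimator chain under the model's assumptions, not performance on real
recordings.  All generators are deterministic under a fixed seed.

## Numerical choices and limitations

* Deconvolution regularization floor 1e−10 of the peak denominator bin;
  unwrap before crop preserves energy exactly (pure re-indexing).
* Lag compensation may be applied once; a second application raises.
* SNR is undefined (flagged, not clamped) when the baseline variance
  exceeds the signal-window variance.
* The split-set correlation uses 100 random class-balanced splits (count
  not fixed by the source recipe) and reports the full distribution.
* Coherence slices are non-overlapping and rectangular; the mismatched
  noise floor excludes identity pairings by construction.
* The wave-V picker (largest local maximum in 5–11 ms) is a stand-in for
  manual peak picking and should not be trusted on low-SNR responses —
  pure noise will still contain local maxima.
* Prediction correlations are computed per trial; multichannel subcortical
  source modelling, artifact rejection/ICA and hearing-loss periphery
  parameterizations are out of scope.
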