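# contabr

Auditory brainstem and cortical responses to **continuous natural stimuli**
(music, speech) derived from EEG by regressor-based deconvolution.

Classically the auditory brainstem response (ABR) — the first ~10 ms of the
auditory evoked potential, with waves I/III/V indexing auditory nerve,
cochlear nucleus and inferior colliculus — is measured by averaging
thousands of clicks.  This package instead treats continuous listening as a
linear encoding model: a nonlinear transform of the stimulus (the
*regressor*) is the input *x*, the EEG is the output *y*, and the evoked
response is the impulse response *h* linking them.  Two regressors are
provided:

* **HWR** — the half-wave rectified stimulus waveform (positive and
  sign-inverted negative halves run separately, responses averaged);
* **ANM** — the instantaneous firing rate of an auditory-periphery model
  (compression, adaptation, tuning), summed over characteristic frequencies
  from 125 Hz to 16 kHz in 1/6-octave steps at 65 dB SPL.  A built-in
  phenomenological periphery is included; an adapter for the published
  Zilany et al. model is used automatically when its Python port is
  installed.

The response is estimated in the frequency domain with inverse-variance
trial weighting,

```
response = F⁻¹{ Σₙ bₙ Xₙ* Yₙ  /  (1/N) Σₙ Xₙ* Xₙ },    bₙ = (1/σₙ²) / Σₘ (1/σₘ²)
```

unwrapped from its circular lag axis to [−200, 600] ms, averaged over
stimulus polarities, and shifted right by the regressor's intrinsic click
lag.  Cortical encoding of the same recordings is modelled with a ridge
temporal response function (TRF) over lags [−50, 400] ms at 125 Hz, with
10-fold cross-validated selection of the penalty.  Evaluation metrics
include response SNR against the pre-stimulus baseline, waveform /
split-set / noise-adjusted correlations, predicted-EEG correlation, and
spectral coherence with a mismatched-trial noise floor.  A forward-model
generator synthesizes music-like and speech-like stimulus surrogates and
EEG with pink noise, mains harmonics and heteroscedastic trials, so the
whole pipeline is testable without recordings.

## Worked example

```python
import contabr as cb

# synthesize a study-sized session: 40 twelve-second music-like trials,
# half-wave-rectified regressors, EEG = kernel * regressor + noise
ses = cb.simulate_abr_session(n_trials=40, duration_s=12.0, seed=42)

# subcortical preprocessing: 1 Hz causal high-pass, 60/120/300 Hz notches,
# earlobe-channel averaging
eeg = cb.reference_subcortical(cb.filter_subcortical(ses.eeg))

# weighted frequency-domain deconvolution
res = cb.AbrDeconvolution(eeg, ses.regressors).fit(window=(-0.2, 0.6))
print(res.snr().snr_db)   # 9.23  (dB, [0, 15] ms vs baseline)
print(res.wave_v())       # 7.90  (ms; the planted wave-V bump sits at 8.0)
```

The SNR of 9.2 dB says the response variance in the first 15 ms stands
about eight times above the baseline noise variance; the wave-V helper
finds the largest local maximum in the 5–11 ms window within one sample of
the planted latency.  Comparing the recovered kernel with the planted one
(passed through the same filters) over [0, 200] ms gives r = 0.964.

A command-line interface covers the same stages
(`contabr simulate | prepare | regress | preprocess | derive-abr |
derive-trf | evaluate | run`); `contabr run` executes the full synthetic
pipeline from a TOML config and writes a hashed artifact manifest.

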