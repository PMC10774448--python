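"""Forward-model synthesis of stimuli, regressors and EEG.

Generates data with the statistical structure the analysis pipeline
assumes: a planted lag-domain kernel (Gaussian bumps standing in for the
brainstem waves and slow cortical deflections) circularly convolved with a
stimulus regressor, plus 1/f background noise, mains harmonics and
heteroscedastic per-trial noise.  Stimulus surrogates come in two classes —
"music-like" (sustained tonal mixture with modest amplitude modulation, so
the broadband envelope has a non-zero mode) and "speech-like" (noise bursts
at a syllabic rate separated by silences, envelope mode at zero).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .containers import (
    EEGTrialSet,
    EvokedResponse,
    GroundTruthKernel,
    NoiseModel,
    Regressor,
    StimulusTrial,
)
from .stimulus import resample_poly_series

__all__ = [
    "make_stimulus_surrogate",
    "default_abr_kernel",
    "default_cortical_kernel",
    "pink_noise",
    "simulate_eeg",
    "simulate_drifted_clock",
    "SimulatedSession",
    "simulate_abr_session",
]

#: per-trial EEG noise of one unit of relative variance has this RMS (volts)
NOISE_RMS_V = 1e-6
#: clean (kernel * regressor) signal RMS in volts at the default gain;
#: calibrated so the planted kernel is recoverable at r >= 0.95 from 40
#: twelve-second trials at the default noise level
SIGNAL_RMS_V = 5e-6


def make_stimulus_surrogate(
    kind: str, duration_s: float = 12.0, fs: float = 48_000.0, seed: int | None = None
) -> StimulusTrial:
    """Synthesize a music-like or speech-like stimulus surrogate.

    music-like: three-partial harmonic complex with slow random amplitude
    modulation (depth ~0.3) plus weak noise — sustained, few near-zero
    envelope values.  speech-like: gamma-amplitude noise bursts at ~4 Hz
    with hard silences between bursts and occasional long (> 0.5 s) pauses.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if kind == "music-like":
        f0 = rng.uniform(180.0, 300.0)
        x = np.zeros(n)
        for h, amp in enumerate((1.0, 0.5, 0.25), start=1):
            x += amp * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
        # slow AM around a sustained level: mode of the envelope stays > 0
        am = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(1.0, 3.0) * t + rng.uniform(0, 2 * np.pi))
        x = x * am + 0.05 * rng.standard_normal(n)
    elif kind == "speech-like":
        x = np.zeros(n)
        pos = 0
        while pos < n:
            burst_n = int(rng.uniform(0.08, 0.25) * fs)
            gap_n = int(rng.uniform(0.05, 0.2) * fs)
            if rng.uniform() < 0.08:  # occasional long pause
                gap_n = int(rng.uniform(0.6, 1.2) * fs)
            amp = rng.gamma(shape=1.5, scale=1.0)
            end = min(pos + burst_n, n)
            ramp = np.hanning(2 * min(burst_n, end - pos))[: end - pos]
            x[pos:end] = amp * rng.standard_normal(end - pos) * ramp
            pos = end + gap_n
    else:
        raise ValueError("kind must be 'music-like' or 'speech-like'")
    x /= max(np.sqrt(np.mean(x**2)), 1e-12)
    return StimulusTrial(x, fs, label=kind)


def default_abr_kernel(fs: float = 10_000.0) -> GroundTruthKernel:
    """Brainstem-like test kernel: bumps near 3.5, 5.5 and 8 ms plus slow
    cortical deflections near 50/100/150 ms (test fixture, not physiology)."""
    return GroundTruthKernel(
        components=[
            (3.5, 0.4, 0.6),
            (5.5, 0.5, 0.8),
            (8.0, 0.6, 1.0),
            (50.0, 12.0, -0.5),
            (100.0, 18.0, 0.7),
            (150.0, 25.0, -0.4),
        ],
        fs=fs,
    )


def default_cortical_kernel(fs: float = 125.0) -> GroundTruthKernel:
    """Two-bump cortical TRF-like kernel (P1/N1-style deflections)."""
    return GroundTruthKernel(components=[(60.0, 15.0, 1.0), (110.0, 25.0, -0.8)], fs=fs)


def pink_noise(
    n: int, exponent: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent."""
    rng = rng or np.random.default_rng()
    freqs = sp_fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    x = sp_fft.irfft(spec, n=n)
    return x / np.sqrt(np.mean(x**2))


def _circular_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = a.size
    return sp_fft.irfft(sp_fft.rfft(a) * sp_fft.rfft(b, n=n), n=n)


def simulate_eeg(
    kernel: GroundTruthKernel,
    regs: list[Regressor],
    noise: NoiseModel | None = None,
    n_channels: int = 2,
    montage_role: str = "subcortical",
    signal_rms: float = SIGNAL_RMS_V,
    seed: int | None = None,
) -> tuple[EEGTrialSet, EvokedResponse]:
    """Forward-model EEG: circular kernel*regressor plus structured noise.

    One regressor per trial; every channel carries the same clean signal
    plus independent pink noise (per-trial variance drawn from the noise
    model's range) and a common mains component.  Returns the trial set and
    the planted kernel scaled to volts (the ground truth that deconvolution
    should recover).
    """
    if not regs:
        raise ValueError("need at least one regressor trial")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    fs = regs[0].fs
    n = regs[0].n_samples
    kern = kernel.render(n / fs)
    clean = np.stack([_circular_convolve(r.series, kern) for r in regs])
    rms = np.sqrt(np.mean(clean**2))
    gain = signal_rms / rms if rms > 0 else 0.0
    clean *= gain

    lo, hi = noise.per_trial_variance_range
    rel_var = rng.uniform(lo, hi, size=len(regs))
    t = np.arange(n) / fs
    trials = np.empty((len(regs), n_channels, n))
    for i in range(len(regs)):
        mains = np.zeros(n)
        for f0, a in zip(noise.line_freqs, noise.line_amplitudes):
            if f0 < fs / 2:
                mains += a * NOISE_RMS_V * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        sigma = np.sqrt(rel_var[i]) * noise.noise_scale * NOISE_RMS_V
        for c in range(n_channels):
            bg = pink_noise(n, noise.pink_exponent, rng) * sigma
            trials[i, c] = clean[i] + bg + mains
    drift_sample = int(round((n / fs - 0.02) * fs))
    triggers = np.tile([0, drift_sample], (len(regs), 1))
    eeg = EEGTrialSet(
        trials, fs_nominal=fs, montage_role=montage_role, triggers=triggers
    )
    truth = EvokedResponse(kernel=kern * gain, fs=fs, t0=0.0, n_trials=len(regs))
    return eeg, truth


def simulate_drifted_clock(eeg: EEGTrialSet, ppm_offset: float) -> EEGTrialSet:
    """Emulate a recorder clock off by ``ppm_offset`` parts per million.

    The waveform is resampled by (1 + ppm*1e-6) and the trigger samples are
    scaled to match, so :func:`~contabr.preprocess.correct_clock_drift`
    should undo the distortion.
    """
    if abs(ppm_offset) >= 10_000:
        raise ValueError("|ppm_offset| must be below 10000")
    if ppm_offset == 0:
        return eeg
    factor = 1.0 + ppm_offset * 1e-6
    out = [
        resample_poly_series(eeg.trials[i], eeg.fs_nominal, eeg.fs_nominal * factor)
        for i in range(eeg.n_trials)
    ]
    n_min = min(x.shape[-1] for x in out)
    trials = np.stack([x[..., :n_min] for x in out])
    triggers = None
    if eeg.triggers is not None:
        triggers = np.round(eeg.triggers * factor).astype(int)
    return eeg.copy_with(trials=trials, triggers=triggers)


@dataclass
class SimulatedSession:
    """A complete synthetic recording: stimuli, regressors, EEG, ground truth."""

    stimuli: list[StimulusTrial]
    regressors: dict[str, list[Regressor]]
    eeg: EEGTrialSet
    truth: EvokedResponse


def simulate_abr_session(
    n_trials: int = 40,
    stimulus_class: str = "music-like",
    duration_s: float = 12.0,
    fs_stim: float = 48_000.0,
    fs_eeg: float = 10_000.0,
    kernel: GroundTruthKernel | None = None,
    noise: NoiseModel | None = None,
    polarities: tuple[str, ...] = ("original",),
    seed: int | None = None,
) -> SimulatedSession:
    """Stimuli -> HWR regressors -> forward-model EEG, ready for deconvolution.

    The EEG is driven by the positive-polarity half-wave-rectified
    regressor, so by default only that regressor is returned and the
    forward model is exactly invertible.  Request
    ``polarities=("original", "inverted")`` to also get the sign-inverted
    regressor (the two-polarity averaging recipe targets stimulus-artifact
    cancellation in real recordings; with this generator the inverted
    regressor did not drive the EEG).
    """
    from .regressors import hwr_regressor

    rng = np.random.default_rng(seed)
    stimuli = [
        make_stimulus_surrogate(
            stimulus_class, duration_s, fs_stim, seed=int(rng.integers(2**31))
        )
        for _ in range(n_trials)
    ]
    pos, neg = zip(*(hwr_regressor(s, fs_eeg) for s in stimuli))
    kernel = kernel or default_abr_kernel(fs_eeg)
    eeg, truth = simulate_eeg(
        kernel, list(pos), noise, seed=int(rng.integers(2**31))
    )
    by_polarity = {"original": list(pos), "inverted": list(neg)}
    return SimulatedSession(
        stimuli=stimuli,
        regressors={p: by_polarity[p] for p in polarities},
        eeg=eeg,
        truth=truth,
    )


def truth_on_lag_axis(
    truth: EvokedResponse, resp: EvokedResponse, filter_fn=None
) -> EvokedResponse:
    """Render the circular planted kernel on a recovered response's lag axis.

    ``filter_fn`` (e.g. the subcortical filter chain) may be applied to the
    planted kernel first: preprocessing filters act on the EEG only, so the
    recoverable kernel is the planted one passed through the same filters —
    content inside the mains notches is removed from the data and cannot be
    estimated back.
    """
    kernel = truth.kernel
    if filter_fn is not None:
        wrapped = EEGTrialSet(kernel[None, None, :], truth.fs)
        kernel = filter_fn(wrapped).trials[0, 0]
    idx = np.round(resp.times * resp.fs).astype(int) % kernel.size
    return EvokedResponse(kernel[idx], fs=resp.fs, t0=resp.t0)
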