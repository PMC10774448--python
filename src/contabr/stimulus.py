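"""Stimulus conditioning: mono conversion, resampling, slow-envelope
flattening, silence removal, third-octave spectral matching and envelope
statistics.

The preparation chain mirrors a continuous-stimulus evoked-response
paradigm: excerpts are converted to mono at a common rate, music-like
material is flattened by its slow (0.1 Hz) envelope so quiet passages are
"turned up", long silences are excised from speech-like material, and all
trials are spectrally matched band-by-band to the across-trial mean
spectrum with a third-octave Butterworth filter bank.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import BandPowerTable, EnvelopeStats, StimulusTrial

__all__ = [
    "to_mono_resample",
    "resample_poly_series",
    "flatten_slow_envelope",
    "remove_silence",
    "third_octave_bands",
    "band_powers",
    "spectral_match",
    "envelope_density",
]


def resample_poly_series(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling from ``fs_in`` to ``fs_out``."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def to_mono_resample(trial: StimulusTrial, fs_target: float) -> StimulusTrial:
    """Average stereo channels to mono and resample to ``fs_target``."""
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if trial.n_channels > 2:
        raise ValueError(f"expected mono or stereo, got {trial.n_channels} channels")
    x = trial.samples
    if x.ndim == 2:
        x = x.mean(axis=0)
    y = resample_poly_series(x, trial.fs, fs_target)
    return StimulusTrial(y, fs_target, label=trial.label, trial_index=trial.trial_index)


def _slow_envelope(x: np.ndarray, fs: float, cutoff_hz: float = 0.1) -> np.ndarray:
    """Magnitude of the analytic signal, low-passed at ``cutoff_hz`` (zero phase)."""
    env = np.abs(signal.hilbert(x))
    nyq = fs / 2.0
    sos = signal.butter(2, cutoff_hz / nyq, btype="low", output="sos")
    return signal.sosfiltfilt(sos, env)


def flatten_slow_envelope(
    trial: StimulusTrial, cutoff_hz: float = 0.1
) -> StimulusTrial:
    """Divide the waveform by its slow envelope: x / (e + 0.1 * sigma_e).

    The 0.1*sigma_e term keeps the division away from zero.  With a
    constant-envelope input (sigma_e = 0) the result is an exact rescaling
    by the envelope value.
    """
    if trial.n_channels != 1:
        raise ValueError("flatten_slow_envelope expects a mono trial")
    x = trial.samples
    if not np.any(x):
        raise ZeroDivisionError("all-zero input: slow envelope is identically zero")
    if trial.duration < 10.0:
        warnings.warn(
            "trial shorter than 10 s: a 0.1 Hz slow envelope is poorly defined",
            stacklevel=2,
        )
    e = np.maximum(_slow_envelope(x, trial.fs, cutoff_hz), 0.0)
    sigma_e = float(np.std(e))
    denom = e + 0.1 * sigma_e
    if sigma_e == 0.0 and np.all(e == 0.0):
        raise ZeroDivisionError("slow envelope is identically zero")
    if sigma_e == 0.0:
        denom = e  # constant envelope: plain rescale, no guard needed
    return trial.copy_with(samples=x / denom)


def _silence_mask(
    x: np.ndarray, fs: float, threshold_frac: float, smooth_hz: float = 40.0
) -> np.ndarray:
    """Boolean mask of samples whose smoothed envelope is below the threshold.

    The threshold is ``threshold_frac`` of the trial RMS (the amplitude
    criterion is this package's choice; see docs/methods.md).
    """
    env = np.abs(x)
    nyq = fs / 2.0
    if smooth_hz < nyq:
        sos = signal.butter(2, smooth_hz / nyq, btype="low", output="sos")
        env = np.maximum(signal.sosfiltfilt(sos, env), 0.0)
    rms = float(np.sqrt(np.mean(x**2)))
    return env < threshold_frac * rms


def remove_silence(
    trial: StimulusTrial,
    max_gap_s: float = 0.5,
    threshold_frac: float = 0.01,
) -> StimulusTrial:
    """Cut out silent stretches strictly longer than ``max_gap_s`` seconds.

    Silence is classified from the smoothed absolute waveform falling below
    ``threshold_frac`` of the trial RMS.  A stretch of exactly
    ``max_gap_s`` is retained (only strictly longer gaps are removed).
    """
    if max_gap_s <= 0:
        raise ValueError("max_gap_s must be positive")
    if trial.n_channels != 1:
        raise ValueError("remove_silence expects a mono trial")
    x = trial.samples
    if not np.any(x):
        raise ValueError("entirely silent input: nothing would remain")
    silent = _silence_mask(x, trial.fs, threshold_frac)
    max_gap_n = int(round(max_gap_s * trial.fs))
    keep = np.ones(x.size, dtype=bool)
    # run-length scan over the silence mask
    edges = np.flatnonzero(np.diff(silent.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, x.size]
    for s, e in zip(starts, ends):
        if silent[s] and (e - s) > max_gap_n:
            keep[s:e] = False
    if not keep.any():
        raise ValueError("entirely silent input: nothing would remain")
    return trial.copy_with(samples=x[keep])


def third_octave_bands(fmin: float, fmax: float) -> np.ndarray:
    """Partition [fmin, fmax] into third-octave bands; returns edges (K, 2).

    Interior edges form an exact geometric ladder with ratio 2^(1/3),
    centred within the range; the leftover bandwidth (when the range is not
    an integer number of third-octaves) is split equally between two
    truncated end bands.  For an exact multiple the partition is purely
    geometric.  This construction yields 28 bands for (50, 22050) Hz.
    """
    if fmin <= 0 or fmax <= fmin:
        raise ValueError("need 0 < fmin < fmax")
    n_thirds = 3.0 * np.log2(fmax / fmin)
    n_full = int(np.floor(n_thirds + 1e-9))
    leftover = n_thirds - n_full
    if leftover < 1e-9:
        # exact multiple of 1/3 octave: pure geometric partition
        edges = fmin * 2.0 ** (np.arange(n_full + 1) / 3.0)
    else:
        # centred ladder: two equal truncated bands at the ends
        first = fmin * 2.0 ** (leftover / 6.0)
        interior = first * 2.0 ** (np.arange(n_full + 1) / 3.0)
        edges = np.r_[fmin, interior, fmax]
    edges[-1] = fmax
    return np.column_stack([edges[:-1], edges[1:]])


def _band_sos(low: float, high: float, fs: float, order: int = 6) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(high, 0.999 * nyq)
    if low >= hi:
        raise ValueError(f"band ({low:g}, {high:g}) Hz exceeds Nyquist {nyq:g} Hz")
    return signal.butter(order, [low / nyq, hi / nyq], btype="band", output="sos")


def _filterbank(x: np.ndarray, fs: float, bands: np.ndarray, order: int = 6) -> np.ndarray:
    """Zero-phase band decomposition; returns (K, n_samples).

    Zero-phase filtering keeps the band components aligned so the
    resynthesized sum reproduces the input (a causal bank would phase-scatter
    the bands and corrupt the reconstruction).
    """
    return np.stack(
        [signal.sosfiltfilt(_band_sos(lo, hi, fs, order), x) for lo, hi in bands]
    )


def band_powers(
    trials: list[StimulusTrial], bands: np.ndarray, order: int = 6
) -> BandPowerTable:
    """Mean power per third-octave band for each trial, plus across-trial means."""
    if not trials:
        raise ValueError("need at least one trial")
    fs = trials[0].fs
    if any(t.fs != fs for t in trials):
        raise ValueError("all trials must share a sampling rate")
    power = np.array(
        [np.mean(_filterbank(t.samples, fs, bands, order) ** 2, axis=1) for t in trials]
    )
    return BandPowerTable(bands, power, power.mean(axis=0))


def spectral_match(
    trials: list[StimulusTrial], bands: np.ndarray, order: int = 6
) -> list[StimulusTrial]:
    """Match every trial's band powers to the across-trial mean spectrum.

    Each output trial is ``sum_k xtilde_{n,k} * sqrt(Pbar_k / P_{n,k})``
    where ``xtilde_{n,k}`` is the 6th-order Butterworth band-filtered trial,
    ``P_{n,k}`` its power and ``Pbar_k`` the across-trial mean band power.
    """
    table = band_powers(trials, bands, order)
    fs = trials[0].fs
    out = []
    for n, trial in enumerate(trials):
        sub = _filterbank(trial.samples, fs, bands, order)
        p = table.per_trial_power[n]
        # a band at less than 1e-8 of the trial's strongest band would be
        # amplified by over 10^4 in amplitude: treat as empty
        zero = np.flatnonzero(p <= 1e-8 * p.max())
        if zero.size:
            raise ValueError(
                f"trial {trial.trial_index} ('{trial.label}') has no power in "
                f"band(s) {zero.tolist()}: scale undefined"
            )
        matched = (sub * np.sqrt(table.mean_power / p)[:, None]).sum(axis=0)
        out.append(trial.copy_with(samples=matched))
    return out


def broadband_envelope(
    x: np.ndarray, fs: float, cutoff_hz: float = 40.0
) -> np.ndarray:
    """Half-wave rectified waveform low-passed at ``cutoff_hz`` (causal)."""
    rect = np.maximum(x, 0.0)
    sos = signal.butter(2, cutoff_hz / (fs / 2.0), btype="low", output="sos")
    return np.maximum(signal.sosfilt(sos, rect), 0.0)


def envelope_density(
    trials: list[StimulusTrial],
    cutoff_hz: float = 40.0,
    n_bins: int = 100,
    bin_range: tuple[float, float] | None = None,
) -> EnvelopeStats:
    """Marginal probability density of the broadband envelope across trials.

    The envelope is the 40 Hz low-passed half-wave-rectified waveform; the
    density is a normalized histogram of its pooled values.  A mode at zero
    marks silence-punctuated (speech-like) material, a strictly positive
    mode sustained (music-like) material.
    """
    if not trials:
        raise ValueError("need at least one trial")
    envs = [broadband_envelope(t.samples, t.fs, cutoff_hz) for t in trials]
    pooled = np.concatenate(envs)
    if bin_range is None:
        hi = float(pooled.max())
        bin_range = (0.0, hi if hi > 0 else 1.0)
    density, edges = np.histogram(pooled, bins=n_bins, range=bin_range, density=True)
    return EnvelopeStats(
        envelope=pooled,
        fs=trials[0].fs,
        sigma_e=float(np.std(pooled)),
        density=density,
        bin_edges=edges,
    )
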