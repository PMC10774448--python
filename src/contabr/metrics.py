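"""Evaluation metrics for deconvolved responses and EEG predictions.

Covers the response SNR (pre-stimulus baseline variance against the [0, 15]
ms window), waveform and split-set correlations with the noise-adjusted
correlation derived from them, forward EEG prediction from a cropped
kernel, broadband prediction correlation, and spectral coherence with a
mismatched-trial noise floor.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .containers import CoherenceSpectrum, EvokedResponse, Regressor, SNREstimate

__all__ = [
    "response_snr",
    "waveform_correlation",
    "split_set_correlation",
    "noise_adjusted_r",
    "predict_eeg",
    "prediction_correlation",
    "spectral_coherence",
    "coherence_noise_floor",
    "find_wave_v",
]


def _window_slice(resp: EvokedResponse, t_min_s: float, t_max_s: float) -> np.ndarray:
    t = resp.times
    mask = (t >= t_min_s - 0.5 / resp.fs) & (t <= t_max_s + 0.5 / resp.fs)
    if not mask.any():
        raise ValueError(f"window [{t_min_s}, {t_max_s}] s is outside the lag axis")
    return mask


def response_snr(
    resp: EvokedResponse,
    signal_window_ms: tuple[float, float] = (0.0, 15.0),
    noise_window_ms: tuple[float, float] = (-200.0, -20.0),
    segment_ms: float = 15.0,
) -> SNREstimate:
    """SNR = 10 log10[(sigma_{S+N}^2 - sigma_N^2) / sigma_N^2].

    ``sigma_{S+N}^2`` is the response variance in the signal window;
    ``sigma_N^2`` averages the variance of consecutive ``segment_ms``
    segments tiling the pre-stimulus baseline.  When the numerator is not
    positive there is too little signal and the SNR is undefined
    (``snr_db`` is None).
    """
    if resp.kernel.ndim != 1:
        raise ValueError("response_snr expects a single-channel response")
    lo, hi = resp.lag_window
    half_ms = 500.0 / resp.fs
    if lo * 1e3 > noise_window_ms[0] + half_ms or hi * 1e3 < signal_window_ms[1] - half_ms:
        raise ValueError("lag window does not cover the SNR analysis windows")
    sig = resp.kernel[_window_slice(resp, *(w / 1e3 for w in signal_window_ms))]
    var_sn = float(np.var(sig))
    noise = resp.kernel[_window_slice(resp, *(w / 1e3 for w in noise_window_ms))]
    seg_n = int(round(segment_ms / 1e3 * resp.fs))
    n_segs = noise.size // seg_n
    if n_segs < 1:
        raise ValueError("baseline too short for one noise segment")
    segs = noise[: n_segs * seg_n].reshape(n_segs, seg_n)
    var_n = float(np.mean(np.var(segs, axis=1)))
    if var_sn <= var_n or var_n <= 0:
        snr_db = None
    else:
        snr_db = float(10.0 * np.log10((var_sn - var_n) / var_n))
    return SNREstimate(
        snr_db,
        signal_variance=var_sn,
        noise_variance=var_n,
        signal_window_ms=signal_window_ms,
        noise_window_ms=noise_window_ms,
        segment_ms=segment_ms,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def waveform_correlation(
    a: EvokedResponse,
    b: EvokedResponse,
    window_ms: tuple[float, float] = (0.0, 15.0),
) -> float:
    """Pearson correlation of two responses over a lag window ([0, 15] ms default)."""
    if a.fs != b.fs:
        raise ValueError("responses must share a sampling rate")
    mask_a = _window_slice(a, *(w / 1e3 for w in window_ms))
    mask_b = _window_slice(b, *(w / 1e3 for w in window_ms))
    xa, xb = a.kernel[mask_a], b.kernel[mask_b]
    if xa.size != xb.size:
        raise ValueError("responses do not share a common lag axis in the window")
    return _pearson(xa, xb)


def split_set_correlation(
    responses_by_class: dict[str, list[EvokedResponse]],
    n_splits: int = 100,
    seed: int | None = None,
    window_ms: tuple[float, float] = (0.0, 15.0),
) -> np.ndarray:
    """Correlations between averages of two randomized class-balanced halves.

    Each split partitions every class's responses into two halves of equal
    size; the two half-averages (pooled over classes) are correlated over
    ``window_ms``.  Returns the ``n_splits`` correlation values; the median
    is the conventional summary (the noise ceiling on between-condition
    correlations).
    """
    rng = np.random.default_rng(seed)
    for label, resps in responses_by_class.items():
        if len(resps) % 2:
            raise ValueError(f"class '{label}' has an odd number of responses")
    out = np.empty(n_splits)
    for s in range(n_splits):
        half_a: list[np.ndarray] = []
        half_b: list[np.ndarray] = []
        for resps in responses_by_class.values():
            order = rng.permutation(len(resps))
            mid = len(resps) // 2
            for i in order[:mid]:
                half_a.append(resps[i].kernel[_window_slice(resps[i], *(w / 1e3 for w in window_ms))])
            for i in order[mid:]:
                half_b.append(resps[i].kernel[_window_slice(resps[i], *(w / 1e3 for w in window_ms))])
        out[s] = _pearson(np.mean(half_a, axis=0), np.mean(half_b, axis=0))
    return out


def noise_adjusted_r(r_ab: float, r_split: float) -> tuple[float, float]:
    """Noise-adjusted correlation: (r_adj, r2_adj) = (|r_ab|/r_split signed,
    r_ab^2/r_split^2).

    ``r_split`` is the split-set (noise-ceiling) correlation; the adjusted
    quantities estimate how much of the *explainable* variance the
    between-condition correlation accounts for.
    """
    if r_split <= 0:
        raise ValueError("r_split must be positive for noise adjustment")
    r2_adj = r_ab**2 / r_split**2
    r_adj = np.sign(r_ab) * abs(r_ab) / r_split if r_ab != 0 else 0.0
    return float(r_adj), float(r2_adj)


def predict_eeg(
    kernel: EvokedResponse,
    reg: Regressor,
    kernel_window: tuple[float, float] = (0.0, 0.2),
) -> np.ndarray:
    """Predicted EEG: the kernel (cropped to ``kernel_window`` seconds)
    linearly convolved with the regressor, trimmed to the regressor length.

    The convolution is aligned so the prediction at sample ``t`` sums
    regressor history weighted by the kernel at its stated lags.
    """
    if kernel.fs != reg.fs:
        raise ValueError("kernel and regressor sampling rates differ")
    cropped = kernel.crop(*kernel_window)
    if cropped.kernel.ndim != 1:
        raise ValueError("predict_eeg expects a single-channel kernel")
    full = np.convolve(reg.series, cropped.kernel)
    # a kernel starting at lag t0 shifts the prediction by round(t0 * fs)
    offset = int(round(cropped.t0 * cropped.fs))
    n = reg.n_samples
    pred = np.zeros(n)
    src = full[max(offset, 0) : offset + n] if offset >= 0 else full[: n + offset]
    if offset >= 0:
        pred[: src.size] = src
    else:
        pred[-offset : -offset + src.size] = src[: n + offset]
    return pred


def prediction_correlation(
    pred: np.ndarray,
    eeg: np.ndarray,
    fs: float | None = None,
    highpass_hz: float | None = None,
) -> float:
    """Pearson correlation between predicted and recorded EEG.

    With ``highpass_hz`` both series are passed through the same
    first-order causal Butterworth high-pass first (e.g. 40 Hz to isolate
    the fast subcortical component).
    """
    pred = np.asarray(pred, dtype=float)
    eeg = np.asarray(eeg, dtype=float)
    if pred.shape != eeg.shape:
        raise ValueError("prediction and EEG must have equal length")
    if highpass_hz is not None:
        if fs is None:
            raise ValueError("fs is required when high-passing")
        sos = signal.butter(1, highpass_hz / (fs / 2.0), btype="high", output="sos")
        pred = signal.sosfilt(sos, pred)
        eeg = signal.sosfilt(sos, eeg)
    return _pearson(pred, eeg)


def spectral_coherence(
    pred: np.ndarray, eeg: np.ndarray, fs: float, slice_s: float = 0.2
) -> CoherenceSpectrum:
    """Complex spectral coherence between two series across time slices.

    Both series are cut into non-overlapping rectangular ``slice_s``
    windows (which set the frequency-bin spacing, 5 Hz for 0.2 s); per bin,

        C_xy(f) = E[X_i*(f) Y_i(f)] / sqrt(E[|X_i|^2] E[|Y_i|^2])

    with the expectation across slices.
    """
    pred = np.asarray(pred, dtype=float)
    eeg = np.asarray(eeg, dtype=float)
    if pred.shape != eeg.shape:
        raise ValueError("series must have equal length")
    n_slice = int(round(slice_s * fs))
    n_slices = pred.size // n_slice
    if n_slices < 2:
        raise ValueError("need at least two slices for an expectation")
    X = sp_fft.rfft(pred[: n_slices * n_slice].reshape(n_slices, n_slice), axis=-1)
    Y = sp_fft.rfft(eeg[: n_slices * n_slice].reshape(n_slices, n_slice), axis=-1)
    cross = np.mean(np.conj(X) * Y, axis=0)
    px = np.mean(np.abs(X) ** 2, axis=0)
    py = np.mean(np.abs(Y) ** 2, axis=0)
    denom = np.sqrt(px * py)
    coh = np.zeros_like(cross)
    ok = denom > 0
    coh[ok] = cross[ok] / denom[ok]
    # numerical guard: |C| can exceed 1 by rounding only
    mag = np.abs(coh)
    over = mag > 1.0
    coh[over] /= mag[over]
    freqs = sp_fft.rfftfreq(n_slice, d=1.0 / fs)
    return CoherenceSpectrum(freqs=freqs, coherence=coh, n_slices=n_slices)


def coherence_noise_floor(
    preds: list[np.ndarray],
    eegs: list[np.ndarray],
    fs: float,
    slice_s: float = 0.2,
    n_shuffles: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Per-bin median |coherence| over mismatched prediction/EEG pairings.

    Each shuffle applies a derangement-checked permutation (no trial is
    paired with itself) before computing coherence; the median across all
    mismatched pairs estimates the chance coherence level.
    """
    if len(preds) != len(eegs) or len(preds) < 2:
        raise ValueError("need matching lists of at least two trials")
    rng = np.random.default_rng(seed)
    n = len(preds)
    mags = []
    for _ in range(n_shuffles):
        while True:
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                break
        for i, j in enumerate(perm):
            mags.append(spectral_coherence(preds[i], eegs[j], fs, slice_s).magnitude)
    return np.median(mags, axis=0)


def find_wave_v(
    resp: EvokedResponse, search_window_ms: tuple[float, float] = (5.0, 11.0)
) -> float | None:
    """Latency (ms) of the largest local maximum in the search window.

    An automatic stand-in for manual wave-V picking: returns None when the
    window contains no local maximum (flat or monotonic response).
    """
    if resp.kernel.ndim != 1:
        raise ValueError("find_wave_v expects a single-channel response")
    mask = _window_slice(resp, *(w / 1e3 for w in search_window_ms))
    x = resp.kernel[mask]
    t = resp.times[mask]
    peaks, _ = signal.find_peaks(x)
    if peaks.size == 0:
        return None
    best = peaks[int(np.argmax(x[peaks]))]
    return float(t[best] * 1e3)
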