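"""EEG conditioning for the subcortical and cortical analysis paths.

Subcortical path: clock-drift correction against the sound card, 1 Hz
first-order causal Butterworth high-pass, second-order IIR notches at 60,
120 and 300 Hz (5 Hz width), then averaging of the two earlobe-referenced
channels.  All subcortical filters are causal so early response latencies
are not smeared backwards.

Cortical TRF path: 0.5-30 Hz zero-phase FIR band-pass, downsampling to
125 Hz, and removal of the first second of each epoch.  The cortical
deconvolution path instead reuses the subcortical filters with a 0.1 Hz
high-pass and no downsampling.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EEGTrialSet
from .stimulus import resample_poly_series

__all__ = [
    "correct_clock_drift",
    "filter_subcortical",
    "reference_subcortical",
    "filter_cortical_trf",
    "filter_cortical_deconv",
]


def correct_clock_drift(
    eeg: EEGTrialSet,
    stim_duration_s: float = 12.0,
    drift_offset_s: float | None = None,
) -> EEGTrialSet:
    """Resample each trial so the EEG clock matches the sound card.

    The true sampling rate is the number of samples between the start and
    drift triggers divided by their known time offset (stimulus duration
    minus the 20 ms pre-end stamp, 11.98 s for a 12 s stimulus).  Trials
    are then resampled back to the nominal rate.
    """
    if eeg.triggers is None:
        raise ValueError("clock-drift correction requires trigger metadata")
    if drift_offset_s is None:
        drift_offset_s = stim_duration_s - 0.02
    if drift_offset_s <= 0:
        raise ValueError("drift offset must be positive")
    spans = eeg.triggers[:, 1] - eeg.triggers[:, 0]
    fs_actual = spans / drift_offset_s
    out = []
    trig_out = []
    for n in range(eeg.n_trials):
        fsa = float(fs_actual[n])
        if abs(fsa - eeg.fs_nominal) < 1e-9:
            out.append(eeg.trials[n])
            trig_out.append(eeg.triggers[n])
            continue
        corrected = resample_poly_series(eeg.trials[n], fsa, eeg.fs_nominal)
        out.append(corrected)
        scale = eeg.fs_nominal / fsa
        trig_out.append(np.round(eeg.triggers[n] * scale).astype(int))
    n_min = min(t.shape[-1] for t in out)
    trials = np.stack([t[..., :n_min] for t in out])
    return eeg.copy_with(
        trials=trials,
        fs_actual=float(eeg.fs_nominal),
        triggers=np.stack(trig_out),
    )


def _highpass_sos(cutoff_hz: float, fs: float, order: int = 1) -> np.ndarray:
    return signal.butter(order, cutoff_hz / (fs / 2.0), btype="high", output="sos")


def _notch_ba(freq: float, fs: float, width_hz: float) -> tuple[np.ndarray, np.ndarray]:
    # Q from the -3 dB width: Q = f0 / width
    return signal.iirnotch(freq, freq / width_hz, fs=fs)


def filter_subcortical(
    eeg: EEGTrialSet,
    highpass_hz: float = 1.0,
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 300.0),
    notch_width_hz: float = 5.0,
) -> EEGTrialSet:
    """Causal 1 Hz first-order high-pass plus 5 Hz-wide IIR notches."""
    fs = eeg.fs_nominal
    x = eeg.trials
    x = signal.sosfilt(_highpass_sos(highpass_hz, fs), x, axis=-1)
    for f0 in notch_freqs:
        if f0 >= fs / 2.0:
            continue
        b, a = _notch_ba(f0, fs, notch_width_hz)
        x = signal.lfilter(b, a, x, axis=-1)
    return eeg.copy_with(trials=x)


def reference_subcortical(eeg: EEGTrialSet) -> EEGTrialSet:
    """Average the two earlobe-referenced channels into one."""
    if eeg.montage_role != "subcortical":
        raise ValueError("subcortical referencing requires the subcortical montage")
    if eeg.n_channels != 2:
        raise ValueError(f"expected exactly 2 channels, got {eeg.n_channels}")
    ref = eeg.trials.mean(axis=1, keepdims=True)
    return eeg.copy_with(trials=ref)


def filter_cortical_trf(
    eeg: EEGTrialSet,
    fs_out: float = 125.0,
    highpass_hz: float = 0.5,
    lowpass_hz: float = 30.0,
    drop_first_s: float = 1.0,
) -> EEGTrialSet:
    """Zero-phase FIR band-pass, downsample to ``fs_out``, drop the first second.

    FIR design: Hamming-window band-pass with transition widths of half the
    high-pass cutoff and 25% of the low-pass cutoff (the published
    procedure does not state the FIR order; see docs/methods.md).
    """
    if eeg.montage_role != "cortical":
        raise ValueError("TRF filtering requires the cortical montage")
    fs = eeg.fs_nominal
    if eeg.n_samples / fs <= drop_first_s:
        raise ValueError("epoch shorter than the onset interval to be dropped")
    numtaps = int(round(3.3 / (0.5 * highpass_hz) * fs))
    numtaps |= 1  # odd length for a type-I linear-phase FIR
    taps = signal.firwin(
        numtaps,
        [highpass_hz, lowpass_hz],
        pass_zero=False,
        fs=fs,
        window="hamming",
    )
    # symmetric FIR applied once with "same" alignment is exactly zero-phase
    x = signal.fftconvolve(eeg.trials, taps[None, None, :], mode="same", axes=-1)
    x = resample_poly_series(x, fs, fs_out)
    drop = int(round(drop_first_s * fs_out))
    x = x[..., drop:]
    return eeg.copy_with(trials=x, fs_nominal=fs_out, fs_actual=fs_out, triggers=None)


def filter_cortical_deconv(eeg: EEGTrialSet, highpass_hz: float = 0.1) -> EEGTrialSet:
    """Cortical deconvolution path: subcortical filters with a 0.1 Hz high-pass."""
    if eeg.montage_role != "cortical":
        raise ValueError("cortical deconvolution filtering requires the cortical montage")
    return filter_subcortical(eeg, highpass_hz=highpass_hz)
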