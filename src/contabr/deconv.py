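"""Weighted frequency-domain deconvolution of EEG against stimulus regressors.

The evoked response is the impulse response of the linear system taking the
regressor ``x`` to the EEG ``y``.  With per-trial spectra ``X_n``, ``Y_n``
it is estimated as

    response = IFFT( sum_n b_n X_n* Y_n  /  (1/N) sum_n X_n* X_n )

where the numerator is weighted by the inverse-variance trial weights
``b_n = (1/sigma_n^2) / sum_m (1/sigma_m^2)`` and the denominator is the
unweighted mean regressor power spectrum.  The FFT length equals the trial
length (no padding), so the estimate is circular: the tail of the response
holds negative lags, recovered by :func:`unwrap_circular`.

:class:`AbrDeconvolution` wraps the full recipe (weights, both regressor
polarities, unwrapping, periphery-lag compensation) in a fit/results pair.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import fft as sp_fft

from .containers import EEGTrialSet, EvokedResponse, Regressor, TrialWeights

__all__ = [
    "compute_weights",
    "deconvolve",
    "unwrap_circular",
    "compensate_lag",
    "combine_polarities",
    "average_category",
    "AbrDeconvolution",
    "AbrResult",
]


def compute_weights(eeg: EEGTrialSet) -> TrialWeights:
    """Inverse-variance trial weights from the filtered single-channel EEG.

    The variance is taken over the full trial duration (averaged across
    channels for multichannel input).
    """
    if eeg.n_trials < 1:
        raise ValueError("need at least one trial")
    var = eeg.trials.var(axis=-1).mean(axis=-1)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0).tolist()
        raise ValueError(f"zero-variance trial(s) {bad}: degenerate recording")
    inv = 1.0 / var
    return TrialWeights(variances=var, weights=inv / inv.sum())


def deconvolve(
    regs: list[Regressor],
    eeg: EEGTrialSet,
    weights: TrialWeights | None = None,
    eps_rel: float = 1e-10,
) -> EvokedResponse:
    """Weighted cross-spectrum over mean auto-spectrum, inverse-transformed.

    ``regs`` holds one regressor per EEG trial at the EEG sampling rate and
    trial length.  Near-null denominator bins are floored at ``eps_rel``
    times the maximum bin power; a warning is emitted when more than 1% of
    bins needed the floor.
    """
    if len(regs) != eeg.n_trials:
        raise ValueError("one regressor per EEG trial is required")
    n = eeg.n_samples
    for r in regs:
        if r.fs != eeg.fs_nominal:
            raise ValueError("regressor and EEG sampling rates differ")
        if r.n_samples != n:
            raise ValueError("regressor and EEG trial lengths differ")
    if weights is None:
        weights = compute_weights(eeg)
    if weights.n_trials != eeg.n_trials:
        raise ValueError("weights do not match the trial count")

    x = np.stack([r.series for r in regs])  # (n_trials, n)
    X = sp_fft.rfft(x, axis=-1)
    Y = sp_fft.rfft(eeg.trials, axis=-1)  # (n_trials, n_channels, nf)
    num = np.einsum("n,nf,ncf->cf", weights.weights, np.conj(X), Y)
    denom = np.mean(np.abs(X) ** 2, axis=0)  # (nf,)
    floor = eps_rel * denom.max()
    n_floored = int(np.sum(denom < floor))
    if n_floored > 0.01 * denom.size:
        warnings.warn(
            f"{n_floored}/{denom.size} spectral bins fell below the "
            "regularization floor; the regressor spectrum is nearly null there",
            stacklevel=2,
        )
    kernel = sp_fft.irfft(num / np.maximum(denom, floor)[None, :], n=n, axis=-1)
    if kernel.shape[0] == 1:
        kernel = kernel[0]
    return EvokedResponse(
        kernel=kernel, fs=eeg.fs_nominal, t0=0.0, n_trials=eeg.n_trials
    )


def unwrap_circular(
    resp: EvokedResponse, window: tuple[float, float] = (-0.2, 0.6)
) -> EvokedResponse:
    """Re-index the circular response from [0, T) to [-T/2, T/2), then crop.

    The deconvolution is circular, so lags near the end of the trial are
    negative lags; splitting the axis in half and concatenating tail before
    head makes them explicit.  The result is cropped to ``window`` seconds.
    """
    t_min, t_max = window
    n = resp.n_lags
    duration = n / resp.fs
    if resp.t0 != 0.0:
        raise ValueError("response is already unwrapped")
    if abs(t_min) + t_max > duration:
        raise ValueError("window exceeds the circular trial duration")
    half = n // 2
    kernel = np.concatenate(
        [resp.kernel[..., n - half :], resp.kernel[..., : n - half]], axis=-1
    )
    full = resp.copy_with(kernel=kernel, t0=-half / resp.fs)
    return full.crop(t_min, t_max)


def compensate_lag(resp: EvokedResponse, lag_ms: float) -> EvokedResponse:
    """Shift the lag axis right by the regressor's intrinsic lag."""
    if lag_ms < 0:
        raise ValueError("lag_ms must be nonnegative")
    if resp.lag_compensated_ms:
        raise ValueError("lag compensation has already been applied")
    return resp.copy_with(t0=resp.t0 + lag_ms / 1e3, lag_compensated_ms=lag_ms)


def _check_axes(a: EvokedResponse, b: EvokedResponse) -> None:
    if a.fs != b.fs or a.n_lags != b.n_lags or abs(a.t0 - b.t0) > 0.25 / a.fs:
        raise ValueError("responses are not on a common lag axis")


def combine_polarities(pos: EvokedResponse, neg: EvokedResponse) -> EvokedResponse:
    """Average the responses from the two stimulus polarities.

    Stimulus artifact components that flip sign with polarity cancel in the
    mean, while the neural response (which does not flip) is preserved.
    """
    _check_axes(pos, neg)
    return pos.copy_with(
        kernel=0.5 * (pos.kernel + neg.kernel),
        n_trials=pos.n_trials + neg.n_trials,
        polarity_combined=True,
    )


def average_category(resps: list[EvokedResponse]) -> EvokedResponse:
    """Unweighted mean across stimulus types (or subjects)."""
    if not resps:
        raise ValueError("need at least one response")
    first = resps[0]
    for r in resps[1:]:
        _check_axes(first, r)
    kernel = np.mean([r.kernel for r in resps], axis=0)
    return first.copy_with(kernel=kernel, n_trials=sum(r.n_trials for r in resps))


class AbrDeconvolution:
    """Evoked-response deconvolution model.

    Parameters
    ----------
    eeg : EEGTrialSet
        Preprocessed (filtered, referenced) EEG, one entry per trial.
    regressors : list of Regressor or dict
        Either one regressor per trial, or a mapping with keys
        ``"original"`` / ``"inverted"`` each holding one regressor per
        trial; with both polarities the two deconvolved responses are
        averaged (cancelling stimulus artifact).
    """

    def __init__(
        self,
        eeg: EEGTrialSet,
        regressors: list[Regressor] | dict[str, list[Regressor]],
    ) -> None:
        if isinstance(regressors, dict):
            unknown = set(regressors) - {"original", "inverted"}
            if unknown:
                raise ValueError(f"unknown polarity keys {sorted(unknown)}")
            self.regressors = dict(regressors)
        else:
            self.regressors = {"original": list(regressors)}
        self.eeg = eeg

    def fit(
        self,
        window: tuple[float, float] = (-0.2, 0.6),
        compensate: bool = True,
        weights: TrialWeights | None = None,
    ) -> "AbrResult":
        """Deconvolve, unwrap to ``window``, combine polarities, shift by lag."""
        w = weights if weights is not None else compute_weights(self.eeg)
        by_polarity = {
            pol: unwrap_circular(deconvolve(regs, self.eeg, w), window)
            for pol, regs in self.regressors.items()
        }
        if len(by_polarity) == 2:
            resp = combine_polarities(
                by_polarity["original"], by_polarity["inverted"]
            )
        else:
            (resp,) = by_polarity.values()
        lag_ms = next(iter(self.regressors.values()))[0].lag_ms
        if compensate and lag_ms:
            resp = compensate_lag(resp, lag_ms)
        return AbrResult(self, resp, w, by_polarity)


class AbrResult:
    """Fitted evoked response with trial weights and per-polarity components."""

    def __init__(
        self,
        model: AbrDeconvolution,
        response: EvokedResponse,
        weights: TrialWeights,
        by_polarity: dict[str, EvokedResponse],
    ) -> None:
        self.model = model
        self.response = response
        self.weights = weights
        self.by_polarity = by_polarity

    def snr(self, **kw):
        from .metrics import response_snr

        return response_snr(self.response, **kw)

    def wave_v(self, **kw):
        from .metrics import find_wave_v

        return find_wave_v(self.response, **kw)

    def predict(self, reg: Regressor, kernel_window=(0.0, 0.2)) -> np.ndarray:
        from .metrics import predict_eeg

        return predict_eeg(self.response, reg, kernel_window)

    def plot(self, ax=None, lowpass_hz: float | None = 1500.0):
        """Plot the response (display low-pass applied only here, never to metrics)."""
        import matplotlib.pyplot as plt
        from scipy import signal as sp_signal

        if ax is None:
            _, ax = plt.subplots()
        kernel = self.response.kernel
        if lowpass_hz is not None and lowpass_hz < self.response.fs / 2:
            sos = sp_signal.butter(
                4, lowpass_hz / (self.response.fs / 2), btype="low", output="sos"
            )
            kernel = sp_signal.sosfiltfilt(sos, kernel, axis=-1)
        ax.plot(self.response.times * 1e3, np.atleast_2d(kernel).T * 1e6, lw=0.8)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("amplitude (µV / regressor unit)")
        return ax

    def summary(self) -> str:
        import pandas as pd

        resp = self.response
        lines = [
            "Evoked-response deconvolution",
            "=" * 34,
            f"trials:            {self.weights.n_trials}",
            f"polarities:        {', '.join(self.by_polarity)}",
            f"lag window:        [{resp.lag_window[0] * 1e3:.1f}, "
            f"{resp.lag_window[1] * 1e3:.1f}] ms",
            f"lag compensation:  {resp.lag_compensated_ms:.2f} ms",
            f"sampling rate:     {resp.fs:g} Hz",
        ]
        try:
            est = self.snr()
            snr_txt = f"{est.snr_db:.2f} dB" if est.defined else "undefined"
            lines.append(f"SNR [0, 15] ms:    {snr_txt}")
        except ValueError:
            pass
        wtab = pd.DataFrame(
            {"variance": self.weights.variances, "weight": self.weights.weights}
        )
        lines += ["", "trial weights:", wtab.to_string(float_format="%.4g")]
        return "\n".join(lines)
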