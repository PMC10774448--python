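"""Cortical temporal response functions (TRF) and deconvolved cortical responses.

The TRF is a lagged ridge regression from a stimulus feature (broadband
Hilbert envelope or the summed auditory-nerve-model rate, both at 125 Hz)
to each EEG channel over lags spanning [-50, 400] ms.  The ridge parameter
is chosen by cross-validated prediction correlation over trials, and the
model is refit on all data at the selected value.

The same EEG can instead be deconvolved channel-by-channel with the
frequency-domain engine; because nothing is downsampled on that path, the
early (brainstem), middle and late (cortical) components coexist on one
lag axis.  The global field power summarizes multichannel responses as the
across-channel standard deviation at each lag.
"""

from __future__ import annotations

import numpy as np

from .containers import EEGTrialSet, EvokedResponse, Regressor, StimulusTrial, TrialWeights
from .deconv import deconvolve, unwrap_circular, compensate_lag
from .stimulus import resample_poly_series

__all__ = [
    "envelope_regressor",
    "TemporalResponseFunction",
    "TRFResult",
    "fit_trf",
    "trf_predict_cv",
    "trf_weight_correlation",
    "cortical_deconvolution",
    "global_field_power",
]


def envelope_regressor(trial: StimulusTrial, fs_out: float = 125.0) -> Regressor:
    """Broadband amplitude envelope: |Hilbert analytic signal|, anti-alias
    downsampled to the EEG rate."""
    from scipy.signal import hilbert

    if trial.n_channels != 1:
        raise ValueError("envelope_regressor expects a mono trial")
    env = np.abs(hilbert(trial.samples))
    series = np.maximum(resample_poly_series(env, trial.fs, fs_out), 0.0)
    return Regressor(
        series,
        fs_out,
        kind="envelope",
        lag_ms=0.0,
        label=trial.label,
        trial_index=trial.trial_index,
    )


def lag_samples(lags_ms: tuple[float, float], fs: float) -> np.ndarray:
    """Integer lag grid covering ``lags_ms``; bounds rounded outward."""
    lo = int(np.floor(lags_ms[0] / 1e3 * fs))
    hi = int(np.ceil(lags_ms[1] / 1e3 * fs))
    return np.arange(lo, hi + 1)


def _design_matrix(series: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Lagged copies of the regressor, zero-padded at the epoch edges.

    Column ``l`` holds ``series[t - lag_l]`` so positive lags model the EEG
    following the stimulus.
    """
    n = series.size
    X = np.zeros((n, lags.size))
    for j, lag in enumerate(lags):
        if lag >= 0:
            X[lag:, j] = series[: n - lag] if lag < n else 0.0
        else:
            X[: n + lag, j] = series[-lag:]
    return X


class TemporalResponseFunction:
    """Ridge-regression TRF model.

    Parameters
    ----------
    regressors : list of Regressor
        One per trial, at the EEG sampling rate.
    eeg : EEGTrialSet
        Cortical EEG (TRF preprocessing path), trials matching the
        regressors in length.
    lags_ms : (float, float)
        Lag window; default [-50, 400] ms, rounded outward to samples.
    """

    def __init__(
        self,
        regressors: list[Regressor],
        eeg: EEGTrialSet,
        lags_ms: tuple[float, float] = (-50.0, 400.0),
    ) -> None:
        if len(regressors) != eeg.n_trials:
            raise ValueError("one regressor per EEG trial is required")
        fs = eeg.fs_nominal
        for r in regressors:
            if r.fs != fs:
                raise ValueError("regressor and EEG sampling rates differ")
            if r.n_samples != eeg.n_samples:
                raise ValueError("regressor and EEG trial lengths differ")
        self.regressors = list(regressors)
        self.eeg = eeg
        self.fs = fs
        self.lags = lag_samples(lags_ms, fs)
        self._designs = [_design_matrix(r.series, self.lags) for r in regressors]

    # -- core linear algebra ------------------------------------------------
    def _accumulate(self, trial_idx) -> tuple[np.ndarray, np.ndarray]:
        XtX = np.zeros((self.lags.size, self.lags.size))
        XtY = np.zeros((self.lags.size, self.eeg.n_channels))
        for i in trial_idx:
            X = self._designs[i]
            XtX += X.T @ X
            XtY += X.T @ self.eeg.trials[i].T
        return XtX, XtY

    @staticmethod
    def _solve_ridge(XtX, XtY, lambdas) -> list[np.ndarray]:
        """Weights (n_lags, n_channels) for every candidate lambda."""
        d, V = np.linalg.eigh(XtX)
        VtY = V.T @ XtY
        out = []
        for lam in lambdas:
            if lam == 0 and np.min(d) < 1e-10 * max(np.max(d), 1.0):
                raise np.linalg.LinAlgError(
                    "singular design with lambda = 0; use a positive ridge penalty"
                )
            out.append(V @ (VtY / (d + lam)[:, None]))
        return out

    def _fold_indices(self, folds: int) -> list[np.ndarray]:
        n = self.eeg.n_trials
        if folds < 2 or folds > n:
            raise ValueError("folds must be between 2 and the number of trials")
        return [np.arange(n)[k::folds] for k in range(folds)]

    def _cv_correlations(self, lambdas, folds) -> np.ndarray:
        """Out-of-fold r, shape (n_lambdas, n_channels), averaged over folds."""
        n = self.eeg.n_trials
        r_sum = np.zeros((len(lambdas), self.eeg.n_channels))
        fold_sets = self._fold_indices(folds)
        for test in fold_sets:
            train = np.setdiff1d(np.arange(n), test)
            XtX, XtY = self._accumulate(train)
            weight_sets = self._solve_ridge(XtX, XtY, lambdas)
            for li, W in enumerate(weight_sets):
                for i in test:
                    pred = self._designs[i] @ W  # (n_samples, n_channels)
                    y = self.eeg.trials[i].T
                    r_sum[li] += _columnwise_r(pred, y) / len(test)
        return r_sum / len(fold_sets)

    def fit(
        self,
        lambdas: np.ndarray | None = None,
        folds: int = 10,
    ) -> "TRFResult":
        """Select the ridge penalty by cross-validated prediction correlation
        (mean over channels and folds), then refit on all trials."""
        if lambdas is None:
            lambdas = np.logspace(-2, 6, 9)
        lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
        if np.any(lambdas < 0):
            raise ValueError("ridge penalties must be nonnegative")
        if lambdas.size > 1:
            cv_r = self._cv_correlations(lambdas, folds)
            best = int(np.argmax(np.nanmean(cv_r, axis=1)))
        else:
            cv_r = np.full((1, self.eeg.n_channels), np.nan)
            best = 0
        lam = float(lambdas[best])
        XtX, XtY = self._accumulate(np.arange(self.eeg.n_trials))
        (W,) = self._solve_ridge(XtX, XtY, [lam])
        oof_r = (
            self._cv_correlations([lam], folds)[0]
            if self.eeg.n_trials >= folds >= 2
            else cv_r[best]
        )
        return TRFResult(
            model=self,
            weights=W.T,  # (n_channels, n_lags)
            ridge_lambda=lam,
            lambdas=lambdas,
            cv_r=oof_r,
            folds=folds,
        )


def _columnwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per column between two (n_samples, n_cols) arrays."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    out = np.zeros(a.shape[1])
    ok = denom > 0
    out[ok] = (a * b).sum(axis=0)[ok] / denom[ok]
    return out


class TRFResult:
    """Fitted TRF weights with the selected penalty and CV accuracies."""

    def __init__(self, model, weights, ridge_lambda, lambdas, cv_r, folds) -> None:
        self.model = model
        self.weights = weights  # (n_channels, n_lags)
        self.ridge_lambda = ridge_lambda
        self.lambdas = lambdas
        self.cv_r = np.asarray(cv_r, dtype=float)
        self.folds = folds

    @property
    def lags_ms(self) -> np.ndarray:
        return self.model.lags / self.model.fs * 1e3

    def predict(self, reg: Regressor) -> np.ndarray:
        """Predicted EEG (n_channels, n_samples) for one regressor trial."""
        if reg.fs != self.model.fs:
            raise ValueError("regressor sampling rate differs from the model")
        X = _design_matrix(reg.series, self.model.lags)
        return (X @ self.weights.T).T

    def summary(self) -> str:
        import pandas as pd

        lines = [
            "Temporal response function (ridge)",
            "=" * 36,
            f"channels:        {self.weights.shape[0]}",
            f"lags:            [{self.lags_ms[0]:.0f}, {self.lags_ms[1]:.0f}] ... "
            f"{self.lags_ms[-1]:.0f} ms ({self.weights.shape[1]} samples)",
            f"ridge lambda:    {self.ridge_lambda:g} "
            f"(grid {self.lambdas.min():g} ... {self.lambdas.max():g})",
            f"CV folds:        {self.folds}",
            f"mean CV r:       {np.nanmean(self.cv_r):.4f}",
        ]
        tab = pd.DataFrame({"cv_r": self.cv_r})
        tab.index.name = "channel"
        lines += ["", tab.to_string(float_format="%.4f")]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lags_ms, self.weights.T, lw=0.7)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("TRF weight")
        return ax


def fit_trf(
    regressors: list[Regressor],
    eeg: EEGTrialSet,
    lags_ms: tuple[float, float] = (-50.0, 400.0),
    lambdas: np.ndarray | None = None,
    folds: int = 10,
) -> TRFResult:
    """Functional wrapper: build and fit a :class:`TemporalResponseFunction`."""
    return TemporalResponseFunction(regressors, eeg, lags_ms).fit(lambdas, folds)


def trf_predict_cv(
    regressors: list[Regressor],
    eeg: EEGTrialSet,
    lags_ms: tuple[float, float] = (-50.0, 400.0),
    ridge_lambda: float = 1.0,
    folds: int = 10,
) -> np.ndarray:
    """Out-of-fold prediction correlation per channel at a fixed penalty."""
    model = TemporalResponseFunction(regressors, eeg, lags_ms)
    return model._cv_correlations([ridge_lambda], folds)[0]


def trf_weight_correlation(
    a: TRFResult, b: TRFResult, window_ms: tuple[float, float] = (0.0, 360.0)
) -> np.ndarray:
    """Pearson r per channel between two TRFs over a lag window."""
    if a.weights.shape != b.weights.shape or a.model.fs != b.model.fs:
        raise ValueError("TRFs must share channels and lag axis")
    if not np.array_equal(a.model.lags, b.model.lags):
        raise ValueError("TRFs must share the lag grid")
    mask = (a.lags_ms >= window_ms[0] - 1e-9) & (a.lags_ms <= window_ms[1] + 1e-9)
    if not mask.any():
        raise ValueError("window contains no lags")
    return _columnwise_r(a.weights[:, mask].T, b.weights[:, mask].T)


def cortical_deconvolution(
    regs: list[Regressor],
    eeg32: EEGTrialSet,
    weights: TrialWeights | None = None,
    window: tuple[float, float] = (-0.2, 0.6),
    lag_ms: float | None = None,
) -> EvokedResponse:
    """Frequency-domain deconvolution applied independently per channel.

    Returns a multichannel :class:`EvokedResponse` (kernel shape
    ``(n_channels, n_lags)``).  No downsampling happens on this path, so
    early and late response components share one lag axis.
    """
    resp = unwrap_circular(deconvolve(regs, eeg32, weights), window)
    comp = lag_ms if lag_ms is not None else regs[0].lag_ms
    if comp:
        resp = compensate_lag(resp, comp)
    return resp


def global_field_power(resp: EvokedResponse) -> np.ndarray:
    """Across-channel standard deviation of a multichannel response at each lag."""
    if resp.kernel.ndim != 2 or resp.kernel.shape[0] < 2:
        raise ValueError("global field power needs at least two channels")
    return resp.kernel.std(axis=0)
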