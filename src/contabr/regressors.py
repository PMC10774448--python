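"""Deconvolution regressors: half-wave rectified stimulus (HWR) and
auditory-nerve-model firing rate (ANM).

The ANM path runs the calibrated pressure waveform through an auditory
periphery model on a grid of characteristic frequencies (125 Hz to 16 kHz
at 1/6-octave steps by default), sums the instantaneous firing rate over
CFs, and downsamples the sum to the EEG rate.  The periphery model is a
pluggable contract: :class:`SimplePeriphery` is the built-in
phenomenological model (nonlinear tuning, compression, adaptation);
:class:`ZilanyPeriphery` adapts the published Zilany et al. model when its
Python port is installed.

Because the periphery introduces its own latency, the lag between a click
and the summed rate is measured by cross-correlation and carried on the
regressor so the deconvolved response can be shifted right by that amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import Regressor, StimulusTrial
from .stimulus import resample_poly_series

__all__ = [
    "PeripheryConfig",
    "SimplePeriphery",
    "ZilanyPeriphery",
    "cf_grid",
    "calibrate_spl",
    "hwr_regressor",
    "anm_regressor",
    "estimate_lag",
]

P_REF = 20e-6  # reference pressure, Pa


@dataclass
class PeripheryConfig:
    """Characteristic-frequency grid and presentation level for the periphery model."""

    cf_lo: float = 125.0
    cf_hi: float = 16000.0
    cf_step_octaves: float = 1.0 / 6.0
    level_db_spl: float = 65.0
    fiber_type: str = "high-spontaneous-rate"
    model_fs: float = 100_000.0

    def __post_init__(self) -> None:
        if not 0 < self.cf_lo < self.cf_hi:
            raise ValueError("need 0 < cf_lo < cf_hi")
        if self.cf_step_octaves <= 0:
            raise ValueError("cf_step_octaves must be positive")
        if self.model_fs <= 2 * self.cf_hi:
            raise ValueError("model_fs must exceed twice the highest CF")


def cf_grid(cfg: PeripheryConfig) -> np.ndarray:
    """Geometric CF grid from cf_lo to cf_hi inclusive (both endpoints kept)."""
    n = int(np.floor(np.log2(cfg.cf_hi / cfg.cf_lo) / cfg.cf_step_octaves + 1e-9))
    return cfg.cf_lo * 2.0 ** (cfg.cf_step_octaves * np.arange(n + 1))


def calibrate_spl(trial: StimulusTrial, level_db_spl: float = 65.0) -> StimulusTrial:
    """Scale the waveform to a pressure in pascals at the given SPL.

    Output RMS equals ``20e-6 * 10**(level/20)`` Pa regardless of the input
    scale (scale-invariant).
    """
    rms = float(np.sqrt(np.mean(trial.samples**2)))
    if rms == 0.0:
        raise ValueError("zero-RMS input cannot be calibrated")
    target = P_REF * 10.0 ** (level_db_spl / 20.0)
    return trial.copy_with(samples=trial.samples * (target / rms))


def hwr_regressor(
    trial: StimulusTrial, fs_out: float = 10_000.0
) -> tuple[Regressor, Regressor]:
    """Half-wave rectified regressors: positive halves and sign-inverted
    negative halves, each anti-alias downsampled to ``fs_out``.

    Resampling ringing can dip slightly below zero; the output is clipped
    at 0 afterwards.
    """
    if trial.n_channels != 1:
        raise ValueError("hwr_regressor expects a mono trial")
    if fs_out > trial.fs:
        raise ValueError("fs_out must not exceed the stimulus rate")
    x = trial.samples
    out = []
    for sign, tag in ((1.0, "original"), (-1.0, "inverted")):
        rect = np.maximum(sign * x, 0.0)
        series = np.maximum(resample_poly_series(rect, trial.fs, fs_out), 0.0)
        out.append(
            Regressor(
                series,
                fs_out,
                kind="HWR",
                lag_ms=0.0,
                polarity=tag,
                label=trial.label,
                trial_index=trial.trial_index,
            )
        )
    return out[0], out[1]


class SimplePeriphery:
    """Phenomenological auditory-periphery model.

    Stages per characteristic frequency:

    1. gammatone band-pass (4th order, all-pole cascade, Glasberg-Moore ERB
       bandwidth scaled by 1.019) — nonlinear tuning is approximated by a
       fixed filter; level-dependent tuning is not modelled;
    2. rectifying, compressive inner-hair-cell transduction
       ``log1p(c * max(v, 0))`` giving rate saturation;
    3. 2nd-order 3 kHz low-pass (IHC membrane), causal;
    4. divisive adaptation: the drive is divided by ``1 + k * s`` where
       ``s`` is the drive smoothed with a 60 ms one-pole — onset overshoot
       and post-stimulus suppression;
    5. a fixed 0.7 ms synaptic delay and a high-spontaneous-rate floor.

    Output is instantaneous firing rate in spikes/s, nonnegative.
    """

    def __init__(
        self,
        compression: float = 200.0,
        ihc_lowpass_hz: float = 3000.0,
        adaptation_tau_s: float = 0.060,
        adaptation_strength: float = 2.0,
        synaptic_delay_s: float = 0.0007,
        spont_rate: float = 50.0,
        driven_gain: float = 500.0,
    ) -> None:
        self.compression = compression
        self.ihc_lowpass_hz = ihc_lowpass_hz
        self.adaptation_tau_s = adaptation_tau_s
        self.adaptation_strength = adaptation_strength
        self.synaptic_delay_s = synaptic_delay_s
        self.spont_rate = spont_rate
        self.driven_gain = driven_gain

    @staticmethod
    def _erb(cf: float) -> float:
        return 24.7 * (4.37 * cf / 1000.0 + 1.0)

    def _gammatone(self, x: np.ndarray, fs: float, cf: float) -> np.ndarray:
        """4th-order all-pole gammatone, unit gain at CF."""
        b = 1.019 * self._erb(cf)
        pole = np.exp((-2 * np.pi * b + 2j * np.pi * cf) / fs)
        y = x.astype(complex)
        r = np.abs(pole)
        for _ in range(4):
            y = signal.lfilter([1.0 - r], [1.0, -pole], y)
        return 2.0 * np.real(y)

    def rates(self, pressure: np.ndarray, fs: float, cfs: np.ndarray) -> np.ndarray:
        """Per-CF instantaneous firing rate, shape (n_cf, n_samples)."""
        pressure = np.asarray(pressure, dtype=float)
        sos_ihc = signal.butter(
            2, self.ihc_lowpass_hz / (fs / 2.0), btype="low", output="sos"
        )
        # one-pole smoother for the adaptation state
        a_ad = np.exp(-1.0 / (self.adaptation_tau_s * fs))
        delay_n = int(round(self.synaptic_delay_s * fs))
        out = np.empty((cfs.size, pressure.size))
        for i, cf in enumerate(cfs):
            v = self._gammatone(pressure, fs, cf)
            drive = np.log1p(self.compression * np.maximum(v, 0.0))
            drive = np.maximum(signal.sosfilt(sos_ihc, drive), 0.0)
            state = signal.lfilter([1.0 - a_ad], [1.0, -a_ad], drive)
            adapted = drive / (1.0 + self.adaptation_strength * state)
            rate = self.spont_rate + self.driven_gain * adapted
            if delay_n:
                rate = np.r_[np.full(delay_n, self.spont_rate), rate[:-delay_n]]
            out[i] = rate
        return out


class ZilanyPeriphery:
    """Adapter to the published Zilany et al. auditory-nerve model.

    Requires the ``cochlea`` Python port; raises ImportError with guidance
    when it is not installed.  High-spontaneous-rate fibers only.
    """

    def __init__(self, species: str = "human") -> None:
        try:
            import cochlea  # type: ignore[import-not-found]
        except ImportError as err:  # pragma: no cover - optional backend
            raise ImportError(
                "The Zilany periphery backend needs the 'cochlea' package; "
                "install it or use SimplePeriphery instead."
            ) from err
        self._cochlea = cochlea
        self.species = species

    def rates(self, pressure, fs, cfs):  # pragma: no cover - optional backend
        if fs < 100_000:
            raise ValueError("the Zilany model requires fs >= 100 kHz")
        out = np.empty((len(cfs), len(pressure)))
        for i, cf in enumerate(cfs):
            rate = self._cochlea.run_zilany2014_rate(
                np.asarray(pressure, dtype=float),
                fs,
                anf_types=["hsr"],
                cf=float(cf),
                species=self.species,
            )
            out[i] = np.asarray(rate).ravel()
        return out


def _click_trial(fs: float, duration_s: float = 0.05, click_s: float = 1e-4) -> StimulusTrial:
    """Rectangular click (one polarity) padded with silence."""
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    onset = n // 4
    x[onset : onset + max(1, int(round(click_s * fs)))] = 1.0
    return StimulusTrial(x, fs, label="click")


def estimate_lag(click: StimulusTrial, reg: Regressor) -> float:
    """Lag (ms) of the cross-correlation peak between a click and a regressor.

    Both series are demeaned; only nonnegative lags are searched (the
    periphery is causal).  Raises on a flat regressor.
    """
    if click.fs != reg.fs:
        raise ValueError("click and regressor must share a sampling rate")
    x = click.samples - np.mean(click.samples)
    y = reg.series - np.mean(reg.series)
    if not np.any(y):
        raise ValueError("flat regressor: lag undefined")
    n = min(x.size, y.size)
    corr = signal.correlate(y[:n], x[:n], mode="full")
    lags = signal.correlation_lags(n, n, mode="full")
    nonneg = lags >= 0
    best = lags[nonneg][int(np.argmax(corr[nonneg]))]
    return float(best) / reg.fs * 1e3


def model_click_lag_ms(
    model, cfg: PeripheryConfig, fs_out: float = 10_000.0
) -> float:
    """Measure the periphery model's intrinsic click lag at the regressor rate."""
    click = _click_trial(cfg.model_fs)
    reg = anm_regressor(click, cfg, model=model, fs_out=fs_out, lag_ms=0.0)
    click_ds = StimulusTrial(
        resample_poly_series(click.samples, click.fs, fs_out), fs_out, label="click"
    )
    return estimate_lag(click_ds, reg)


def anm_regressor(
    trial: StimulusTrial,
    cfg: PeripheryConfig | None = None,
    model=None,
    fs_out: float = 10_000.0,
    polarity: str = "original",
    lag_ms: float | None = None,
) -> Regressor:
    """Auditory-nerve-model regressor: summed firing rate over the CF grid.

    The stimulus is upsampled to ``cfg.model_fs``, calibrated to pascals at
    ``cfg.level_db_spl``, optionally polarity-inverted, run through the
    periphery model at every CF, summed (unweighted) across CFs and
    anti-alias downsampled to ``fs_out``.  ``lag_ms`` defaults to the
    model's click lag measured by :func:`model_click_lag_ms`; pass a number
    to skip that measurement.
    """
    if trial.n_channels != 1:
        raise ValueError("anm_regressor expects a mono trial")
    cfg = cfg or PeripheryConfig()
    model = model if model is not None else SimplePeriphery()
    x = resample_poly_series(trial.samples, trial.fs, cfg.model_fs)
    if np.any(x):
        pressure = calibrate_spl(
            StimulusTrial(x, cfg.model_fs, label=trial.label), cfg.level_db_spl
        ).samples
    else:
        pressure = x  # silence stays silence; the model emits spontaneous rate
    if polarity == "inverted":
        pressure = -pressure
    elif polarity != "original":
        raise ValueError("polarity must be 'original' or 'inverted'")
    cfs = cf_grid(cfg)
    try:
        per_cf = model.rates(pressure, cfg.model_fs, cfs)
    except Exception as err:
        raise RuntimeError(f"periphery model failed on CF grid {cfs[0]:.0f}-"
                           f"{cfs[-1]:.0f} Hz: {err}") from err
    summed = per_cf.sum(axis=0)
    series = np.maximum(resample_poly_series(summed, cfg.model_fs, fs_out), 0.0)
    if lag_ms is None:
        lag_ms = model_click_lag_ms(model, cfg, fs_out)
    return Regressor(
        series,
        fs_out,
        kind="ANM",
        lag_ms=float(lag_ms),
        polarity=polarity,  # type: ignore[arg-type]
        label=trial.label,
        trial_index=trial.trial_index,
    )
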