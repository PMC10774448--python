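"""Core data containers shared across the pipeline.

Lightweight dataclasses wrapping numpy arrays with the sampling-rate and
provenance metadata each stage needs.  Units: stimulus samples are
dimensionless until SPL calibration converts them to pascals; EEG is in
volts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "StimulusTrial",
    "Regressor",
    "EEGTrialSet",
    "EvokedResponse",
    "TrialWeights",
    "BandPowerTable",
    "EnvelopeStats",
    "SNREstimate",
    "CoherenceSpectrum",
    "GroundTruthKernel",
    "NoiseModel",
]


def _as_float_array(x, name: str, allow_2d: bool = False) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if not allow_2d and arr.ndim != 1:
        if arr.ndim == 2 and 1 in arr.shape:
            arr = arr.ravel()
        else:
            raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class StimulusTrial:
    """One audio excerpt.

    ``samples`` may be 1-D (mono) or 2-D ``(n_channels, n_samples)`` for raw
    stereo input; every processing stage past :func:`to_mono_resample`
    expects mono.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples", allow_2d=True)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_samples == 0:
            raise ValueError("trial has zero duration")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    def copy_with(self, **kw) -> "StimulusTrial":
        return replace(self, **kw)


@dataclass
class Regressor:
    """Nonlinearly transformed stimulus used as the encoding-model input.

    ``lag_ms`` is the intrinsic delay the transform introduces between the
    acoustic waveform and the regressor (0 for half-wave rectification;
    measured by cross-correlation with a click for periphery models).  The
    deconvolved response is later shifted right by this amount.
    """

    series: np.ndarray
    fs: float
    kind: Literal["HWR", "ANM", "envelope"] = "HWR"
    lag_ms: float = 0.0
    polarity: Literal["original", "inverted"] = "original"
    label: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.series = _as_float_array(self.series, "series")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be nonnegative")
        if self.kind in ("HWR", "ANM") and np.any(self.series < 0):
            raise ValueError(f"{self.kind} regressor must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.series.size


@dataclass
class EEGTrialSet:
    """Per-trial EEG aligned to stimulus onsets.

    ``trials`` is ``(n_trials, n_channels, n_samples)`` in volts.  The
    subcortical montage carries the two earlobe-referenced channels (later
    averaged to one); the cortical montage carries 32 scalp channels.
    ``triggers`` holds per-trial ``(start_sample, drift_sample)`` pairs used
    for clock-drift correction.
    """

    trials: np.ndarray
    fs_nominal: float
    montage_role: Literal["subcortical", "cortical"] = "subcortical"
    fs_actual: float | None = None
    triggers: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.trials, dtype=float)
        if arr.ndim == 2:  # single-channel convenience: (n_trials, n_samples)
            arr = arr[:, None, :]
        if arr.ndim != 3:
            raise ValueError(
                "trials must be (n_trials, n_channels, n_samples), got shape "
                f"{arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("EEG contains non-finite values")
        self.trials = arr
        if self.fs_nominal <= 0:
            raise ValueError("fs_nominal must be positive")
        if self.fs_actual is None:
            self.fs_actual = float(self.fs_nominal)
        if abs(self.fs_actual - self.fs_nominal) > 0.01 * self.fs_nominal:
            raise ValueError("fs_actual deviates more than 1% from fs_nominal")
        if self.triggers is not None:
            trig = np.asarray(self.triggers, dtype=int)
            if trig.shape != (self.n_trials, 2):
                raise ValueError("triggers must be (n_trials, 2)")
            if np.any(trig[:, 1] <= trig[:, 0]):
                raise ValueError("drift trigger must follow the start trigger")
            self.triggers = trig

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def copy_with(self, **kw) -> "EEGTrialSet":
        return replace(self, **kw)


@dataclass
class TrialWeights:
    """Inverse-variance trial weights b_n = (1/sigma_n^2) / sum_m (1/sigma_m^2)."""

    variances: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.variances = _as_float_array(self.variances, "variances")
        self.weights = _as_float_array(self.weights, "weights")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @property
    def n_trials(self) -> int:
        return self.weights.size


@dataclass
class EvokedResponse:
    """Deconvolved kernel on a lag axis.

    ``kernel`` may be 1-D (single channel) or ``(n_channels, n_lags)``.
    ``t0`` is the time of the first sample in seconds so the lag axis is
    ``t0 + arange(n_lags)/fs``.
    """

    kernel: np.ndarray
    fs: float
    t0: float = 0.0
    lag_compensated_ms: float = 0.0
    n_trials: int = 0
    polarity_combined: bool = False

    def __post_init__(self) -> None:
        self.kernel = _as_float_array(self.kernel, "kernel", allow_2d=True)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_lags(self) -> int:
        return self.kernel.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_lags) / self.fs

    @property
    def lag_window(self) -> tuple[float, float]:
        return (self.t0, self.t0 + (self.n_lags - 1) / self.fs)

    def crop(self, t_min: float, t_max: float) -> "EvokedResponse":
        """Return the response restricted to lags in [t_min, t_max]."""
        t = self.times
        mask = (t >= t_min - 0.5 / self.fs) & (t <= t_max + 0.5 / self.fs)
        if not mask.any():
            raise ValueError("crop window contains no samples")
        first = int(np.argmax(mask))
        return replace(self, kernel=self.kernel[..., mask], t0=float(t[first]))

    def copy_with(self, **kw) -> "EvokedResponse":
        return replace(self, **kw)


@dataclass
class BandPowerTable:
    """Per-trial band powers P_{n,k} and their across-trial means."""

    band_edges: np.ndarray  # (K, 2) low/high in Hz
    per_trial_power: np.ndarray  # (n_trials, K)
    mean_power: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        edges = np.asarray(self.band_edges, dtype=float)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("band_edges must be (K, 2)")
        if np.any(edges[:, 1] <= edges[:, 0]):
            raise ValueError("band edges must be strictly increasing")
        self.band_edges = edges
        self.per_trial_power = np.asarray(self.per_trial_power, dtype=float)
        self.mean_power = np.asarray(self.mean_power, dtype=float)
        if np.any(self.per_trial_power < 0) or np.any(self.mean_power < 0):
            raise ValueError("band powers must be nonnegative")
        if self.per_trial_power.shape[1] != edges.shape[0]:
            raise ValueError("power table width must equal the number of bands")

    @property
    def n_bands(self) -> int:
        return self.band_edges.shape[0]


@dataclass
class EnvelopeStats:
    """Broadband envelope with its marginal probability density."""

    envelope: np.ndarray
    fs: float
    sigma_e: float
    density: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.envelope = _as_float_array(self.envelope, "envelope")
        self.density = _as_float_array(self.density, "density")
        self.bin_edges = _as_float_array(self.bin_edges, "bin_edges")
        if np.any(self.envelope < -1e-12):
            raise ValueError("envelope must be nonnegative")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be nonnegative")
        widths = np.diff(self.bin_edges)
        total = float(np.sum(self.density * widths))
        if abs(total - 1.0) > 1e-6:
            raise ValueError("density must integrate to 1")

    @property
    def mode(self) -> float:
        """Center of the highest-density histogram bin."""
        i = int(np.argmax(self.density))
        return float(0.5 * (self.bin_edges[i] + self.bin_edges[i + 1]))


@dataclass
class SNREstimate:
    """Evoked-response SNR; ``snr_db`` is None when the signal estimate is negative."""

    snr_db: float | None
    signal_variance: float
    noise_variance: float
    signal_window_ms: tuple[float, float] = (0.0, 15.0)
    noise_window_ms: tuple[float, float] = (-200.0, -20.0)
    segment_ms: float = 15.0

    @property
    def defined(self) -> bool:
        return self.snr_db is not None


@dataclass
class CoherenceSpectrum:
    """Complex spectral coherence per frequency bin, with optional noise floor."""

    freqs: np.ndarray
    coherence: np.ndarray
    n_slices: int
    noise_floor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = _as_float_array(self.freqs, "freqs")
        coh = np.asarray(self.coherence, dtype=complex)
        if np.any(np.abs(coh) > 1 + 1e-9):
            raise ValueError("|coherence| must not exceed 1")
        self.coherence = coh

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coherence)


@dataclass
class GroundTruthKernel:
    """Synthetic impulse response built from Gaussian bumps.

    ``components`` is a list of ``(latency_ms, width_ms, amplitude)``; widths
    are Gaussian standard deviations.  Stands in for the brainstem waves and
    slow cortical deflections when simulating EEG.
    """

    components: list[tuple[float, float, float]]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for lat, width, _amp in self.components:
            if width <= 0:
                raise ValueError("bump widths must be positive")

    def render(self, duration_s: float, t0: float = 0.0) -> np.ndarray:
        """Sample the kernel on ``t0 + arange(n)/fs`` over ``duration_s`` seconds."""
        n = int(round(duration_s * self.fs))
        t_ms = (t0 + np.arange(n) / self.fs) * 1e3
        out = np.zeros(n)
        for lat, width, amp in self.components:
            out += amp * np.exp(-0.5 * ((t_ms - lat) / width) ** 2)
        return out


@dataclass
class NoiseModel:
    """Additive EEG noise: 1/f^alpha background, mains harmonics, per-trial scale."""

    pink_exponent: float = 1.0
    line_freqs: tuple[float, ...] = (60.0, 120.0, 300.0)
    line_amplitudes: tuple[float, ...] = (1.0, 0.3, 0.1)
    per_trial_variance_range: tuple[float, float] = (1.0, 10.0)
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.per_trial_variance_range
        if lo <= 0 or hi < lo:
            raise ValueError("per_trial_variance_range must be positive and ordered")
        if len(self.line_freqs) != len(self.line_amplitudes):
            raise ValueError("line_freqs and line_amplitudes must align")
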