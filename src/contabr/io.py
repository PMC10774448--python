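"""Reading and writing the pipeline's on-disk formats.

Audio goes through WAV (PCM16/24 or float32, via scipy).  EEG fixtures use
a simple array container: a ``.npy`` file with shape (n_trials, n_channels,
n_samples) plus a JSON sidecar holding the sampling rate, montage role and
per-trial trigger samples.  Regressors and evoked responses are saved the
same way (array + JSON metadata).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .containers import EEGTrialSet, EvokedResponse, Regressor, StimulusTrial

__all__ = [
    "read_wav",
    "write_wav",
    "write_eeg_fixture",
    "read_eeg_fixture",
    "write_regressor",
    "read_regressor",
    "write_evoked",
    "read_evoked",
]


def read_wav(path, label: str = "", trial_index: int = 0) -> StimulusTrial:
    """Read a WAV file; integer PCM is scaled to [-1, 1]."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:  # wavfile uses (n_samples, n_channels)
        data = data.T
    return StimulusTrial(data, float(fs), label=label, trial_index=trial_index)


def write_wav(path, trial: StimulusTrial) -> None:
    data = trial.samples.astype(np.float32)
    if data.ndim == 2:
        data = data.T
    wavfile.write(path, int(round(trial.fs)), data)


def write_eeg_fixture(directory, eeg: EEGTrialSet, name: str = "eeg") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", eeg.trials)
    meta = {
        "fs_nominal": eeg.fs_nominal,
        "fs_actual": eeg.fs_actual,
        "montage_role": eeg.montage_role,
        "triggers": eeg.triggers.tolist() if eeg.triggers is not None else None,
    }
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=1))


def read_eeg_fixture(directory, name: str = "eeg") -> EEGTrialSet:
    directory = Path(directory)
    trials = np.load(directory / f"{name}.npy")
    meta = json.loads((directory / f"{name}.json").read_text())
    triggers = meta.get("triggers")
    return EEGTrialSet(
        trials,
        fs_nominal=meta["fs_nominal"],
        montage_role=meta["montage_role"],
        fs_actual=meta.get("fs_actual"),
        triggers=np.asarray(triggers, dtype=int) if triggers is not None else None,
    )


def write_regressor(directory, reg: Regressor, name: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", reg.series)
    meta = {
        "fs": reg.fs,
        "kind": reg.kind,
        "lag_ms": reg.lag_ms,
        "polarity": reg.polarity,
        "label": reg.label,
        "trial_index": reg.trial_index,
    }
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=1))


def read_regressor(directory, name: str) -> Regressor:
    directory = Path(directory)
    series = np.load(directory / f"{name}.npy")
    meta = json.loads((directory / f"{name}.json").read_text())
    return Regressor(series, **meta)


def write_evoked(directory, resp: EvokedResponse, name: str = "response") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", resp.kernel)
    meta = {
        "fs": resp.fs,
        "t0": resp.t0,
        "lag_compensated_ms": resp.lag_compensated_ms,
        "n_trials": resp.n_trials,
        "polarity_combined": resp.polarity_combined,
    }
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=1))


def read_evoked(directory, name: str = "response") -> EvokedResponse:
    directory = Path(directory)
    kernel = np.load(directory / f"{name}.npy")
    meta = json.loads((directory / f"{name}.json").read_text())
    return EvokedResponse(kernel, **meta)
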