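import numpy as np
import pytest

import contabr as cb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic recording shared by read-only tests."""
    return cb.simulate_abr_session(
        n_trials=6, duration_s=3.0, fs_stim=16_000.0, fs_eeg=4_000.0, seed=99
    )


def white_regressors(rng, n_trials, n, fs, kind="HWR"):
    """Rectified white-noise regressors (flat-ish spectrum, nonnegative)."""
    return [
        cb.Regressor(np.abs(rng.standard_normal(n)), fs, kind=kind)
        for _ in range(n_trials)
    ]


@pytest.fixture
def make_white_regressors(rng):
    def _make(n_trials=5, n=2048, fs=1000.0):
        return white_regressors(rng, n_trials, n, fs)

    return _make


def uniform_weights(n):
    return cb.TrialWeights(variances=np.ones(n), weights=np.full(n, 1.0 / n))
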