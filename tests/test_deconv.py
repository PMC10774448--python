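"""Frequency-domain deconvolution engine: weights, exact recovery, circular
unwrapping, polarity and category averaging, and the time-domain oracle."""

import numpy as np
import pytest
from scipy import fft as sp_fft
from scipy.linalg import circulant

import contabr as cb
from conftest import uniform_weights, white_regressors


def forward_circular(reg_series, kernel):
    n = reg_series.size
    return sp_fft.irfft(sp_fft.rfft(reg_series) * sp_fft.rfft(kernel, n=n), n=n)


class TestComputeWeights:
    def test_equal_variances_give_equal_weights(self):
        x = np.tile([1.0, -1.0], 50)
        eeg = cb.EEGTrialSet(np.tile(x, (4, 1, 1)), 100.0)
        w = cb.compute_weights(eeg)
        np.testing.assert_allclose(w.weights, 0.25)

    def test_inverse_variance_formula(self):
        # exact variances 1, 1, 2 -> weights 0.4, 0.4, 0.2
        base = np.tile([1.0, -1.0], 50)
        trials = np.stack([base, base, np.sqrt(2.0) * base])[:, None, :]
        w = cb.compute_weights(cb.EEGTrialSet(trials, 100.0))
        np.testing.assert_allclose(w.variances, [1.0, 1.0, 2.0])
        np.testing.assert_allclose(w.weights, [0.4, 0.4, 0.2])

    def test_single_trial_weight_is_one(self, rng):
        w = cb.compute_weights(cb.EEGTrialSet(rng.standard_normal((1, 1, 100)), 100.0))
        np.testing.assert_allclose(w.weights, [1.0])

    def test_zero_variance_trial_rejected(self):
        trials = np.stack([np.ones(100), np.random.default_rng(0).standard_normal(100)])
        with pytest.raises(ValueError, match="zero-variance"):
            cb.compute_weights(cb.EEGTrialSet(trials[:, None, :], 100.0))

    def test_weights_sum_to_one(self, rng):
        eeg = cb.EEGTrialSet(rng.standard_normal((7, 1, 500)) * rng.uniform(0.5, 3, (7, 1, 1)), 100.0)
        w = cb.compute_weights(eeg)
        assert abs(w.weights.sum() - 1.0) < 1e-12


class TestDeconvolve:
    fs = 10_000.0

    def test_identity_system_yields_unit_impulse(self, rng):
        x = np.abs(rng.standard_normal(2048))
        reg = cb.Regressor(x, self.fs)
        eeg = cb.EEGTrialSet(x[None, None, :], self.fs)
        resp = cb.deconvolve([reg], eeg)
        peak = resp.kernel[0]
        assert peak == pytest.approx(1.0, abs=1e-9)
        assert np.sum(resp.kernel[1:] ** 2) < 1e-6 * peak**2

    def test_pure_circular_delay_appears_at_its_lag(self, rng):
        x = np.abs(rng.standard_normal(4096))
        y = np.roll(x, 80)  # +8 ms at 10 kHz
        resp = cb.deconvolve([cb.Regressor(x, self.fs)],
                             cb.EEGTrialSet(y[None, None, :], self.fs))
        assert np.argmax(resp.kernel) == 80
        assert resp.times[80] == pytest.approx(0.008)

    def test_known_kernel_recovered_from_ten_noiseless_trials(self, rng):
        n, fs = 4096, 1000.0
        kernel = cb.GroundTruthKernel([(40.0, 6.0, 1.0), (120.0, 15.0, -0.6)], fs).render(n / fs)
        regs = white_regressors(rng, 10, n, fs)
        eeg = cb.EEGTrialSet(
            np.stack([forward_circular(r.series, kernel) for r in regs])[:, None, :], fs
        )
        resp = cb.deconvolve(regs, eeg, uniform_weights(10))
        r = np.corrcoef(resp.kernel, kernel)[0, 1]
        assert r > 0.999

    def test_matches_time_domain_circular_least_squares(self, rng):
        # brute-force oracle on tiny instances: stack circulant design
        # matrices and solve ordinary least squares
        n, fs, n_trials = 256, 1000.0, 3
        regs = white_regressors(rng, n_trials, n, fs)
        ys = [rng.standard_normal(n) for _ in range(n_trials)]
        eeg = cb.EEGTrialSet(np.stack(ys)[:, None, :], fs)
        resp = cb.deconvolve(regs, eeg, uniform_weights(n_trials))
        design = np.vstack([circulant(r.series) for r in regs])
        target = np.concatenate(ys)
        oracle, *_ = np.linalg.lstsq(design, target, rcond=None)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(resp.kernel - oracle)) < 1e-8 * max(scale, 1.0)

    def test_linear_in_the_eeg(self, rng):
        n, fs = 1024, 1000.0
        regs = white_regressors(rng, 4, n, fs)
        w = uniform_weights(4)
        y1 = rng.standard_normal((4, 1, n))
        y2 = rng.standard_normal((4, 1, n))
        r1 = cb.deconvolve(regs, cb.EEGTrialSet(y1, fs), w).kernel
        r2 = cb.deconvolve(regs, cb.EEGTrialSet(y2, fs), w).kernel
        r12 = cb.deconvolve(regs, cb.EEGTrialSet(2 * y1 - 0.5 * y2, fs), w).kernel
        np.testing.assert_allclose(r12, 2 * r1 - 0.5 * r2, atol=1e-9)

    def test_inverse_variance_weighting_beats_uniform(self, rng):
        # heteroscedastic noise spanning 10x in variance
        n, fs, n_trials, n_reps = 512, 1000.0, 8, 100
        kernel = cb.GroundTruthKernel([(40.0, 6.0, 1.0)], fs).render(n / fs)
        wins = 0
        for _ in range(n_reps):
            regs = white_regressors(rng, n_trials, n, fs)
            sigma2 = rng.uniform(1.0, 10.0, n_trials)
            ys = np.stack([
                forward_circular(r.series, kernel)
                + np.sqrt(s2) * rng.standard_normal(n)
                for r, s2 in zip(regs, sigma2)
            ])[:, None, :]
            eeg = cb.EEGTrialSet(ys, fs)
            k_w = cb.deconvolve(regs, eeg, cb.compute_weights(eeg)).kernel
            k_u = cb.deconvolve(regs, eeg, uniform_weights(n_trials)).kernel
            if np.mean((k_w - kernel) ** 2) < np.mean((k_u - kernel) ** 2):
                wins += 1
        assert wins >= 95


class TestUnwrapCircular:
    fs = 1000.0

    def _impulse_resp(self, pos, n=2000):
        k = np.zeros(n)
        k[pos] = 1.0
        return cb.EvokedResponse(k, self.fs)

    def test_zero_lag_impulse_stays_at_zero(self):
        out = cb.unwrap_circular(self._impulse_resp(0), (-0.2, 0.6))
        assert out.times[np.argmax(out.kernel)] == pytest.approx(0.0)

    def test_tail_energy_becomes_negative_lag(self):
        n = 2000
        out = cb.unwrap_circular(self._impulse_resp(n - 50), (-0.2, 0.6))
        assert out.times[np.argmax(out.kernel)] == pytest.approx(-0.05)

    def test_reindexing_conserves_energy(self, rng):
        k = rng.standard_normal(2000)
        resp = cb.EvokedResponse(k, self.fs)
        out = cb.unwrap_circular(resp, (-1.0, 1.0 - 1 / self.fs))
        assert np.sum(out.kernel**2) == pytest.approx(np.sum(k**2))

    def test_window_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="window"):
            cb.unwrap_circular(self._impulse_resp(0), (-2.0, 2.0))


class TestLagAndAveraging:
    fs = 1000.0

    def test_lag_compensation_shifts_latencies(self):
        k = np.zeros(100)
        k[:] = 0.0
        resp = cb.EvokedResponse(k, 10_000.0, t0=0.0)
        resp.kernel[int(0.00525 * 10_000)] = 1.0
        out = cb.compensate_lag(resp, 2.75)
        assert out.times[np.argmax(out.kernel)] * 1e3 == pytest.approx(8.0, abs=0.06)

    def test_double_compensation_guarded(self):
        resp = cb.EvokedResponse(np.zeros(10) + 1.0, self.fs)
        once = cb.compensate_lag(resp, 2.75)
        with pytest.raises(ValueError, match="already"):
            cb.compensate_lag(once, 2.75)

    def test_zero_lag_is_identity(self):
        resp = cb.EvokedResponse(np.arange(10.0), self.fs)
        out = cb.compensate_lag(resp, 0.0)
        assert out.t0 == resp.t0

    def test_polarity_average_cancels_artifact(self, rng):
        h = rng.standard_normal(500)
        a = rng.standard_normal(500)
        pos = cb.EvokedResponse(h + a, self.fs)
        neg = cb.EvokedResponse(h - a, self.fs)
        out = cb.combine_polarities(pos, neg)
        np.testing.assert_allclose(out.kernel, h, atol=1e-12)
        assert out.polarity_combined

    def test_polarity_axis_mismatch_rejected(self):
        a = cb.EvokedResponse(np.zeros(100) + 1.0, self.fs, t0=0.0)
        b = cb.EvokedResponse(np.zeros(100) + 1.0, self.fs, t0=0.05)
        with pytest.raises(ValueError, match="axis"):
            cb.combine_polarities(a, b)

    def test_category_average_of_opposites_is_zero(self, rng):
        h = rng.standard_normal(200)
        out = cb.average_category(
            [cb.EvokedResponse(h, self.fs), cb.EvokedResponse(-h, self.fs)]
        )
        np.testing.assert_allclose(out.kernel, 0.0, atol=1e-12)

    def test_six_way_average_gains_sixfold_variance_reduction(self, rng):
        h = np.sin(2 * np.pi * 5 * np.arange(2000) / self.fs)
        noises = rng.standard_normal((6, 2000))
        resps = [cb.EvokedResponse(h + n, self.fs) for n in noises]
        avg = cb.average_category(resps)
        residual = avg.kernel - h
        single_noise_var = np.mean([np.var(n) for n in noises])
        assert np.var(residual) == pytest.approx(single_noise_var / 6.0, rel=0.15)


class TestAbrDeconvolutionModel:
    def test_fit_recovers_planted_kernel_and_reports(self, small_session):
        from contabr.preprocess import filter_subcortical
        from contabr.synthetic import truth_on_lag_axis

        ses = small_session
        eeg = cb.reference_subcortical(cb.filter_subcortical(ses.eeg))
        result = cb.AbrDeconvolution(eeg, ses.regressors).fit(window=(-0.2, 0.3))
        truth = truth_on_lag_axis(ses.truth, result.response, filter_fn=filter_subcortical)
        r = cb.waveform_correlation(result.response, truth, window_ms=(0.0, 200.0))
        assert r > 0.8
        text = result.summary()
        assert "trials" in text and "lag window" in text

    def test_fit_with_both_polarities_combines_them(self, rng):
        fs, n = 1000.0, 2000
        x = rng.standard_normal(n)
        pos = cb.Regressor(np.maximum(x, 0), fs)
        neg = cb.Regressor(np.maximum(-x, 0), fs)
        y = forward_circular(pos.series, cb.GroundTruthKernel([(30, 5, 1.0)], fs).render(n / fs))
        eeg = cb.EEGTrialSet(y[None, None, :], fs)
        res = cb.AbrDeconvolution(eeg, {"original": [pos], "inverted": [neg]}).fit(
            window=(-0.1, 0.3)
        )
        assert res.response.polarity_combined
        assert set(res.by_polarity) == {"original", "inverted"}
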