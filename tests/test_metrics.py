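"""Response SNR, waveform/split-set/noise-adjusted correlations, EEG
prediction and spectral coherence with its mismatched noise floor."""

import numpy as np
import pytest

import contabr as cb


def _resp_with_variances(var_signal, var_noise, fs=10_000.0, seed=0):
    """Response whose [0,15] ms window and baseline have set variances."""
    rng = np.random.default_rng(seed)
    t0 = -0.2
    n = int(0.25 * fs)
    k = rng.standard_normal(n)
    times = t0 + np.arange(n) / fs
    base = (times >= -0.2) & (times <= -0.02)
    sig = (times >= 0.0) & (times <= 0.015)
    k[base] *= np.sqrt(var_noise) / np.std(k[base])
    k[sig] *= np.sqrt(var_signal) / np.std(k[sig])
    return cb.EvokedResponse(k, fs, t0=t0)


class TestResponseSnr:
    def test_zero_db_when_signal_equals_noise_power(self):
        est = cb.response_snr(_resp_with_variances(2.0, 1.0))
        assert est.defined
        assert est.snr_db == pytest.approx(0.0, abs=0.5)

    def test_closed_form_nine_to_one(self):
        est = cb.response_snr(_resp_with_variances(10.0, 1.0))
        assert est.snr_db == pytest.approx(10 * np.log10(9.0), abs=0.5)

    def test_undefined_when_no_signal_exceeds_noise(self):
        est = cb.response_snr(_resp_with_variances(0.5, 1.0))
        assert not est.defined and est.snr_db is None

    def test_scale_invariance(self):
        resp = _resp_with_variances(10.0, 1.0)
        est1 = cb.response_snr(resp)
        est2 = cb.response_snr(resp.copy_with(kernel=resp.kernel * 7.3))
        assert est1.snr_db == pytest.approx(est2.snr_db)

    def test_missing_baseline_rejected(self):
        resp = cb.EvokedResponse(np.zeros(200) + 1.0, 10_000.0, t0=0.0)
        with pytest.raises(ValueError, match="window"):
            cb.response_snr(resp)


class TestWaveformCorrelation:
    fs = 10_000.0

    def _resp(self, k):
        return cb.EvokedResponse(k, self.fs, t0=-0.01)

    def test_self_correlation_is_one(self, rng):
        a = self._resp(rng.standard_normal(400))
        assert cb.waveform_correlation(a, a) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        k = rng.standard_normal(400)
        r = cb.waveform_correlation(self._resp(k), self._resp(-k))
        assert r == pytest.approx(-1.0)

    def test_attenuation_matches_simulation_oracle(self, rng):
        # shared kernel + independent noise on both sides at SNR 4:
        # E[r] ~ 1 / (1 + 1/SNR)
        snr = 4.0
        n = 151  # [0, 15] ms window length
        rs = []
        for _ in range(400):
            h = rng.standard_normal(400)
            a = h + rng.standard_normal(400) / np.sqrt(snr)
            b = h + rng.standard_normal(400) / np.sqrt(snr)
            rs.append(cb.waveform_correlation(self._resp(a), self._resp(b)))
        assert np.mean(rs) == pytest.approx(1.0 / (1.0 + 1.0 / snr), abs=0.02)

    def test_zero_variance_rejected(self):
        flat = self._resp(np.ones(400))
        with pytest.raises(ValueError, match="zero-variance"):
            cb.waveform_correlation(flat, flat)


class TestSplitSetCorrelation:
    fs = 10_000.0

    def _resps(self, arrays):
        return [cb.EvokedResponse(a, self.fs, t0=-0.01) for a in arrays]

    def test_noiseless_identical_responses_split_at_one(self, rng):
        h = rng.standard_normal(400)
        classes = {"music": self._resps([h] * 4), "speech": self._resps([h] * 4)}
        rs = cb.split_set_correlation(classes, n_splits=20, seed=0)
        np.testing.assert_allclose(rs, 1.0)

    def test_pure_noise_splits_near_zero(self, rng):
        classes = {
            "music": self._resps(rng.standard_normal((10, 400))),
            "speech": self._resps(rng.standard_normal((10, 400))),
        }
        rs = cb.split_set_correlation(classes, n_splits=200, seed=1)
        assert abs(np.median(rs)) < 0.15

    def test_calibrated_snr_matches_attenuation_prediction(self, rng):
        # each half-average of m responses at per-response SNR s has SNR m*s
        s, m = 1.0, 8
        h = rng.standard_normal(400)
        h /= np.std(h)
        resps = self._resps(h + rng.standard_normal((2 * m, 400)) / np.sqrt(s))
        rs = cb.split_set_correlation({"all": resps}, n_splits=200, seed=2)
        expected = 1.0 / (1.0 + 1.0 / (m * s))
        assert np.median(rs) == pytest.approx(expected, abs=0.08)

    def test_seeded_and_reproducible(self, rng):
        classes = {"m": self._resps(rng.standard_normal((6, 300)))}
        a = cb.split_set_correlation(classes, n_splits=10, seed=7)
        b = cb.split_set_correlation(classes, n_splits=10, seed=7)
        np.testing.assert_array_equal(a, b)
        c = cb.split_set_correlation(classes, n_splits=10, seed=8)
        assert not np.array_equal(a, c)

    def test_odd_class_count_rejected(self, rng):
        classes = {"m": self._resps(rng.standard_normal((3, 300)))}
        with pytest.raises(ValueError, match="odd"):
            cb.split_set_correlation(classes, seed=0)


class TestNoiseAdjustedR:
    def test_published_worked_example(self):
        r_adj, r2_adj = cb.noise_adjusted_r(0.86, 0.90)
        assert round(r2_adj, 2) == 0.91
        # published r of 0.95 is the square root of the rounded r-squared
        assert r_adj == pytest.approx(np.sqrt(0.91), abs=0.01)

    def test_perfect_split_reliability(self):
        _, r2 = cb.noise_adjusted_r(0.5, 1.0)
        assert r2 == pytest.approx(0.25)

    def test_fully_explained_case(self):
        r_adj, _ = cb.noise_adjusted_r(0.5, 0.5)
        assert r_adj == pytest.approx(1.0)

    def test_self_adjustment_is_unity_for_any_positive_r(self):
        for r in (0.1, 0.37, 0.99):
            assert cb.noise_adjusted_r(r, r)[0] == pytest.approx(1.0)

    def test_nonpositive_split_rejected(self):
        with pytest.raises(ValueError):
            cb.noise_adjusted_r(0.5, 0.0)


class TestPredictEeg:
    fs = 1000.0

    def test_unit_impulse_kernel_reproduces_regressor(self, rng):
        n = 2000
        k = np.zeros(300)
        k[0] = 1.0
        kernel = cb.EvokedResponse(k, self.fs, t0=0.0)
        reg = cb.Regressor(np.abs(rng.standard_normal(n)), self.fs)
        pred = cb.predict_eeg(kernel, reg, kernel_window=(0.0, 0.2))
        np.testing.assert_allclose(pred, reg.series, atol=1e-12)

    def test_zero_kernel_predicts_zero(self, rng):
        kernel = cb.EvokedResponse(np.zeros(300), self.fs, t0=0.0)
        reg = cb.Regressor(np.abs(rng.standard_normal(500)), self.fs)
        np.testing.assert_allclose(cb.predict_eeg(kernel, reg), 0.0)

    def test_forward_model_round_trip(self, rng):
        n = 4000
        truth = cb.GroundTruthKernel([(40.0, 6.0, 1.0), (120.0, 20.0, -0.5)], self.fs)
        k = truth.render(0.2)
        reg = cb.Regressor(np.abs(rng.standard_normal(n)), self.fs)
        clean = np.convolve(reg.series, k)[:n]
        kernel = cb.EvokedResponse(k, self.fs, t0=0.0)
        pred = cb.predict_eeg(kernel, reg, kernel_window=(0.0, 0.2))
        r = np.corrcoef(pred[300:], clean[300:])[0, 1]
        assert r > 0.999

    def test_rate_mismatch_rejected(self, rng):
        kernel = cb.EvokedResponse(np.zeros(100) + 1.0, 500.0)
        reg = cb.Regressor(np.abs(rng.standard_normal(100)), 1000.0)
        with pytest.raises(ValueError, match="rate"):
            cb.predict_eeg(kernel, reg)


class TestPredictionCorrelation:
    def test_identity_is_one(self, rng):
        x = rng.standard_normal(1000)
        assert cb.prediction_correlation(x, x) == pytest.approx(1.0)

    def test_known_snr_closed_form(self, rng):
        # r = sqrt(signal var / total var) in expectation
        n = 100_000
        s = rng.standard_normal(n)
        noise = rng.standard_normal(n) * 2.0
        r = cb.prediction_correlation(s, s + noise)
        assert r == pytest.approx(np.sqrt(1.0 / (1.0 + 4.0)), abs=0.02)

    def test_independent_noise_is_null(self, rng):
        n = 20_000
        r = cb.prediction_correlation(rng.standard_normal(n), rng.standard_normal(n))
        assert abs(r) < 3.0 / np.sqrt(n)

    def test_highpass_is_applied_to_both_series(self, rng):
        fs = 1000.0
        n = 10_000
        t = np.arange(n) / fs
        shared_fast = rng.standard_normal(n)
        a = shared_fast + 5 * np.sin(2 * np.pi * 2 * t)
        b = shared_fast - 5 * np.sin(2 * np.pi * 2 * t)
        r_raw = cb.prediction_correlation(a, b)
        r_hp = cb.prediction_correlation(a, b, fs=fs, highpass_hz=40.0)
        assert r_hp > r_raw + 0.2  # slow anticorrelated part removed


class TestSpectralCoherence:
    fs = 1000.0

    def test_self_coherence_is_unity(self, rng):
        x = rng.standard_normal(4000)
        c = cb.spectral_coherence(x, x, self.fs)
        np.testing.assert_allclose(c.magnitude[c.freqs > 0], 1.0, atol=1e-12)
        assert c.freqs[1] == pytest.approx(1.0 / 0.2)

    def test_pure_delay_keeps_unit_magnitude_with_linear_phase(self):
        # periodic signal with the slice length as period: a roll is a
        # per-slice circular delay, so coherence magnitude must stay 1
        n_slice = 200
        base = np.sin(2 * np.pi * np.arange(n_slice) * 5 / n_slice) + \
            0.5 * np.sin(2 * np.pi * np.arange(n_slice) * 11 / n_slice)
        x = np.tile(base, 20)
        tau = 0.004
        y = np.roll(x, int(tau * self.fs))
        c = cb.spectral_coherence(x, y, self.fs)
        driven = np.isclose(c.freqs, 25.0) | np.isclose(c.freqs, 55.0)
        np.testing.assert_allclose(c.magnitude[driven], 1.0, atol=1e-9)
        phase = np.angle(c.coherence[driven])
        expected = -2 * np.pi * c.freqs[driven] * tau
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (phase - expected))), 0.0, atol=1e-9
        )

    def test_magnitude_never_exceeds_one(self, rng):
        x = rng.standard_normal(3000)
        y = 0.3 * x + rng.standard_normal(3000)
        c = cb.spectral_coherence(x, y, self.fs)
        assert np.all(c.magnitude <= 1.0 + 1e-9)

    def test_null_level_matches_brute_force_simulation(self, rng):
        # analytic-free oracle: simulate the null directly many times
        n_slices = 20
        n = n_slices * 200
        sims = [
            np.median(cb.spectral_coherence(
                rng.standard_normal(n), rng.standard_normal(n), self.fs
            ).magnitude[1:])
            for _ in range(30)
        ]
        meds = [
            np.median(cb.spectral_coherence(
                rng.standard_normal(n), rng.standard_normal(n), self.fs
            ).magnitude[1:])
            for _ in range(30)
        ]
        assert np.median(meds) == pytest.approx(np.median(sims), abs=0.05)

    def test_too_few_slices_rejected(self, rng):
        with pytest.raises(ValueError, match="slices"):
            cb.spectral_coherence(rng.standard_normal(150), rng.standard_normal(150), self.fs)


class TestCoherenceNoiseFloor:
    fs = 1000.0

    def _driven_pairs(self, rng, n_trials=4, n=4000):
        preds, eegs = [], []
        for _ in range(n_trials):
            p = rng.standard_normal(n)
            preds.append(p)
            eegs.append(p + 0.5 * rng.standard_normal(n))
        return preds, eegs

    def test_floor_sits_below_matched_coherence(self, rng):
        preds, eegs = self._driven_pairs(rng)
        floor = cb.coherence_noise_floor(preds, eegs, self.fs, seed=0)
        matched = np.median(
            [cb.spectral_coherence(p, e, self.fs).magnitude for p, e in zip(preds, eegs)],
            axis=0,
        )
        driven = slice(1, None)
        assert np.median(matched[driven]) > 2 * np.median(floor[driven])

    def test_floor_shrinks_with_more_slices(self, rng):
        short = self._driven_pairs(rng, n=2000)
        long = self._driven_pairs(rng, n=16_000)
        f_short = cb.coherence_noise_floor(*short, self.fs, seed=1)
        f_long = cb.coherence_noise_floor(*long, self.fs, seed=1)
        assert np.median(f_long[1:]) < np.median(f_short[1:])

    def test_reproducible_under_seed(self, rng):
        preds, eegs = self._driven_pairs(rng)
        a = cb.coherence_noise_floor(preds, eegs, self.fs, seed=3)
        b = cb.coherence_noise_floor(preds, eegs, self.fs, seed=3)
        np.testing.assert_array_equal(a, b)


class TestFindWaveV:
    fs = 10_000.0

    def _bump_resp(self, *bumps):
        k = cb.GroundTruthKernel(list(bumps), self.fs).render(0.02)
        return cb.EvokedResponse(k, self.fs, t0=0.0)

    def test_single_bump_latency_recovered(self):
        lat = cb.find_wave_v(self._bump_resp((8.0, 0.5, 1.0)))
        assert lat == pytest.approx(8.0, abs=0.1)

    def test_larger_of_two_bumps_wins(self):
        lat = cb.find_wave_v(self._bump_resp((7.0, 0.4, 1.0), (9.5, 0.4, 0.6)))
        assert lat == pytest.approx(7.0, abs=0.1)

    def test_flat_response_flags_no_peak(self):
        resp = cb.EvokedResponse(np.ones(300), self.fs, t0=0.0)
        assert cb.find_wave_v(resp) is None
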