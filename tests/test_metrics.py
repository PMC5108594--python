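"""Evaluation statistics: predictive power, coherence, contrast gain, blocks."""

import numpy as np
import pytest

from divs import (
    TrialSet,
    block_stats,
    coherence,
    contrast_ln_analysis,
    contrast_switching_stimulus,
    predictive_power,
)
from divs.stimulus import bandlimited_noise


class TestPredictivePower:
    def test_perfect_prediction_of_noiseless_trials(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal(3000)
        trials = np.tile(sig, (5, 1))
        assert np.isclose(predictive_power(sig, trials), 1.0)

    def test_independent_prediction_near_zero(self):
        rng = np.random.default_rng(1)
        sig = bandlimited_noise(3000, 1.0, 30.0, rng)
        trials = sig + rng.normal(0, 0.5, (10, 3000))
        pred = bandlimited_noise(3000, 1.0, 30.0, rng)  # unrelated signal
        assert abs(predictive_power(pred, trials)) < 0.05

    def test_true_signal_scores_one_despite_noise(self):
        # trials have explainable fraction ~0.6 but the true signal captures
        # all of the *explainable* variance
        rng = np.random.default_rng(2)
        sig = bandlimited_noise(3000, 1.0, 30.0, rng)
        noise_sd = np.sqrt(sig.var() * 0.4 / 0.6)
        trials = sig + rng.normal(0, noise_sd, (10, 3000))
        assert abs(predictive_power(sig, trials) - 1.0) < 0.05

    def test_single_trial_raises(self):
        with pytest.raises(ValueError):
            predictive_power(np.zeros(100), np.zeros((1, 100)))


class TestCoherence:
    def test_identical_prediction_gives_unity(self):
        rng = np.random.default_rng(3)
        sig = rng.standard_normal(4000)
        res = coherence(sig, np.tile(sig, (3, 1)), dt=1.0)
        assert np.allclose(res.gamma2, 1.0)
        assert np.all((res.gamma2 >= 0) & (res.gamma2 <= 1))

    def test_signal_plus_noise_matches_closed_form(self):
        # trials = common band-limited signal + white noise; in-band coherence
        # with the signal approaches SNR/(1+SNR)
        rng = np.random.default_rng(4)
        n = 60_000
        sig = bandlimited_noise(n, 1.0, 30.0, rng) * 2.0
        trials = np.stack([sig + rng.standard_normal(n) for _ in range(4)])
        res = coherence(sig, trials, dt=1.0)
        band = (res.freqs_hz > 2) & (res.freqs_hz < 28)
        # in-band signal PSD: variance 4 concentrated below 30 Hz of 500 Hz
        snr = 4.0 / (2 * 30.0 / 1000.0)  # signal PSD / unit white PSD
        expected = snr / (1.0 + snr)
        got = res.gamma2[band].mean()
        assert abs(got - expected) < 0.1
        assert np.all((res.gamma2 >= 0) & (res.gamma2 <= 1))
        assert np.all((res.noise_bound >= 0) & (res.noise_bound <= 1))

    def test_noise_bound_tracks_trial_consistency(self):
        rng = np.random.default_rng(5)
        sig = bandlimited_noise(20_000, 1.0, 30.0, rng)
        trials = np.stack([sig + 0.1 * rng.standard_normal(20_000) for _ in range(5)])
        res = coherence(sig, trials, dt=1.0)
        band = res.freqs_hz < 28
        assert res.noise_bound[band].mean() > 0.9

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            coherence(np.zeros(50), np.zeros((3, 60)))

    def test_omega_is_angular(self):
        rng = np.random.default_rng(6)
        sig = rng.standard_normal(2000)
        res = coherence(sig, np.tile(sig, (2, 1)), dt=1.0)
        assert np.allclose(res.omega, 2 * np.pi * res.freqs_hz)


@pytest.fixture(scope="module")
def cs_stim():
    return contrast_switching_stimulus(n_cycles=7, seed=13)


class TestContrastAdaptation:
    def test_linear_system_has_unit_contrast_gain(self, cs_stim, divs_truth):
        k = divs_truth.exc_filter.kernel[:, 0]
        rng = np.random.default_rng(7)
        resp = np.convolve(cs_stim.values[:, 0] - 1.0, k)[: cs_stim.n_bins]
        resp = resp + rng.normal(0, resp.std() * 0.05, len(resp))
        res = contrast_ln_analysis(cs_stim, resp)
        assert abs(res.contrast_gain - 1.0) < 0.05
        # a linear system's aligned filters also share the biphasic index
        assert abs(res.biphasic_index["HC"] - res.biphasic_index["LC"]) < 0.1

    def test_biphasic_index_matches_kernel_extremes(self, cs_stim, divs_truth):
        k = divs_truth.exc_filter.kernel[:, 0]
        resp = np.convolve(cs_stim.values[:, 0] - 1.0, k)[: cs_stim.n_bins]
        res = contrast_ln_analysis(cs_stim, resp)
        expected = abs(k.min() / k.max())
        assert abs(res.biphasic_index["HC"] - expected) < 0.1

    def test_divisive_suppression_raises_contrast_gain(self, cs_stim, divs_truth):
        resp = divs_truth.predict(cs_stim)
        res = contrast_ln_analysis(cs_stim, resp)
        assert res.contrast_gain > 1.0

    def test_missing_contrast_raises(self, divs_truth):
        from divs import single_contrast_stimulus

        stim = single_contrast_stimulus(n_cycles=2, seed=0)
        with pytest.raises(ValueError):
            contrast_ln_analysis(stim, divs_truth.predict(stim))

    def test_summary_prints_gain(self, cs_stim, divs_truth):
        res = contrast_ln_analysis(cs_stim, divs_truth.predict(cs_stim))
        assert "contrast gain" in res.summary()


class TestBlockStats:
    def test_constant_trace_zero_sd(self):
        ts = TrialSet(np.full((3, 5000), 2.0), dt=1.0)
        df = block_stats(ts, window_s=1.0)
        assert np.nanmax(df["sd"]) < 1e-12
        assert np.allclose(df["mean"].dropna(), 2.0)

    def test_white_noise_unit_sd(self):
        rng = np.random.default_rng(8)
        ts = TrialSet(rng.standard_normal((5, 20_000)), dt=1.0)
        df = block_stats(ts, window_s=1.0)
        mid = df["sd"].iloc[2000:-2000]
        assert abs(mid.mean() - 1.0) < 0.1

    def test_step_change_tracked(self):
        y = np.concatenate([np.zeros(5000), np.full(5000, 3.0)])
        df = block_stats(TrialSet(y[None, :], dt=1.0), window_s=1.0)
        assert df["mean"].iloc[2500] < 0.5
        assert df["mean"].iloc[7500] > 2.5

    def test_window_longer_than_trial_raises(self):
        with pytest.raises(ValueError):
            block_stats(TrialSet(np.zeros((2, 500)), dt=1.0), window_s=1.0)
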