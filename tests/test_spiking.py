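"""Spiking models: likelihood oracle, GLM recovery, history effects, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson as sp_poisson

from divs import (
    FitConfig,
    PoissonGLM,
    SpikingDivS,
    SpikingParams,
    poisson_ll,
    refit_without_history,
    simulate_spikes,
    single_contrast_stimulus,
    softplus,
)
from divs.spiking import HistoryFilter
from divs.synth import generate_recording, make_ground_truth


class TestPoissonLL:
    def test_single_spike_constant_rate(self):
        T, lam = 50, 0.2
        counts = np.zeros(T)
        counts[7] = 1
        assert np.isclose(poisson_ll(np.full(T, lam), counts), np.log(lam) - T * lam)

    def test_zero_spikes(self):
        rates = np.array([0.1, 0.4, 0.0])
        assert np.isclose(poisson_ll(rates, np.zeros(3)), -rates.sum())

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_scipy_logpmf_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rates = rng.uniform(0.01, 3.0, 40)
        counts = rng.poisson(1.0, 40)
        got = poisson_ll(rates, counts)
        # Eq-style LL omits the factorial constant of the Poisson pmf
        from math import lgamma

        expected = sp_poisson.logpmf(counts, rates).sum() + np.sum(
            [lgamma(int(c) + 1) for c in counts]
        )
        assert np.isclose(got, expected)

    def test_zero_rate_with_spike_is_minus_inf(self):
        assert poisson_ll(np.array([0.0, 1.0]), np.array([1, 0])) == -np.inf

    def test_negative_rate_raises(self):
        with pytest.raises(ValueError):
            poisson_ll(np.array([-0.1]), np.array([0]))


class TestSoftplus:
    def test_limits(self):
        assert np.isclose(softplus(np.array([0.0]))[0], np.log(2.0))
        g = np.array([50.0])
        assert abs(softplus(g)[0] - 50.0) < 1e-9
        assert softplus(np.array([-800.0]))[0] >= 0.0


@pytest.fixture(scope="module")
def glm_truth():
    return make_ground_truth("glm")


@pytest.fixture(scope="module")
def glm_data(glm_truth):
    # 150 s of the cycle protocol; one continuous simulated train
    return generate_recording(glm_truth, {"protocol": "single"}, n_trials=15, seed=5)


@pytest.fixture(scope="module")
def glm_fit(glm_data):
    cfg = FitConfig(seed=0)
    return PoissonGLM(glm_data.stimulus, glm_data, cfg, with_history=True).fit()


class TestGLM:
    def test_stimulus_filter_recovery(self, glm_truth, glm_fit):
        k_t = glm_truth.subunits[0].filter.kernel[:, 0]
        k_f = glm_fit.params.subunits[0].filter.kernel[:, 0]
        cos = abs(np.dot(k_t, k_f)) / (np.linalg.norm(k_t) * np.linalg.norm(k_f))
        assert cos > 0.95

    def test_ll_non_decreasing(self, glm_fit):
        assert np.all(np.diff(glm_fit.ll_path) >= -1e-12)

    def test_absolute_refractory_structure_recovered(self, glm_fit):
        h = glm_fit.params.history.kernel
        assert h[:2].max() < h[19:50].mean()

    def test_rate_strictly_positive_and_ll_finite(self, glm_data, glm_fit):
        rate = glm_fit.rate()
        assert rate.min() > 0
        assert np.isfinite(glm_fit.train_ll)

    def test_no_spikes_raises(self, glm_data):
        with pytest.raises(ValueError, match="no spikes"):
            PoissonGLM(glm_data.stimulus, np.zeros(glm_data.stimulus.n_bins), FitConfig())


@pytest.fixture(scope="module")
def sdivs_truth_nohist():
    return make_ground_truth("divs_spike", overrides={"history": False})


@pytest.fixture(scope="module")
def quick_fit(glm_data):
    # fitting the (mismatched) spiking-DivS model still must respect all
    # constraints and improve on its LN+RP initialization
    cfg = FitConfig(n_random_inits=0, max_outer_iters=6, seed=0)
    glm = PoissonGLM(glm_data.stimulus, glm_data, cfg).fit()
    fit = SpikingDivS(glm_data.stimulus, glm_data, cfg).fit(glm_init=glm)
    return glm, fit


class TestSpikingDivS:

    def test_constraints_hold(self, quick_fit):
        _, fit = quick_fit
        su = fit.params.subunits[0]
        assert su.sup_nl.weights.min() >= 0 and su.sup_nl.weights.max() <= 1
        assert su.sup_nl(np.array([0.0]))[0] == 1.0
        assert su.exc_nl.check_constraint()

    def test_ll_path_non_decreasing(self, quick_fit):
        _, fit = quick_fit
        assert np.all(np.diff(fit.ll_path) >= -1e-12)

    def test_nesting_never_worse_than_glm(self, quick_fit):
        glm, fit = quick_fit
        assert fit.train_ll >= glm.train_ll - 1e-9

    def test_refit_without_history(self, sdivs_truth_nohist):
        rec = generate_recording(
            sdivs_truth_nohist, {"protocol": "single"}, n_trials=10, seed=9
        )
        cfg = FitConfig(n_random_inits=0, max_outer_iters=8, seed=0)
        full = SpikingDivS(rec.stimulus, rec, cfg).fit()
        reduced = refit_without_history(full)
        assert reduced.params.history is None
        # ground truth had no history: removing the (≈0) fitted history and
        # refitting loses at most 1% of held-out likelihood
        assert reduced.heldout_ll() >= full.heldout_ll() - 0.01 * abs(full.heldout_ll())
        # training LL from refit is at least the zeroed-history warm start
        zeroed = SpikingParams(full.params.subunits, full.params.theta, None)
        from divs.spiking import _rate_terms

        model = reduced.model
        g = zeroed.stimulus_drive(model.stim)[model.train_mask] - zeroed.theta
        r, _, _ = _rate_terms(g)
        ll_zeroed = (np.sum(model.y * np.log(np.maximum(r, 1e-300))) - r.sum()) / len(model.y)
        assert reduced.train_ll >= ll_zeroed - 1e-9

    def test_refit_requires_history(self, sdivs_truth_nohist):
        rec = generate_recording(
            sdivs_truth_nohist, {"protocol": "single"}, n_trials=4, seed=10
        )
        cfg = FitConfig(n_random_inits=0, max_outer_iters=2, seed=0)
        res = SpikingDivS(rec.stimulus, rec, cfg, with_history=False).fit()
        with pytest.raises(ValueError):
            refit_without_history(res)


class TestSimulation:
    def test_same_seed_identical(self, glm_truth, stim_short):
        a, _ = simulate_spikes(glm_truth, stim_short, n_repeats=2, seed=7)
        b, _ = simulate_spikes(glm_truth, stim_short, n_repeats=2, seed=7)
        for x, y in zip(a.trials, b.trials):
            assert np.array_equal(x, y)

    def test_fano_near_one_without_history(self, sdivs_truth_nohist):
        stim = single_contrast_stimulus(n_cycles=1, cycle_s=5.0, unique_s=4.0, seed=3)
        trains, _ = simulate_spikes(sdivs_truth_nohist, stim, n_repeats=300, seed=1)
        counts = np.array([len(t) for t in trains.trials])
        fano = counts.var(ddof=1) / counts.mean()
        assert abs(fano - 1.0) < 0.15

    def test_strong_refractoriness_suppresses_short_isis(self, glm_truth):
        hb = np.eye(100)[:, :8].astype(float)  # direct per-lag basis, first 8 lags
        hb[:, 0] = 0.0
        hb[0, 0] = 1.0
        hb[1, 0] = 1.0
        kernel_coeffs = np.zeros(8)
        kernel_coeffs[0] = -10.0
        model = SpikingParams(
            glm_truth.subunits,
            glm_truth.theta,
            HistoryFilter(hb, kernel_coeffs),
        )
        stim = single_contrast_stimulus(n_cycles=4, seed=8)
        trains, _ = simulate_spikes(model, stim, n_repeats=10, seed=2)
        isis = np.concatenate([np.diff(t) for t in trains.trials if len(t) > 1])
        assert len(isis) > 200
        # the history term acts from the next bin on (within-bin multiplets
        # are Poisson emission, untouched by any binned history): cross-bin
        # ISIs at suppressed lags are rarer than e^-10 would ever allow by
        # chance
        cross_bin = isis[isis >= 1.0]
        assert (cross_bin <= 2.0).mean() < 0.01
        # and the suppression is real: without history short ISIs are common
        free, _ = simulate_spikes(
            SpikingParams(model.subunits, model.theta, None), stim,
            n_repeats=10, seed=2,
        )
        isis0 = np.concatenate([np.diff(t) for t in free.trials if len(t) > 1])
        assert (isis0 <= 2.0).mean() > 3 * (isis <= 2.0).mean()

    def test_psth_shape_and_rate(self, glm_truth, stim_short):
        trains, psth = simulate_spikes(glm_truth, stim_short, n_repeats=20, seed=0)
        assert len(psth) == stim_short.n_bins
        assert np.isclose(psth.mean(), np.mean([len(t) for t in trains.trials]) / stim_short.n_bins)
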