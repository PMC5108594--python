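"""Shared fixtures: small stimuli, canonical ground truths, one cached DivS fit."""

import pytest

from divs import FitConfig, single_contrast_stimulus
from divs.current import DivS
from divs.synth import generate_recording, make_ground_truth


@pytest.fixture(scope="session")
def divs_truth():
    return make_ground_truth("divs")


@pytest.fixture(scope="session")
def ln_truth():
    return make_ground_truth("ln")


@pytest.fixture(scope="session")
def stim_short():
    """20-s high-contrast cycle stimulus."""
    return single_contrast_stimulus(n_cycles=2, seed=42)


@pytest.fixture(scope="session")
def divs_fit_small(divs_truth):
    """DivS recording (50 s, SNR 10) and a modest DivS fit, shared across tests."""
    rec = generate_recording(divs_truth, {"protocol": "single"}, n_trials=5, snr=10.0, seed=3)
    cfg = FitConfig(n_random_inits=1, max_outer_iters=20, rel_tol=1e-6, seed=0)
    fit = DivS(rec.stimulus, rec.current, cfg).fit()
    return rec, fit
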