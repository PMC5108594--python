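"""Evaluation statistics: predictive power, coherence, contrast adaptation.

* :func:`predictive_power` — fraction of *explainable* (signal) variance a
  prediction captures, corrected for trial noise from the between- vs
  within-trial variance decomposition.
* :func:`coherence` — trial-averaged magnitude-squared coherence between a
  prediction and single-trial responses, with the noise-corrected upper bound
  obtained by using the leave-one-out trial mean as the ideal predictor.
* :func:`contrast_ln_analysis` — separate LN analysis per contrast level with
  x-scale/y-offset alignment of the nonlinearities; yields contrast gain
  (SD ratio of aligned filters, low/high) and the biphasic index |min/max|.
* :func:`block_stats` — sliding-window mean and SD of the response across the
  trial timeline (slow-adaptation diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import minimize_scalar

from . import _optim
from .containers import TrialSet
from .params import basis_design, temporal_basis
from .stimulus import Stimulus

__all__ = [
    "CoherenceResult",
    "AdaptationResult",
    "predictive_power",
    "coherence",
    "contrast_ln_analysis",
    "block_stats",
]


def _trials_matrix(trials) -> np.ndarray:
    if isinstance(trials, TrialSet):
        return trials.trials
    return np.atleast_2d(np.asarray(trials, dtype=float))


def predictive_power(pred: np.ndarray, trials) -> float:
    """Noise-corrected fraction of explainable variance captured by ``pred``.

    With n trials y_i(t), trial mean m(t) and per-trial variances, the signal
    power is estimated as ``P_sig = (n Var(m) - mean_i Var(y_i)) / (n - 1)``;
    the returned statistic is ``corr(pred, m)^2 * Var(m) / P_sig`` — the
    fraction of the *predictable* variance captured, 1 for the true underlying
    signal regardless of trial noise, ~0 for a prediction unrelated to it.
    """
    Y = _trials_matrix(trials)
    if Y.shape[0] < 2:
        raise ValueError("need >= 2 trials to estimate trial noise")
    pred = np.asarray(pred, dtype=float).ravel()
    if len(pred) != Y.shape[1]:
        raise ValueError("prediction and trials must have equal length")
    n = Y.shape[0]
    m = Y.mean(axis=0)
    var_m = float(m.var())
    p_bar = float(Y.var(axis=1).mean())
    p_sig = (n * var_m - p_bar) / (n - 1)
    if p_sig <= 0:
        raise ValueError("no explainable signal variance in the trials")
    c = np.corrcoef(pred, m)[0, 1]
    return float(c**2 * var_m / p_sig)


@dataclass
class CoherenceResult:
    """Frequency-resolved coherence and its noise-corrected upper bound."""

    freqs_hz: np.ndarray
    gamma2: np.ndarray
    noise_bound: np.ndarray

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return 2.0 * np.pi * self.freqs_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.freqs_hz,
                "omega_rad_s": self.omega,
                "gamma2": self.gamma2,
                "noise_bound": self.noise_bound,
            }
        )


def coherence(pred: np.ndarray, trials, dt: float = 1.0,
              nperseg_s: float = 1.0) -> CoherenceResult:
    """Trial-averaged magnitude-squared coherence between ``pred`` and trials.

    Welch estimation with tapered segments of ``nperseg_s`` seconds and 50%
    overlap, per trial, then averaged across trials. The noise bound repeats
    the computation with the leave-one-out trial mean in place of the model
    prediction (the ideal stimulus-locked predictor).
    """
    Y = _trials_matrix(trials)
    pred = np.asarray(pred, dtype=float).ravel()
    if len(pred) != Y.shape[1]:
        raise ValueError("prediction and trials must have equal length")
    if Y.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    fs = 1000.0 / dt
    nperseg = min(int(round(nperseg_s * fs)), Y.shape[1])
    g2 = []
    nb = []
    n = Y.shape[0]
    for i in range(n):
        f, c = sps.coherence(pred, Y[i], fs=fs, nperseg=nperseg)
        g2.append(c)
        loo = (Y.sum(axis=0) - Y[i]) / (n - 1)
        _, cb = sps.coherence(loo, Y[i], fs=fs, nperseg=nperseg)
        nb.append(cb)
    return CoherenceResult(
        freqs_hz=f,
        gamma2=np.clip(np.mean(g2, axis=0), 0.0, 1.0),
        noise_bound=np.clip(np.mean(nb, axis=0), 0.0, 1.0),
    )


@dataclass
class AdaptationResult:
    """Per-contrast LN analysis with aligned nonlinearities.

    ``filters`` hold the aligned filters (the x-scale folded into the
    low-contrast filter); ``contrast_gain = SD(k_LC) / SD(k_HC)`` after
    alignment, so values > 1 mean the effective gain is reduced at high
    contrast (adaptation). ``biphasic_index[label] = |min(k)/max(k)|``.
    """

    lags_ms: np.ndarray
    filters: dict
    nonlinearities: dict = field(repr=False)
    x_scale: float = 1.0
    y_offset: float = 0.0
    contrast_gain: float = 1.0
    biphasic_index: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Contrast-adaptation LN analysis",
            "=" * 40,
            f"contrast gain (LC/HC): {self.contrast_gain:.3f}",
            f"x-scale:               {self.x_scale:.3f}",
            f"y-offset:              {self.y_offset:.4g}",
        ]
        for lab, bi in self.biphasic_index.items():
            lines.append(f"biphasic index {lab}:     {bi:.3f}")
        return "\n".join(lines)


def _ln_branch(stim: Stimulus, resp: np.ndarray, label: str, n_basis: int,
               t_max: float, n_bins_nl: int = 20):
    """Whitened reverse-correlation filter + binned nonlinearity for one contrast."""
    basis = temporal_basis(n_basis, t_max, stim.dt)
    mask = stim.mask(label=label, burn_in_ms=t_max)
    # exclude bins whose filter window crosses a block boundary into the other contrast
    lab_mask = stim.mask(label=label)
    lag = basis.n_bins
    valid = np.ones(stim.n_bins, dtype=bool)
    idx = np.flatnonzero(~lab_mask)
    for i in idx:
        valid[i: i + lag] = False
    mask &= valid
    if mask.sum() < 10 * n_basis:
        raise ValueError(f"not enough samples for contrast {label!r}")
    centered = Stimulus(
        values=stim.values - stim.values.mean(axis=0, keepdims=True),
        dt=stim.dt, mean_level=0.0,
        schedule=stim.schedule, repeat_windows=stim.repeat_windows,
    )
    D = basis_design(centered, basis)[mask]
    y = resp[mask]
    a = _optim.solve_lsq(D, y - y.mean())
    kernel = basis.expand(a).ravel()
    g = D @ a
    # nonparametric nonlinearity: response mean in quantile bins of g
    edges = np.quantile(g, np.linspace(0, 1, n_bins_nl + 1))
    edges[0] -= 1e-9
    which = np.clip(np.searchsorted(edges, g) - 1, 0, n_bins_nl - 1)
    centers = np.array([g[which == b].mean() for b in range(n_bins_nl)])
    values = np.array([y[which == b].mean() for b in range(n_bins_nl)])
    return kernel, centers, values


def contrast_ln_analysis(
    stim: Stimulus,
    resp: np.ndarray,
    n_basis: int = 12,
    t_max: float = 200.0,
) -> AdaptationResult:
    """LN analysis per contrast with x-scale/y-offset nonlinearity alignment.

    Filters are estimated by whitened reverse correlation (regression on the
    orthonormal temporal basis) separately within HC and LC blocks, and the
    two nonparametric nonlinearities are aligned by a scaling of the LC
    x-axis and an offset of its y-axis minimizing their mean squared
    deviation. The x-scale is folded into the LC filter, so any gain change
    appears in the filters and ``contrast_gain = SD(k_LC)/SD(k_HC)``.
    """
    labels = {lab for _, _, lab in stim.schedule}
    if not {"HC", "LC"} <= labels:
        raise ValueError("need both HC and LC blocks in the schedule")
    resp = np.asarray(resp, dtype=float).ravel()
    k_hc, x_hc, f_hc = _ln_branch(stim, resp, "HC", n_basis, t_max)
    k_lc, x_lc, f_lc = _ln_branch(stim, resp, "LC", n_basis, t_max)

    def misfit(log_alpha):
        alpha = np.exp(log_alpha)
        f_hc_at = np.interp(
            alpha * x_lc, x_hc, f_hc, left=f_hc[0], right=f_hc[-1]
        )
        beta = float(np.mean(f_lc - f_hc_at))
        return float(np.mean((f_lc - f_hc_at - beta) ** 2))

    grid = np.linspace(np.log(0.2), np.log(5.0), 81)
    best = grid[int(np.argmin([misfit(la) for la in grid]))]
    res = minimize_scalar(
        misfit, bounds=(best - 0.15, best + 0.15), method="bounded",
        options={"xatol": 1e-5},
    )
    alpha = float(np.exp(res.x))
    f_hc_at = np.interp(alpha * x_lc, x_hc, f_hc, left=f_hc[0], right=f_hc[-1])
    beta = float(np.mean(f_lc - f_hc_at))
    k_lc_aligned = alpha * k_lc
    gain = float(np.std(k_lc_aligned) / np.std(k_hc))
    bi = {
        "HC": float(abs(k_hc.min() / k_hc.max())),
        "LC": float(abs(k_lc_aligned.min() / k_lc_aligned.max())),
    }
    lags = np.arange(len(k_hc)) * stim.dt
    return AdaptationResult(
        lags_ms=lags,
        filters={"HC": k_hc, "LC": k_lc_aligned},
        nonlinearities={"HC": (x_hc, f_hc), "LC": (x_lc, f_lc)},
        x_scale=alpha,
        y_offset=beta,
        contrast_gain=gain,
        biphasic_index=bi,
    )


def block_stats(resp: TrialSet, window_s: float = 1.0) -> pd.DataFrame:
    """Sliding-window mean and SD per trial, averaged over trials.

    Returns a DataFrame with columns ``time_ms``, ``mean``, ``sd`` — the
    slow-adaptation diagnostic of offset and gain across the trial timeline.
    """
    Y = _trials_matrix(resp)
    dt = resp.dt if isinstance(resp, TrialSet) else 1.0
    win = int(round(window_s * 1000.0 / dt))
    if win >= Y.shape[1]:
        raise ValueError("window longer than the trial")
    frame = pd.DataFrame(Y.T)
    roll = frame.rolling(win, center=True, min_periods=max(win // 2, 2))
    mean = roll.mean().mean(axis=1).to_numpy()
    sd = roll.std(ddof=1).mean(axis=1).to_numpy()
    return pd.DataFrame(
        {"time_ms": np.arange(Y.shape[1]) * dt, "mean": mean, "sd": sd}
    )
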