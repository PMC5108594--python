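"""Point-process spiking models: LN, LN+RP (GLM), spiking DivS, DivS-RP.

Spikes are modeled as an inhomogeneous Poisson process at 1-ms resolution
with instantaneous rate

    r(t) = F_spk[ sum_i zeta_i[s(t)] + h_spk . R(t) - theta ],

where ``F_spk[g] = log(1 + exp(g))`` (softplus, fixed), the upstream
subunits ``zeta_i`` are either linear filters or DivS units (excitatory LN
times suppressive LN with the same constraints as the current models),
``h_spk`` is a spike-history filter on a log-spaced bump basis covering
1–100 ms, and ``theta`` is the spiking threshold. Parameters maximize the
Poisson log-likelihood ``LL = sum_t [r_obs(t) log r(t) - r(t)]``; the
history term is driven by the *observed* spike train during fitting, and by
the simulated train's own history (causally, bin by bin) when generating
cross-validated predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import expit

from .basis import history_basis
from .containers import Recording, SpikeTrainSet
from .params import (
    MONOTONE,
    SUPPRESSIVE,
    FitConfig,
    Nonlinearity1D,
    TemporalFilter,
    basis_design,
    lagged_design,
    shifted_coeffs,
    symmetric_knots,
)
from . import _optim
from .stimulus import Stimulus

__all__ = [
    "poisson_ll",
    "softplus",
    "SpikingParams",
    "LinearSubunit",
    "DivSSubunit",
    "HistoryFilter",
    "PoissonGLM",
    "SpikingDivS",
    "SpikingResults",
    "fit_glm",
    "fit_divs_spike",
    "refit_without_history",
    "simulate_spikes",
]


def softplus(g: np.ndarray) -> np.ndarray:
    """F_spk[g] = log(1 + exp(g)), numerically stable."""
    return np.logaddexp(0.0, g)


def poisson_ll(rate: np.ndarray, spikes: np.ndarray) -> float:
    """Poisson log-likelihood sum_t [n_t log r_t - r_t] (nats), 0 log 0 = 0.

    Returns -inf if any bin has zero rate but a nonzero count.
    """
    r = np.asarray(rate, dtype=float).ravel()
    n = np.asarray(spikes, dtype=float).ravel()
    if r.shape != n.shape:
        raise ValueError("rate and count arrays must have equal length")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    active = n > 0
    if np.any(r[active] == 0):
        return -np.inf
    ll = -float(r.sum())
    ll += float(np.sum(n[active] * np.log(r[active])))
    return ll


@dataclass
class HistoryFilter:
    """Spike-history filter: coefficients on the log-spaced bump basis.

    The expanded kernel covers lags 1..n_lags bins; lag 0 is excluded so a
    spike never drives its own bin.
    """

    basis: np.ndarray = field(repr=False)  # (n_lags, n_funcs)
    coeffs: np.ndarray = None

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()

    @property
    def kernel(self) -> np.ndarray:
        return self.basis @ self.coeffs


@dataclass
class LinearSubunit:
    """zeta[s] = k_lin . s (the filter carries its own scale)."""

    filter: TemporalFilter
    kind: str = field(default="linear", init=False)

    def drive(self, stim: Stimulus) -> np.ndarray:
        return self.filter.apply(stim)


@dataclass
class DivSSubunit:
    """zeta[s] = weight * fe[ke.s] * fs[ks.s], DivS constraints as for currents."""

    exc_filter: TemporalFilter
    exc_nl: Nonlinearity1D
    sup_filter: TemporalFilter
    sup_nl: Nonlinearity1D
    kind: str = field(default="divs", init=False)

    def drive(self, stim: Stimulus) -> np.ndarray:
        return self.exc_nl(self.exc_filter.apply(stim)) * self.sup_nl(
            self.sup_filter.apply(stim)
        )

    def delay_ms(self, channel: int = 0) -> float:
        return self.sup_filter.peak_lag_ms(channel) - self.exc_filter.peak_lag_ms(channel)


@dataclass
class SpikingParams:
    """Subunits + optional spike history + threshold; softplus output per bin."""

    subunits: list
    theta: float
    history: HistoryFilter | None = None
    kind: str = field(default="spiking", init=False)

    def stimulus_drive(self, stim: Stimulus) -> np.ndarray:
        return np.sum([su.drive(stim) for su in self.subunits], axis=0)

    def rate(self, stim: Stimulus, observed_counts: np.ndarray | None = None) -> np.ndarray:
        """Per-bin rate; history (if any) is driven by the observed counts."""
        g = self.stimulus_drive(stim) - self.theta
        if self.history is not None:
            if observed_counts is None:
                raise ValueError(
                    "model has a spike-history term: pass observed counts or use simulate"
                )
            g = g + history_drive(observed_counts, self.history.kernel)
        return softplus(g)


def history_drive(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution of past counts with the history kernel (lag >= 1)."""
    counts = np.asarray(counts, dtype=float).ravel()
    full = np.convolve(counts, kernel)
    return np.concatenate([[0.0], full])[: len(counts)]


def _history_design(counts: np.ndarray, hb: np.ndarray) -> np.ndarray:
    """Design (T, n_funcs): column j = counts convolved with basis bump j, lag >= 1."""
    L = hb.shape[0]
    lagged = lagged_design(np.concatenate([[0.0], counts])[:-1], L)
    return lagged @ hb


@njit(cache=True)
def _simulate_loop(drive, h_kernel, seed):
    np.random.seed(seed)
    T = drive.shape[0]
    L = h_kernel.shape[0]
    counts = np.zeros(T)
    hbuf = np.zeros(T + L + 1)
    for t in range(T):
        g = drive[t] + hbuf[t]
        r = np.logaddexp(0.0, g)
        n = np.random.poisson(r)
        if n > 0:
            counts[t] = n
            for k in range(L):
                hbuf[t + 1 + k] += n * h_kernel[k]
    return counts


def simulate_spikes(
    model: SpikingParams,
    stim: Stimulus,
    n_repeats: int = 500,
    seed: int = 0,
) -> tuple[SpikeTrainSet, np.ndarray]:
    """Simulate repeats of the Poisson process with self-generated history.

    Per 1-ms bin a Poisson count is drawn from the instantaneous rate computed
    with the simulated train's own spike history (causally). Spikes within a
    bin are spread uniformly inside the bin so times are strictly increasing.
    Returns the trains and the across-repeat mean rate (PSTH, spikes/bin).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    drive = np.ascontiguousarray(model.stimulus_drive(stim) - model.theta)
    kernel = (
        np.ascontiguousarray(model.history.kernel)
        if model.history is not None
        else np.zeros(1)
    )
    dt = stim.dt
    trials = []
    psth = np.zeros(stim.n_bins)
    for rep in range(n_repeats):
        rep_seed = (seed * 1_000_003 + rep * 7919) % (2**31 - 1)
        counts = _simulate_loop(drive, kernel, rep_seed)
        psth += counts
        idx = np.nonzero(counts)[0]
        times = []
        for t in idx:
            n = int(counts[t])
            times.extend(t * dt + (np.arange(n) + 0.5) / n * dt)
        trials.append(np.array(times))
    psth /= n_repeats
    return SpikeTrainSet(trials, duration=stim.duration_ms, dt=dt), psth


def _as_counts(spikes, stim: Stimulus) -> np.ndarray:
    if isinstance(spikes, Recording):
        return spikes.binned_spikes()
    if isinstance(spikes, SpikeTrainSet):
        if spikes.n_trials != 1:
            raise ValueError("pass the continuous train (one trial spanning the stimulus)")
        edges = np.arange(stim.n_bins + 1) * stim.dt
        return np.histogram(spikes.trials[0], bins=edges)[0].astype(float)
    arr = np.asarray(spikes, dtype=float).ravel()
    if len(arr) == stim.n_bins and (np.all(arr == np.round(arr))):
        return arr
    edges = np.arange(stim.n_bins + 1) * stim.dt
    return np.histogram(arr, bins=edges)[0].astype(float)


def _rate_terms(g: np.ndarray):
    """softplus(g), its derivative, and d/dg log softplus(g), all stable."""
    r = softplus(g)
    s = expit(g)
    # counts * dlog r = counts * s / r ; as g -> -inf, s/r -> 1
    ratio = np.where(r > 1e-12, s / np.where(r > 1e-12, r, 1.0), 1.0)
    return r, s, ratio


class _SpikingModelBase:
    def __init__(self, stim: Stimulus, spikes, config: FitConfig | None = None):
        self.stim = stim
        self.config = config or FitConfig()
        if abs(self.config.dt - stim.dt) > 1e-12:
            self.config = replace(self.config, dt=stim.dt)
        self.counts = _as_counts(spikes, stim)
        if self.counts.sum() == 0:
            raise ValueError("degenerate fit: no spikes in the training data")
        self.basis = self.config.make_temporal_basis()
        self.hb = history_basis(
            self.config.n_history_basis, self.config.history_t_max, self.config.dt
        )
        self.train_mask = stim.mask(exclude_repeats=True, burn_in_ms=self.config.t_max)
        self._X_full = basis_design(stim, self.basis)
        self._H_full = _history_design(self.counts, self.hb)
        self.X = self._X_full[self.train_mask]
        self.H = self._H_full[self.train_mask]
        self.y = self.counts[self.train_mask]
        self.n_coef = self.X.shape[1]

    @classmethod
    def from_recording(cls, rec: Recording, config: FitConfig | None = None, **kw):
        return cls(rec.stimulus, rec, config, **kw)

    def _nll_linear(self, A: np.ndarray, const: np.ndarray):
        """Negative LL and gradient for drive = A @ x + const (concave in x)."""
        y = self.y
        n = len(y)

        def f(x):
            g = A @ x + const
            r, s, ratio = _rate_terms(g)
            nll = (r.sum() - np.sum(y * np.log(np.maximum(r, 1e-300)))) / n
            grad = (A.T @ (s - y * ratio)) / n
            return float(nll), grad

        return f

    def _maximize_linear(self, A, const, x0, bounds=None, maxiter=200):
        res = minimize(
            self._nll_linear(A, const),
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        return res.x, -float(res.fun)


@dataclass
class SpikingResults:
    """Fit results for a point-process spiking model."""

    model: object = field(repr=False)
    params: SpikingParams
    ll_path: np.ndarray  # train LL per bin (non-decreasing over outer iterations)
    converged: bool
    restart_lls: list = field(default_factory=list)

    @property
    def train_ll(self) -> float:
        return float(self.ll_path[-1])

    def rate(self, stim: Stimulus | None = None, observed_counts=None) -> np.ndarray:
        stim = stim if stim is not None else self.model.stim
        if observed_counts is None and self.params.history is not None:
            observed_counts = self.model.counts
        return self.params.rate(stim, observed_counts)

    def heldout_ll(self, label: str | None = None) -> float:
        """Cross-validated LL per bin on the repeat windows (observed history)."""
        stim = self.model.stim
        rate = self.rate()
        counts = self.model.counts
        mask = np.zeros(stim.n_bins, dtype=bool)
        windows = stim.repeat_windows if label is None else stim.repeat_windows_for(label)
        for w in windows:
            mask[stim.window_slice(w)] = True
        return poisson_ll(rate[mask], counts[mask]) / mask.sum()

    def simulate(self, stim: Stimulus | None = None, n_repeats: int = 500, seed: int = 0):
        return simulate_spikes(
            self.params, stim if stim is not None else self.model.stim, n_repeats, seed
        )

    def summary(self) -> str:
        p = self.params
        kinds = "+".join(su.kind for su in p.subunits)
        lines = [
            "Poisson spiking model fit",
            "=" * 40,
            f"subunits:        {kinds}",
            f"spike history:   {'yes' if p.history is not None else 'no'}",
            f"theta:           {p.theta:.4g}",
            f"train LL/bin:    {self.train_ll:.6g}",
            f"spikes (train):  {int(self.model.y.sum())}",
        ]
        for su in p.subunits:
            if hasattr(su, "delay_ms"):
                lines.append(f"supp. delay:     {su.delay_ms():.1f} ms")
        return "\n".join(lines)


class PoissonGLM(_SpikingModelBase):
    """LN / LN+RP spiking model: r = F_spk[k_lin.s + h_spk.R - theta].

    The log-likelihood is concave in all parameters, so a single quasi-Newton
    run finds the maximum.
    """

    def __init__(self, stim, spikes, config=None, with_history: bool = True):
        super().__init__(stim, spikes, config)
        self.with_history = with_history

    def fit(self) -> SpikingResults:
        A = np.column_stack([self.X, self.H] if self.with_history else [self.X])
        A = np.column_stack([A, np.ones(len(self.y))])
        x0 = np.zeros(A.shape[1])
        x0[-1] = np.log(np.expm1(max(self.y.mean(), 1e-4)))  # match mean rate
        nll0, _ = self._nll_linear(A, np.zeros(len(self.y)))(x0)
        x, ll = self._maximize_linear(A, np.zeros(len(self.y)), x0)
        nf = self.n_coef
        filt = TemporalFilter(
            self.basis, x[:nf].reshape(self.basis.n_funcs, -1, order="F"), unit_norm=False
        )
        hist = (
            HistoryFilter(self.hb, x[nf: nf + self.hb.shape[1]]) if self.with_history else None
        )
        params = SpikingParams(
            subunits=[LinearSubunit(filt)], theta=-float(x[-1]), history=hist
        )
        return SpikingResults(self, params, np.array([-nll0, ll]), True, [ll])


class SpikingDivS(_SpikingModelBase):
    """Spiking DivS model: r = F_spk[beta * fe[ke.s] fs[ks.s] + h_spk.R - theta].

    Fit by block-coordinate ascent of the Poisson LL: concave updates of the
    excitatory/suppressive nonlinearity weights (bound-constrained) and of the
    history/threshold block alternate with quasi-Newton updates of the filter
    coefficients; every block is accepted only if the training LL does not
    decrease. Includes the spike-history term by default (the divisive term
    cannot be estimated robustly without it).
    """

    def __init__(self, stim, spikes, config=None, with_history: bool = True):
        super().__init__(stim, spikes, config)
        self.with_history = with_history

    def fit(self, glm_init: SpikingResults | None = None) -> SpikingResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        if glm_init is None:
            glm_init = PoissonGLM(
                self.stim, self.counts, cfg, with_history=self.with_history
            ).fit()
        a_lin = glm_init.params.subunits[0].filter.coeffs.ravel(order="F")
        ae0 = a_lin / np.linalg.norm(a_lin)
        inits = [
            (ae0, ae0.copy(), False),
            # nested start: suppression initially inactive (fs = 1), so this
            # restart begins at (and can only improve on) the LN+RP solution
            (ae0, shifted_coeffs(self.basis, ae0, 8.0), True),
        ]
        inits += [
            (ae0, self._random_coeffs(rng), False) for _ in range(cfg.n_random_inits)
        ]
        best = None
        restart_lls = []
        for ae, as_, nested in inits:
            st = self._fit_single(ae, as_, glm_init, nested)
            restart_lls.append(st["path"][-1])
            if best is None or st["path"][-1] > best["path"][-1]:
                best = st
        params = self._pack(best)
        converged = len(best["path"]) < cfg.max_outer_iters
        return SpikingResults(self, params, np.array(best["path"]), converged, restart_lls)

    # -- internals -------------------------------------------------------
    def _random_coeffs(self, rng):
        a = rng.standard_normal(self.n_coef)
        return a / np.linalg.norm(a)

    def _ll(self, st) -> float:
        g = self._drive(st)
        r, _, _ = _rate_terms(g)
        return (np.sum(self.y * np.log(np.maximum(r, 1e-300))) - r.sum()) / len(self.y)

    def _drive(self, st):
        fe = st["tbe"].interp(st["ge"], st["we"])
        fs = st["tbs"].interp(st["gs"], st["ws"])
        g = fe * fs - st["theta"]
        if self.with_history:
            g = g + self.H @ st["b"]
        return g

    def _hist_const(self, st):
        return (self.H @ st["b"] if self.with_history else np.zeros(len(self.y)))

    def _update_exc_nl(self, st):
        fs = st["tbs"].interp(st["gs"], st["ws"])
        D = st["tbe"].design(st["ge"]) * fs[:, None]
        C = _optim.monotone_map(st["tbe"].n_funcs, anchor_first_zero=True)
        A = np.column_stack([D @ C, -np.ones(len(self.y))])
        x0 = np.concatenate([np.maximum(np.diff(st["we"]), 0.0), [st["theta"]]])
        bounds = [(0, None)] * (A.shape[1] - 1) + [(None, None)]
        x, _ = self._maximize_linear(A, self._hist_const(st), x0, bounds, maxiter=100)
        trial = dict(st)
        trial["we"] = C @ x[:-1]
        trial["theta"] = float(x[-1])
        return trial

    def _update_sup_nl(self, st):
        fe = st["tbe"].interp(st["ge"], st["we"])
        D = st["tbs"].design(st["gs"]) * fe[:, None]
        i0 = st["tbs"].n_funcs // 2
        keep = np.ones(D.shape[1], dtype=bool)
        keep[i0] = False
        const = self._hist_const(st) + D[:, i0] * 1.0 - st["theta"]
        x0 = st["ws"][keep]
        bounds = [(0.0, 1.0)] * int(keep.sum())
        x, _ = self._maximize_linear(D[:, keep], const, x0, bounds, maxiter=100)
        trial = dict(st)
        ws = np.empty(D.shape[1])
        ws[keep] = x
        ws[i0] = 1.0
        trial["ws"] = ws
        return trial

    def _update_history(self, st):
        if not self.with_history:
            return st
        fe = st["tbe"].interp(st["ge"], st["we"])
        fs = st["tbs"].interp(st["gs"], st["ws"])
        A = np.column_stack([self.H, -np.ones(len(self.y))])
        x0 = np.concatenate([st["b"], [st["theta"]]])
        x, _ = self._maximize_linear(A, fe * fs, x0, maxiter=100)
        trial = dict(st)
        trial["b"] = x[:-1]
        trial["theta"] = float(x[-1])
        return trial

    def _filter_nll(self, st, which):
        X, y = self.X, self.y
        tbe, tbs = st["tbe"], st["tbs"]
        we, ws = st["we"], st["ws"]
        hist = self._hist_const(st) - st["theta"]
        n = len(y)

        def f(a):
            if which == "exc":
                ge = X @ a
                gs = st["gs"]
            else:
                ge = st["ge"]
                gs = X @ a
            fe = tbe.interp(ge, we)
            fs = tbs.interp(gs, ws)
            g = fe * fs + hist
            r, s, ratio = _rate_terms(g)
            dg = s - y * ratio
            if which == "exc":
                chain = dg * fs * tbe.deriv(ge, we)
            else:
                chain = dg * fe * tbs.deriv(gs, ws)
            nll = (r.sum() - np.sum(y * np.log(np.maximum(r, 1e-300)))) / n
            return float(nll), (X.T @ chain) / n

        return f

    def _joint_filter_nll(self, st):
        X, y = self.X, self.y
        tbe, tbs = st["tbe"], st["tbs"]
        we, ws = st["we"], st["ws"]
        hist = self._hist_const(st) - st["theta"]
        n = len(y)
        nc = self.n_coef

        def f(a):
            ge = X @ a[:nc]
            gs = X @ a[nc:]
            fe = tbe.interp(ge, we)
            fs = tbs.interp(gs, ws)
            g = fe * fs + hist
            r, s, ratio = _rate_terms(g)
            dg = s - y * ratio
            ce = dg * fs * tbe.deriv(ge, we)
            cs = dg * fe * tbs.deriv(gs, ws)
            nll = (r.sum() - np.sum(y * np.log(np.maximum(r, 1e-300)))) / n
            return float(nll), np.concatenate([X.T @ ce, X.T @ cs]) / n

        return f

    def _joint_filter_step(self, st, ll):
        res = minimize(
            self._joint_filter_nll(st),
            np.concatenate([st["ae"], st["as"]]),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.config.inner_maxiter},
        )
        nc = self.n_coef
        trial = dict(st)
        for key, a_new in (("ae", res.x[:nc]), ("as", res.x[nc:])):
            nrm = np.linalg.norm(a_new)
            if nrm == 0:
                return st, ll
            trial[key] = a_new / nrm
        trial["ge"] = self.X @ trial["ae"]
        trial["gs"] = self.X @ trial["as"]
        trial = self._update_exc_nl(trial)
        trial = self._update_sup_nl(trial)
        ll_t = self._ll(trial)
        if ll_t >= ll:
            return trial, ll_t
        return st, ll

    def _fit_single(self, ae, as_, glm_init, nested):
        cfg = self.config
        st = {
            "ae": ae,
            "as": as_,
            "ge": self.X @ ae,
            "gs": self.X @ as_,
            "theta": glm_init.params.theta,
            "b": (
                glm_init.params.history.coeffs.copy()
                if (self.with_history and glm_init.params.history is not None)
                else np.zeros(self.hb.shape[1])
            ),
        }
        st["tbe"] = symmetric_knots(st["ge"], cfg.n_knots)
        st["tbs"] = symmetric_knots(st["gs"], cfg.n_knots)
        st["we"] = np.zeros(st["tbe"].n_funcs)
        x = st["tbs"].knots
        if nested:
            st["ws"] = np.ones(st["tbs"].n_funcs)
        else:
            st["ws"] = np.clip(1.0 - 0.3 * (x / x[-1]) ** 2, 0.0, 1.0)
            st["ws"][len(x) // 2] = 1.0
        st = self._update_exc_nl(st)
        ll = self._ll(st)
        path = [ll]
        for _ in range(cfg.max_outer_iters):
            ll_before = ll
            for update in (self._update_exc_nl, self._update_sup_nl, self._update_history):
                trial = update(st)
                if self._ll(trial) >= ll:
                    st = trial
                    ll = self._ll(st)
            for which in ("exc", "sup"):
                key_a, key_g = ("ae", "ge") if which == "exc" else ("as", "gs")
                res = minimize(
                    self._filter_nll(st, which),
                    st[key_a],
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": cfg.inner_maxiter},
                )
                a_new = res.x
                nrm = np.linalg.norm(a_new)
                if nrm == 0:
                    continue
                trial = dict(st)
                trial[key_a] = a_new / nrm
                trial[key_g] = self.X @ trial[key_a]
                trial = (
                    self._update_exc_nl(trial) if which == "exc" else self._update_sup_nl(trial)
                )
                if self._ll(trial) >= ll:
                    st = trial
                    ll = self._ll(st)
            st, ll = self._joint_filter_step(st, ll)
            path.append(ll)
            if ll - ll_before < cfg.rel_tol * max(abs(ll), 1e-300):
                break
        st["path"] = path
        return st

    def _pack(self, st) -> SpikingParams:
        nf = self.basis.n_funcs
        ae = st["ae"].reshape(nf, -1, order="F")
        as_ = st["as"].reshape(nf, -1, order="F")
        ws = st["ws"]
        if float(np.dot(st["ae"], st["as"])) < 0:
            as_ = -as_
            ws = ws[::-1].copy()
        sub = DivSSubunit(
            exc_filter=TemporalFilter(self.basis, ae),
            exc_nl=Nonlinearity1D(st["tbe"], st["we"], MONOTONE),
            sup_filter=TemporalFilter(self.basis, as_),
            sup_nl=Nonlinearity1D(st["tbs"], ws, SUPPRESSIVE),
        )
        hist = HistoryFilter(self.hb, st["b"]) if self.with_history else None
        return SpikingParams(subunits=[sub], theta=st["theta"], history=hist)


def fit_glm(stim, spikes, cfg: FitConfig | None = None, with_history: bool = True) -> SpikingResults:
    return PoissonGLM(stim, spikes, cfg, with_history=with_history).fit()


def fit_divs_spike(stim, spikes, cfg: FitConfig | None = None) -> SpikingResults:
    return SpikingDivS(stim, spikes, cfg).fit()


def refit_without_history(
    results: SpikingResults, stim=None, spikes=None, cfg: FitConfig | None = None
) -> SpikingResults:
    """Drop the spike-history term and re-optimize from the full-model solution.

    This is the DivS-RP construction: the stimulus-processing parameters are
    warm-started at the full model's solution and re-fit without history.
    """
    if results.params.history is None:
        raise ValueError("model has no history term to remove")
    model = results.model
    stim = stim if stim is not None else model.stim
    spikes = spikes if spikes is not None else model.counts
    cfg = cfg if cfg is not None else model.config
    p = results.params
    if isinstance(p.subunits[0], DivSSubunit):
        new = SpikingDivS(stim, spikes, cfg, with_history=False)
        su = p.subunits[0]
        ae = su.exc_filter.coeffs.ravel(order="F")
        as_ = su.sup_filter.coeffs.ravel(order="F")
        st = {
            "ae": ae,
            "as": as_,
            "ge": new.X @ ae,
            "gs": new.X @ as_,
            "theta": p.theta,
            "b": np.zeros(new.hb.shape[1]),
            "tbe": su.exc_nl.basis,
            "tbs": su.sup_nl.basis,
            "we": su.exc_nl.weights.copy(),
            "ws": su.sup_nl.weights.copy(),
        }
        ll = new._ll(st)
        path = [ll]
        for _ in range(cfg.max_outer_iters):
            ll_before = ll
            for update in (new._update_exc_nl, new._update_sup_nl):
                trial = update(st)
                if new._ll(trial) >= ll:
                    st = trial
                    ll = new._ll(st)
            for which in ("exc", "sup"):
                key_a, key_g = ("ae", "ge") if which == "exc" else ("as", "gs")
                res = minimize(
                    new._filter_nll(st, which), st[key_a], jac=True,
                    method="L-BFGS-B", options={"maxiter": cfg.inner_maxiter},
                )
                nrm = np.linalg.norm(res.x)
                if nrm == 0:
                    continue
                trial = dict(st)
                trial[key_a] = res.x / nrm
                trial[key_g] = new.X @ trial[key_a]
                trial = new._update_exc_nl(trial) if which == "exc" else new._update_sup_nl(trial)
                if new._ll(trial) >= ll:
                    st = trial
                    ll = new._ll(st)
            st, ll = new._joint_filter_step(st, ll)
            path.append(ll)
            if ll - ll_before < cfg.rel_tol * max(abs(ll), 1e-300):
                break
        st["path"] = path
        params = new._pack(st)
        return SpikingResults(new, params, np.array(path), True, [path[-1]])
    # linear subunit: concave re-fit without history
    new = PoissonGLM(stim, spikes, cfg, with_history=False)
    return new.fit()
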