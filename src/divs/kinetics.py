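"""Linear-Nonlinear-Kinetic (LNK) model of synaptic depression.

An LN front-end drives first-order kinetics among three states of a signaling
pool — resting (R), active (A) and inactivated (I). The stimulus-dependent
drive ``u(t) = f[k . s(t)]`` (a nonnegative rate, 1/s) moves elements from R
to A; elements inactivate at a constant rate ``k_AI`` and recover at ``k_IR``.
The synaptic current is proportional to the active-state occupancy:
``c(t) = gain * A(t) + offset``. Use-dependent depletion of R produces
divisive-like gain control engaged at high contrast.

Integration uses per-bin linear transition probabilities ``p = rate * dt``
under an explicit stability precondition (every probability < 0.2). This
scheme conserves occupancy exactly and its fixed point under constant drive
is exactly the continuous-time steady state
``A* = u k_IR / (u k_IR + u k_AI + k_AI k_IR)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize

from . import _optim
from .containers import Recording
from .params import (
    MONOTONE,
    FitConfig,
    Nonlinearity1D,
    TemporalFilter,
    basis_design,
    symmetric_knots,
)
from .stimulus import Stimulus

__all__ = [
    "LNKParams",
    "LNK",
    "LNKResults",
    "LNKComponent",
    "simulate_lnk",
    "fit_lnk",
    "extended_lnk_simulate",
    "lnk_steady_state",
    "center_fraction",
]

_MAX_STEP_PROB = 0.2


@njit(cache=True)
def _lnk_loop(u, p_ai, p_ir, dt_s):
    T = u.shape[0]
    states = np.empty((T, 3))
    R, A, I = 1.0, 0.0, 0.0
    for t in range(T):
        d_ra = R * u[t] * dt_s
        d_ai = A * p_ai
        d_ir = I * p_ir
        R = R - d_ra + d_ir
        A = A + d_ra - d_ai
        I = I + d_ai - d_ir
        states[t, 0] = R
        states[t, 1] = A
        states[t, 2] = I
    return states


def lnk_steady_state(u0: float, k_ai: float, k_ir: float) -> float:
    """Active-state occupancy under constant drive (closed form)."""
    return u0 * k_ir / (u0 * k_ir + u0 * k_ai + k_ai * k_ir)


def _kinetic_states(u: np.ndarray, k_ai: float, k_ir: float, dt_ms: float,
                    check: bool = True) -> np.ndarray:
    dt_s = dt_ms / 1000.0
    if check:
        worst = max(float(np.max(u)) * dt_s, k_ai * dt_s, k_ir * dt_s)
        if worst >= _MAX_STEP_PROB:
            raise ValueError(
                f"step too large: max per-bin transition probability {worst:.3f} "
                f">= {_MAX_STEP_PROB}; reduce dt or the rates"
            )
    return _lnk_loop(np.ascontiguousarray(u, dtype=np.float64), k_ai * dt_s, k_ir * dt_s, dt_s)


@dataclass
class LNKParams:
    """Three-state LNK model parameters.

    ``filter`` is unit-norm; ``input_nl`` (monotone, zero at its left knot,
    hence nonnegative) carries the drive scale in 1/s. ``k_ai`` and ``k_ir``
    are the A->I and I->R rate constants (1/s).
    """

    filter: TemporalFilter
    input_nl: Nonlinearity1D
    k_ai: float
    k_ir: float
    gain: float = 1.0
    offset: float = 0.0
    kind: str = field(default="lnk", init=False)

    def drive(self, stim: Stimulus) -> np.ndarray:
        return np.maximum(self.input_nl(self.filter.apply(stim)), 0.0)

    def simulate(self, stim: Stimulus, dt: float | None = None):
        """Return (current trace, state trajectories R/A/I of shape (T, 3))."""
        dt = stim.dt if dt is None else dt
        states = _kinetic_states(self.drive(stim), self.k_ai, self.k_ir, dt)
        return self.gain * states[:, 1] + self.offset, states

    def predict(self, stim: Stimulus) -> np.ndarray:
        return self.simulate(stim)[0]


def simulate_lnk(model: LNKParams, stim: Stimulus, dt: float | None = None):
    """Simulate the kinetic chain; errors if the step-size stability bound fails."""
    return model.simulate(stim, dt)


@dataclass
class LNKResults:
    model: object = field(repr=False)
    params: LNKParams
    train_mse: float
    restart_mses: list = field(default_factory=list)

    def predict(self, stim: Stimulus | None = None) -> np.ndarray:
        return self.params.predict(stim if stim is not None else self.model.stim)

    def heldout_r2(self, label: str | None = None) -> float:
        from .current import heldout_r2

        return heldout_r2(self.predict(), self.model.stim, self.model.endog, label)

    def summary(self) -> str:
        p = self.params
        lines = [
            "LNK model fit",
            "=" * 40,
            f"train MSE:   {self.train_mse:.6g}",
            f"k_AI:        {p.k_ai:.3g} 1/s",
            f"k_IR:        {p.k_ir:.3g} 1/s",
            f"gain:        {p.gain:.4g}",
            f"offset:      {p.offset:.4g}",
        ]
        try:
            lines.append(f"held-out R^2: {self.heldout_r2():.4f}")
        except ValueError:
            pass
        return "\n".join(lines)


class LNK:
    """Constrained MSE fit of the three-state LNK model.

    Filter coefficients, input-nonlinearity increments and log rate constants
    are optimized jointly (quasi-Newton with bound constraints, multi-start);
    the output gain and offset are profiled out by linear least squares at
    every objective evaluation. The kinetic chain is simulated over the full
    recording so state dynamics carry across segment boundaries; the loss is
    evaluated on the unique (non-repeat) segments only.
    """

    def __init__(self, stim: Stimulus, current, config: FitConfig | None = None):
        from .current import _as_trace

        self.stim = stim
        self.config = config or FitConfig()
        if abs(self.config.dt - stim.dt) > 1e-12:
            self.config = replace(self.config, dt=stim.dt)
        self.endog = _as_trace(current, stim)
        if np.ptp(stim.values) == 0:
            raise ValueError("singular design: stimulus is constant")
        self.basis = self.config.make_temporal_basis()
        self.train_mask = stim.mask(exclude_repeats=True, burn_in_ms=self.config.t_max)
        self.X = basis_design(stim, self.basis)
        self.y = self.endog[self.train_mask]
        self.n_coef = self.X.shape[1]

    @classmethod
    def from_recording(cls, rec: Recording, config: FitConfig | None = None):
        return cls(rec.stimulus, rec.current, config)

    def fit(self) -> LNKResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        a0 = self._init_coeffs()
        tb = symmetric_knots(self.X[self.train_mask] @ a0, cfg.n_knots)
        self._tb = tb
        n_inc = tb.n_funcs - 1
        dt_s = cfg.dt / 1000.0
        u_cap = (_MAX_STEP_PROB * 0.95) / dt_s

        starts = []
        for u_scale, kai0, kir0 in ((30.0, 25.0, 5.0), (80.0, 60.0, 15.0)):
            d0 = np.full(n_inc, u_scale / n_inc)
            starts.append((a0.copy(), d0, np.log(kai0), np.log(kir0)))
        for _ in range(max(cfg.n_random_inits - 1, 0)):
            u_scale = rng.uniform(15.0, 100.0)
            d0 = np.full(n_inc, u_scale / n_inc) * rng.uniform(0.5, 1.5, n_inc)
            starts.append(
                (a0.copy(), d0, np.log(rng.uniform(5.0, 80.0)), np.log(rng.uniform(1.0, 30.0)))
            )

        best = None
        restart_mses = []
        for a_init, d_init, lkai, lkir in starts:
            theta0 = np.concatenate([a_init, d_init, [lkai, lkir]])
            lb = np.concatenate(
                [np.full(self.n_coef, -np.inf), np.zeros(n_inc), [np.log(0.1), np.log(0.1)]]
            )
            ub = np.concatenate(
                [np.full(self.n_coef, np.inf), np.full(n_inc, u_cap), [np.log(500.0), np.log(500.0)]]
            )
            res = minimize(
                self._objective,
                theta0,
                args=(u_cap,),
                method="L-BFGS-B",
                bounds=list(zip(lb, ub)),
                options={"maxiter": 150},
            )
            restart_mses.append(float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        params = self._unpack(best.x, u_cap)
        return LNKResults(self, params, float(best.fun), restart_mses)

    # -- internals -------------------------------------------------------
    def _init_coeffs(self) -> np.ndarray:
        y = self.y - self.y.mean()
        a = _optim.solve_lsq(self.X[self.train_mask], y)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("singular design: response uncorrelated with stimulus")
        return a / n

    def _split(self, theta):
        n, nk = self.n_coef, self._tb.n_funcs
        a = theta[: n]
        d = theta[n: n + nk - 1]
        k_ai, k_ir = np.exp(theta[-2]), np.exp(theta[-1])
        return a, d, k_ai, k_ir

    def _objective(self, theta, u_cap):
        a, d, k_ai, k_ir = self._split(theta)
        nrm = np.linalg.norm(a)
        if nrm == 0:
            return 1e12
        g = self.X @ (a / nrm)
        w = np.concatenate([[0.0], np.cumsum(d)])
        u = np.clip(self._tb.interp(g, w), 0.0, u_cap)
        states = _kinetic_states(u, min(k_ai, u_cap), min(k_ir, u_cap), self.config.dt, check=False)
        A = states[self.train_mask, 1]
        D = np.column_stack([A, np.ones(len(A))])
        coef = _optim.solve_lsq(D, self.y)
        resid = D @ coef - self.y
        return float(np.mean(resid**2))

    def _unpack(self, theta, u_cap) -> LNKParams:
        a, d, k_ai, k_ir = self._split(theta)
        a = a / np.linalg.norm(a)
        w = np.concatenate([[0.0], np.cumsum(d)])
        g = self.X @ a
        u = np.clip(self._tb.interp(g, w), 0.0, u_cap)
        states = _kinetic_states(u, min(k_ai, u_cap), min(k_ir, u_cap), self.config.dt, check=False)
        A = states[self.train_mask, 1]
        D = np.column_stack([A, np.ones(len(A))])
        gain, offset = _optim.solve_lsq(D, self.y)
        nf = self.basis.n_funcs
        return LNKParams(
            filter=TemporalFilter(self.basis, a.reshape(nf, -1, order="F")),
            input_nl=Nonlinearity1D(self._tb, w, MONOTONE),
            k_ai=float(k_ai),
            k_ir=float(k_ir),
            gain=float(gain),
            offset=float(offset),
        )


def fit_lnk(stim, current, cfg: FitConfig | None = None) -> LNKResults:
    return LNK(stim, current, cfg).fit()


@dataclass
class LNKComponent:
    """One rectified pathway of an extended (spot/annulus) LNK circuit."""

    filter: TemporalFilter
    weight: float
    channel: int = 0
    rectifier: object | None = None  # callable; default max(0, x)

    def drive(self, stim: Stimulus) -> np.ndarray:
        from .params import apply_filter

        sub = Stimulus(
            values=stim.values[:, self.channel],
            dt=stim.dt,
            mean_level=stim.mean_level,
            schedule=stim.schedule,
            repeat_windows=stim.repeat_windows,
        )
        g = apply_filter(self.filter, sub)
        rect = self.rectifier if self.rectifier is not None else lambda x: np.maximum(x, 0.0)
        return self.weight * rect(g)


def extended_lnk_simulate(
    variant: str,
    components: list[LNKComponent],
    rates: tuple[float, float],
    stim: Stimulus,
    gain: float = 1.0,
    offset: float = 0.0,
):
    """Simulate center/surround LNK circuits with shared or independent kinetics.

    ``variant="shared_depression"`` feeds the summed rectified channel drives
    into a single kinetic stage; ``"independent_depression"`` runs one kinetic
    stage per component (same rate constants) and sums the active-state
    outputs. Returns (current trace, list of per-stage state trajectories).
    """
    k_ai, k_ir = rates
    if variant == "shared_depression":
        u = np.sum([c.drive(stim) for c in components], axis=0)
        states = _kinetic_states(np.maximum(u, 0.0), k_ai, k_ir, stim.dt)
        return gain * states[:, 1] + offset, [states]
    if variant == "independent_depression":
        all_states = []
        total = np.zeros(stim.n_bins)
        for c in components:
            states = _kinetic_states(np.maximum(c.drive(stim), 0.0), k_ai, k_ir, stim.dt)
            all_states.append(states)
            total += states[:, 1]
        return gain * total + offset, all_states
    raise ValueError(f"unknown variant {variant!r}")


def center_fraction(filt: TemporalFilter, center_channel: int = 0) -> float:
    """Norm of the center-channel kernel divided by the norm of the full kernel."""
    k = filt.kernel
    return float(np.linalg.norm(k[:, center_channel]) / np.linalg.norm(k))
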