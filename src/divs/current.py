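"""Models of continuous synaptic-current responses: LN, DivS, AddS, 2-D.

Each model class is constructed from a stimulus and a continuous current
trace and exposes ``fit()`` returning a Results object (statsmodels-style).
Fitting minimizes mean-squared error between predicted and observed current
on the unique (non-repeat) stimulus segments by block-coordinate descent:
filter-coefficient updates (quasi-Newton, on the orthonormal temporal basis)
alternate with nonlinearity-weight updates (constrained linear least squares
on the tent/pyramid bases). Temporal filters are kept at unit L2 norm after
every update — the nonlinearities carry all gain — and every block update is
accepted only if it does not increase the training MSE, so the MSE path is
non-increasing by construction.

Constraints (enforced exactly at every iterate):

* DivS: ``fe`` monotone increasing with ``fe = 0`` at the leftmost knot;
  ``fs`` in [0, 1] with ``fs(0) = 1``.
* AddS: ``fe`` as above; ``fs <= 0`` with ``fs(0) = 0``.
* 2-D: surface monotone non-decreasing along the excitatory axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import _optim
from .basis import PyramidBasis2D, pyramid_basis_2d
from .containers import Recording, TrialSet
from .params import (
    MONOTONE,
    NONPOSITIVE,
    SUPPRESSIVE,
    AddSParams,
    DivSParams,
    FitConfig,
    LNParams,
    Nonlinearity1D,
    Surface2DParams,
    TemporalFilter,
    basis_design,
    shifted_coeffs,
    symmetric_knots,
)
from .stimulus import Stimulus

__all__ = [
    "LN",
    "DivS",
    "AddS",
    "Surface2D",
    "CurrentResults",
    "fit_ln",
    "fit_divs",
    "fit_adds",
    "fit_2d",
    "predict_current",
    "separability_r2",
    "best_separable_r2",
    "heldout_r2",
]


def _as_trace(current, stim: Stimulus) -> np.ndarray:
    if isinstance(current, Recording):
        current = current.current
    if isinstance(current, TrialSet):
        if current.n_trials != 1 and current.n_bins != stim.n_bins:
            raise ValueError("pass the continuous trace, not repeat trials")
        current = current.trials.mean(axis=0) if current.n_trials > 1 else current.trials[0]
    trace = np.asarray(current, dtype=float).ravel()
    if len(trace) != stim.n_bins:
        raise ValueError("current trace must be aligned to the stimulus")
    return trace


def heldout_r2(pred: np.ndarray, stim: Stimulus, current: np.ndarray,
               label: str | None = None) -> float:
    """R^2 of a full-length prediction on the repeat (cross-validation) windows.

    The prediction and the observed current are averaged across the repeat
    windows of each contrast (the repeated stimulus makes those windows
    trials) before comparing.
    """
    current = np.asarray(current, dtype=float).ravel()
    labels = sorted({stim.label_of(w[0]) for w in stim.repeat_windows}) if label is None else [label]
    pred_parts, obs_parts = [], []
    for lab in labels:
        windows = stim.repeat_windows_for(lab)
        if not windows:
            raise ValueError(f"no repeat windows for label {lab!r}")
        pred_parts.append(np.mean([pred[stim.window_slice(w)] for w in windows], axis=0))
        obs_parts.append(np.mean([current[stim.window_slice(w)] for w in windows], axis=0))
    p = np.concatenate(pred_parts)
    o = np.concatenate(obs_parts)
    ss_res = float(np.sum((p - o) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed repeat response has zero variance")
    return 1.0 - ss_res / ss_tot


class _CurrentModel:
    """Shared data preparation for the current-response models."""

    def __init__(self, stim: Stimulus, current, config: FitConfig | None = None):
        self.stim = stim
        self.config = config or FitConfig()
        if abs(self.config.dt - stim.dt) > 1e-12:
            self.config = replace(self.config, dt=stim.dt)
        self.endog = _as_trace(current, stim)
        if np.ptp(stim.values) == 0:
            raise ValueError("singular design: stimulus is constant")
        self.basis = self.config.make_temporal_basis()
        self.train_mask = stim.mask(exclude_repeats=True, burn_in_ms=self.config.t_max)
        self._design_full = basis_design(stim, self.basis)
        self.X = self._design_full[self.train_mask]
        self.y = self.endog[self.train_mask]
        self.n_coef = self.X.shape[1]

    @classmethod
    def from_recording(cls, rec: Recording, config: FitConfig | None = None):
        return cls(rec.stimulus, rec.current, config)

    # -- initialization -------------------------------------------------
    def _regression_init(self) -> np.ndarray:
        """Whitened reverse-correlation (ridge regression) filter coefficients."""
        y = self.y - self.y.mean()
        a = _optim.solve_lsq(self.X, y)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("singular design: response uncorrelated with stimulus")
        return a / n

    def _random_coeffs(self, rng) -> np.ndarray:
        a = rng.standard_normal(self.n_coef)
        return a / np.linalg.norm(a)

    def _filter_update(self, a0, loss_grad):
        """Quasi-Newton update of filter coefficients for a smooth loss."""
        res = minimize(
            loss_grad,
            a0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.config.inner_maxiter},
        )
        a = res.x
        n = np.linalg.norm(a)
        return a / n if n > 0 else a0


@dataclass
class CurrentResults:
    """Fit results for a current-response model.

    Attributes
    ----------
    params : LNParams | DivSParams | AddSParams | Surface2DParams
        The fitted parameter container (``results.params.predict(stim)``
        evaluates the model).
    mse_path : ndarray
        Training MSE after each accepted outer iteration (non-increasing).
    restart_mses : list of float
        Final training MSE of every initialization tried.
    """

    model: object = field(repr=False)
    params: object
    mse_path: np.ndarray
    converged: bool
    restart_mses: list = field(default_factory=list)

    @property
    def train_mse(self) -> float:
        return float(self.mse_path[-1])

    def predict(self, stim: Stimulus | None = None) -> np.ndarray:
        return self.params.predict(stim if stim is not None else self.model.stim)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def heldout_r2(self, label: str | None = None) -> float:
        return heldout_r2(self.predict(), self.model.stim, self.model.endog, label)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{type(p).__name__.replace('Params', '')} model fit",
            "=" * 40,
            f"observations (train): {self.model.y.size}",
            f"train MSE:            {self.train_mse:.6g}",
            f"outer iterations:     {len(self.mse_path)}",
            f"converged:            {self.converged}",
        ]
        try:
            lines.append(f"held-out R^2:         {self.heldout_r2():.4f}")
        except ValueError:
            pass
        if hasattr(p, "delay_ms"):
            lines.append(f"suppressive delay:    {p.delay_ms():.1f} ms")
        if hasattr(p, "offset"):
            lines.append(f"offset c0:            {p.offset:.4g}")
        return "\n".join(lines)

    def plot_components(self, ax=None):
        """Plot fitted kernels (and nonlinearities when present)."""
        import matplotlib.pyplot as plt

        p = self.params
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(8, 3))
        lags = self.model.basis.lags_ms
        if hasattr(p, "filter"):
            ax[0].plot(lags, p.filter.kernel, label="k")
            x = p.nonlinearity.basis.knots
            ax[1].plot(x, p.nonlinearity(x), label="f")
        else:
            ax[0].plot(lags, p.exc_filter.kernel, label="exc", color="g")
            ax[0].plot(lags, p.sup_filter.kernel, label="sup", color="c")
            if hasattr(p, "exc_nl"):
                ax[1].plot(p.exc_nl.basis.knots, p.exc_nl(p.exc_nl.basis.knots), "g")
                ax[1].plot(p.sup_nl.basis.knots, p.sup_nl(p.sup_nl.basis.knots), "c")
        ax[0].set_xlabel("lag (ms)")
        ax[0].legend()
        return ax


class LN(_CurrentModel):
    """Linear-nonlinear cascade fit to a synaptic-current trace."""

    def fit(self) -> CurrentResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        inits = [self._regression_init()]
        inits += [self._random_coeffs(rng) for _ in range(cfg.n_random_inits)]
        best = None
        restart_mses = []
        for a0 in inits:
            out = self._fit_single(a0)
            restart_mses.append(out[-1][-1])
            if best is None or out[-1][-1] < best[-1][-1]:
                best = out
        a, tb, w, path = best
        a, w = self._canonical_sign(a, tb, w)
        filt = TemporalFilter(self.basis, a.reshape(self.basis.n_funcs, -1, order="F"))
        params = LNParams(filter=filt, nonlinearity=Nonlinearity1D(tb, w, None), offset=0.0)
        converged = len(path) < cfg.max_outer_iters
        return CurrentResults(self, params, np.array(path), converged, restart_mses)

    def _fit_single(self, a):
        cfg = self.config
        g = self.X @ a
        tb = symmetric_knots(g, cfg.n_knots)
        w = _optim.solve_lsq(tb.design(g), self.y)
        mse = float(np.mean((tb.interp(g, w) - self.y) ** 2))
        path = [mse]
        for _ in range(cfg.max_outer_iters):
            a_new = self._filter_update(a, self._make_loss(tb, w))
            g_new = self.X @ a_new
            w_new = _optim.solve_lsq(tb.design(g_new), self.y)
            mse_new = float(np.mean((tb.interp(g_new, w_new) - self.y) ** 2))
            if mse_new <= mse:
                a, w, g = a_new, w_new, g_new
                improved = mse - mse_new
                mse = mse_new
                path.append(mse)
                if improved < cfg.rel_tol * max(mse, 1e-300):
                    break
            else:
                break
        return a, tb, w, path

    def _make_loss(self, tb, w):
        X, y = self.X, self.y

        def loss_grad(a):
            g = X @ a
            resid = tb.interp(g, w) - y
            grad = 2.0 / len(y) * (X.T @ (resid * tb.deriv(g, w)))
            return float(np.mean(resid**2)), grad

        return loss_grad

    @staticmethod
    def _canonical_sign(a, tb, w):
        """Orient the filter so the nonlinearity is on-average increasing."""
        slope = np.polyfit(tb.knots, w, 1)[0]
        if slope < 0:
            return -a, w[::-1].copy()
        return a, w


class _TwoFilterModel(_CurrentModel):
    """Shared machinery for DivS and AddS (multiplicative vs additive)."""

    multiplicative: bool

    def fit(self, from_ln: CurrentResults | None = None) -> CurrentResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        ae0 = self._regression_init()
        inits = []
        if from_ln is not None:
            a_ln = from_ln.params.filter.coeffs.ravel(order="F")
            a_ln = a_ln / np.linalg.norm(a_ln)
            inits.append((a_ln, shifted_coeffs(self.basis, a_ln, 8.0)))
        inits.append((ae0, shifted_coeffs(self.basis, ae0, 8.0)))
        inits += [(ae0, self._random_coeffs(rng)) for _ in range(cfg.n_random_inits)]
        best = None
        restart_mses = []
        for ae, as_ in inits:
            out = self._fit_single(ae, as_, from_ln)
            restart_mses.append(out["path"][-1])
            if best is None or out["path"][-1] < best["path"][-1]:
                best = out
        params = self._pack(best)
        converged = len(best["path"]) < cfg.max_outer_iters
        return CurrentResults(self, params, np.array(best["path"]), converged, restart_mses)

    # -- block updates ---------------------------------------------------
    def _predict_train(self, st):
        fe = st["tbe"].interp(st["ge"], st["we"])
        fs = st["tbs"].interp(st["gs"], st["ws"])
        if self.multiplicative:
            return fe * fs + st["c0"]
        return fe + fs + st["c0"]

    def _mse(self, st):
        return float(np.mean((self._predict_train(st) - self.y) ** 2))

    def _update_exc_nl(self, st):
        """fe (monotone, anchored at 0) and offset c0, jointly: linear LSQ."""
        D = st["tbe"].design(st["ge"])
        if self.multiplicative:
            fs = st["tbs"].interp(st["gs"], st["ws"])
            A = D * fs[:, None]
            target = self.y
        else:
            A = D
            target = self.y - st["tbs"].interp(st["gs"], st["ws"])
        C = _optim.monotone_map(st["tbe"].n_funcs, anchor_first_zero=True)
        Afull = np.column_stack([A @ C, np.ones(len(target))])
        lb = np.zeros(Afull.shape[1])
        lb[-1] = -np.inf
        sol = _optim.solve_bounded(Afull, target, lb, np.full(Afull.shape[1], np.inf))
        st["we"] = C @ sol[:-1]
        st["c0"] = float(sol[-1])

    def _update_sup_nl(self, st):
        """fs with its anchor knot at x=0 fixed (1 for DivS, 0 for AddS)."""
        D = st["tbs"].design(st["gs"])
        i0 = st["tbs"].n_funcs // 2  # symmetric grid: middle knot is x = 0
        fe = st["tbe"].interp(st["ge"], st["we"])
        if self.multiplicative:
            A = D * fe[:, None]
            target = self.y - st["c0"] - A[:, i0] * 1.0
            lb, ub = 0.0, 1.0
            anchor = 1.0
        else:
            A = D
            target = self.y - st["c0"] - fe
            lb, ub = -np.inf, 0.0
            anchor = 0.0
        keep = np.ones(A.shape[1], dtype=bool)
        keep[i0] = False
        sol = _optim.solve_bounded(
            A[:, keep], target,
            np.full(keep.sum(), lb), np.full(keep.sum(), ub),
        )
        ws = np.empty(A.shape[1])
        ws[keep] = sol
        ws[i0] = anchor
        st["ws"] = ws

    def _filter_loss(self, st, which):
        X, y = self.X, self.y
        tbe, tbs = st["tbe"], st["tbs"]
        we, ws, c0 = st["we"], st["ws"], st["c0"]
        mult = self.multiplicative
        if which == "exc":
            other = tbs.interp(st["gs"], ws)

            def loss_grad(a):
                g = X @ a
                fe = tbe.interp(g, we)
                pred = fe * other + c0 if mult else fe + other + c0
                resid = pred - y
                chain = resid * tbe.deriv(g, we)
                if mult:
                    chain = chain * other
                return float(np.mean(resid**2)), 2.0 / len(y) * (X.T @ chain)

        else:
            fe = tbe.interp(st["ge"], we)

            def loss_grad(a):
                g = X @ a
                fs = tbs.interp(g, ws)
                pred = fe * fs + c0 if mult else fe + fs + c0
                resid = pred - y
                chain = resid * tbs.deriv(g, ws)
                if mult:
                    chain = chain * fe
                return float(np.mean(resid**2)), 2.0 / len(y) * (X.T @ chain)

        return loss_grad

    def _joint_filter_loss(self, st):
        """Loss and gradient in the concatenated (exc, sup) coefficients."""
        X, y = self.X, self.y
        tbe, tbs = st["tbe"], st["tbs"]
        we, ws, c0 = st["we"], st["ws"], st["c0"]
        mult = self.multiplicative
        n = self.n_coef

        def loss_grad(a):
            ge = X @ a[:n]
            gs = X @ a[n:]
            fe = tbe.interp(ge, we)
            fs = tbs.interp(gs, ws)
            pred = fe * fs + c0 if mult else fe + fs + c0
            resid = pred - y
            ce = resid * tbe.deriv(ge, we)
            cs = resid * tbs.deriv(gs, ws)
            if mult:
                ce = ce * fs
                cs = cs * fe
            grad = 2.0 / len(y) * np.concatenate([X.T @ ce, X.T @ cs])
            return float(np.mean(resid**2)), grad

        return loss_grad

    def _fit_single(self, ae, as_, from_ln=None):
        cfg = self.config
        st = {"ae": ae, "as": as_, "ge": self.X @ ae, "gs": self.X @ as_, "c0": 0.0}
        st["tbe"] = symmetric_knots(st["ge"], cfg.n_knots)
        st["tbs"] = symmetric_knots(st["gs"], cfg.n_knots)
        st["we"] = np.zeros(st["tbe"].n_funcs)
        if from_ln is not None and self.multiplicative:
            # nested start: suppression inactive (fs = 1 everywhere)
            st["ws"] = np.ones(st["tbs"].n_funcs)
        else:
            x = st["tbs"].knots
            if self.multiplicative:
                st["ws"] = np.clip(1.0 - 0.3 * (x / x[-1]) ** 2, 0.0, 1.0)
                st["ws"][len(x) // 2] = 1.0
            else:
                st["ws"] = -0.1 * np.abs(x)
                st["ws"][len(x) // 2] = 0.0
        self._update_exc_nl(st)
        mse = self._mse(st)
        path = [mse]
        for _ in range(cfg.max_outer_iters):
            mse_before = mse
            self._update_exc_nl(st)
            self._update_sup_nl(st)
            mse = min(mse, self._mse(st))
            for which in ("exc", "sup"):
                key_a, key_g = ("ae", "ge") if which == "exc" else ("as", "gs")
                a_new = self._filter_update(st[key_a], self._filter_loss(st, which))
                trial = dict(st)
                trial[key_a] = a_new
                trial[key_g] = self.X @ a_new
                if which == "exc":
                    self._update_exc_nl(trial)
                else:
                    self._update_sup_nl(trial)
                if self._mse(trial) <= mse:
                    st = trial
                    mse = self._mse(st)
            # joint filter update breaks coordinate-wise stalls
            res = minimize(
                self._joint_filter_loss(st),
                np.concatenate([st["ae"], st["as"]]),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.config.inner_maxiter},
            )
            n = self.n_coef
            trial = dict(st)
            for key, a_new in (("ae", res.x[:n]), ("as", res.x[n:])):
                nrm = np.linalg.norm(a_new)
                trial[key] = a_new / nrm if nrm > 0 else st[key]
            trial["ge"] = self.X @ trial["ae"]
            trial["gs"] = self.X @ trial["as"]
            self._update_exc_nl(trial)
            self._update_sup_nl(trial)
            if self._mse(trial) <= mse:
                st = trial
                mse = self._mse(st)
            path.append(mse)
            if mse_before - mse < cfg.rel_tol * max(mse, 1e-300):
                break
        st["path"] = path
        return st

    def _pack(self, st):
        nf = self.basis.n_funcs
        ae = st["ae"].reshape(nf, -1, order="F")
        as_ = st["as"].reshape(nf, -1, order="F")
        # canonical suppressive-filter sign: aligned with excitation
        if float(np.dot(st["ae"], st["as"])) < 0:
            as_ = -as_
            st["ws"] = st["ws"][::-1].copy()
        cls = DivSParams if self.multiplicative else AddSParams
        return cls(
            exc_filter=TemporalFilter(self.basis, ae),
            exc_nl=Nonlinearity1D(st["tbe"], st["we"], MONOTONE),
            sup_filter=TemporalFilter(self.basis, as_),
            sup_nl=Nonlinearity1D(
                st["tbs"], st["ws"], SUPPRESSIVE if self.multiplicative else NONPOSITIVE
            ),
            offset=st["c0"],
        )


class DivS(_TwoFilterModel):
    """Divisive-suppression model: fe[ke.s] * fs[ks.s] + c0."""

    multiplicative = True


class AddS(_TwoFilterModel):
    """Additive-suppression control model: fe[ke.s] + fs[ks.s] + c0."""

    multiplicative = False


class Surface2D(_CurrentModel):
    """Nonparametric 2-D nonlinearity over a fixed or jointly-refined filter pair."""

    def __init__(self, stim, current, filters, config=None):
        super().__init__(stim, current, config)
        ke, ks = filters
        self.ae = ke.coeffs.ravel(order="F").copy()
        self.as_ = ks.coeffs.ravel(order="F").copy()

    def fit(self, refine_filters: bool = True) -> CurrentResults:
        cfg = self.config
        ae, as_ = self.ae, self.as_
        ge, gs = self.X @ ae, self.X @ as_
        n = cfg.grid_n
        pyr = pyramid_basis_2d(
            np.linspace(*self._span(ge), n), np.linspace(*self._span(gs), n)
        )
        w = self._surface_update(pyr, ge, gs)
        mse = self._mse2d(pyr, w, ge, gs)
        path = [mse]
        n_outer = cfg.max_outer_iters if refine_filters else 1
        for it in range(n_outer):
            mse_before = mse
            if refine_filters and it > 0:
                for which in ("exc", "sup"):
                    a0 = ae if which == "exc" else as_
                    a_new = self._filter_update(
                        a0, self._surface_filter_loss(pyr, w, ge, gs, which)
                    )
                    ge_t = self.X @ a_new if which == "exc" else ge
                    gs_t = self.X @ a_new if which == "sup" else gs
                    w_t = self._surface_update(pyr, ge_t, gs_t)
                    if self._mse2d(pyr, w_t, ge_t, gs_t) <= mse:
                        if which == "exc":
                            ae, ge = a_new, ge_t
                        else:
                            as_, gs = a_new, gs_t
                        w = w_t
                        mse = self._mse2d(pyr, w, ge, gs)
            else:
                w = self._surface_update(pyr, ge, gs)
                mse = min(mse, self._mse2d(pyr, w, ge, gs))
            path.append(mse)
            if mse_before - mse < cfg.rel_tol * max(mse, 1e-300):
                break
        nf = self.basis.n_funcs
        params = Surface2DParams(
            exc_filter=TemporalFilter(self.basis, ae.reshape(nf, -1, order="F")),
            sup_filter=TemporalFilter(self.basis, as_.reshape(nf, -1, order="F")),
            surface_basis=pyr,
            weights=w.reshape(pyr.shape),
        )
        converged = len(path) - 1 < n_outer
        return CurrentResults(self, params, np.array(path), converged, [path[-1]])

    @staticmethod
    def _span(g):
        m = abs(float(g.mean())) + 3.0 * float(g.std())
        return -m, m

    def _surface_update(self, pyr: PyramidBasis2D, ge, gs):
        """Monotone-along-x surface weights by bounded least squares."""
        from scipy import sparse

        P = pyr.design(ge, gs)
        nx, ny = pyr.shape
        # params: base level per column j, then nonnegative increments along x
        n_par = ny + (nx - 1) * ny
        rows, cols, vals = [], [], []
        for i in range(nx):
            for j in range(ny):
                v = i * ny + j
                rows.append(v)
                cols.append(j)
                vals.append(1.0)
                for ii in range(i):
                    rows.append(v)
                    cols.append(ny + ii * ny + j)
                    vals.append(1.0)
        M = sparse.csr_matrix((vals, (rows, cols)), shape=(nx * ny, n_par))
        A = P @ M
        lb = np.concatenate([np.full(ny, -np.inf), np.zeros(n_par - ny)])
        sol = _optim.solve_bounded(A, self.y, lb, np.full(n_par, np.inf))
        return np.asarray(M @ sol)

    def _mse2d(self, pyr, w, ge, gs):
        return float(np.mean((pyr.interp(ge, gs, w) - self.y) ** 2))

    def _surface_filter_loss(self, pyr, w, ge, gs, which):
        X, y = self.X, self.y

        def loss_grad(a):
            g = X @ a
            ge_, gs_ = (g, gs) if which == "exc" else (ge, g)
            pred = pyr.interp(ge_, gs_, w)
            resid = pred - y
            fx, fy = pyr.gradient(ge_, gs_, w)
            chain = resid * (fx if which == "exc" else fy)
            return float(np.mean(resid**2)), 2.0 / len(y) * (X.T @ chain)

        return loss_grad


def best_separable_r2(surface: Surface2DParams, stim: Stimulus | None = None,
                      max_iter: int = 100) -> float:
    """R^2 of the best product-plus-offset approximation to a 2-D surface.

    Finds ``a_i b_j + c`` minimizing the (density-weighted) squared deviation
    from the surface values on its grid by alternating least squares, and
    returns the weighted R^2. This measures how separable the surface is
    without reference to any particular DivS fit.
    """
    pyr = surface.surface_basis
    F = surface.weights
    if stim is not None:
        ge = surface.exc_filter.apply(stim)
        gs = surface.sup_filter.apply(stim)
        ix = np.clip(np.searchsorted(pyr.grid_x, ge), 0, len(pyr.grid_x) - 1)
        iy = np.clip(np.searchsorted(pyr.grid_y, gs), 0, len(pyr.grid_y) - 1)
        w = np.zeros(pyr.shape)
        np.add.at(w, (ix, iy), 1.0)
        w += 1e-12
    else:
        w = np.ones(pyr.shape)
    c = float((w * F).sum() / w.sum())
    # init b from the dominant right singular vector of the centered surface
    _, _, vt = np.linalg.svd(F - c)
    b = vt[0]
    a = np.ones(F.shape[0])
    prev = np.inf
    for _ in range(max_iter):
        denom_a = w @ (b**2)
        a = ((w * (F - c)) @ b) / np.where(denom_a > 0, denom_a, 1.0)
        denom_b = w.T @ (a**2)
        b = ((w * (F - c)).T @ a) / np.where(denom_b > 0, denom_b, 1.0)
        c = float((w * (F - np.outer(a, b))).sum() / w.sum())
        sse = float((w * (F - np.outer(a, b) - c) ** 2).sum())
        if prev - sse < 1e-12 * max(prev, 1.0):
            break
        prev = sse
    mean_F = float((w * F).sum() / w.sum())
    ss_tot = float((w * (F - mean_F) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if sse == 0 else 0.0
    return 1.0 - sse / ss_tot


def separability_r2(
    surface: Surface2DParams, divs: DivSParams, stim: Stimulus | None = None
) -> float:
    """How well the separable DivS product reproduces the 2-D surface.

    Evaluates the fitted surface ``F[x, y]`` on its grid and compares it to
    ``fe(x) * fs(y) + c0``, weighting vertices by the empirical density of the
    generator signals when a stimulus is given (uniform weights otherwise).
    """
    pyr = surface.surface_basis
    gx, gy = pyr.grid_x, pyr.grid_y
    F = surface.weights
    prod = np.outer(divs.exc_nl(gx), divs.sup_nl(gy)) + divs.offset
    if stim is not None:
        ge = surface.exc_filter.apply(stim)
        gs = surface.sup_filter.apply(stim)
        ix = np.clip(np.searchsorted(gx, ge), 0, len(gx) - 1)
        iy = np.clip(np.searchsorted(gy, gs), 0, len(gy) - 1)
        wgt = np.zeros(pyr.shape)
        np.add.at(wgt, (ix, iy), 1.0)
    else:
        wgt = np.ones(pyr.shape)
    wsum = wgt.sum()
    mean_F = float((wgt * F).sum() / wsum)
    ss_res = float((wgt * (F - prod) ** 2).sum())
    ss_tot = float((wgt * (F - mean_F) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


# -- thin functional surface over the model classes ----------------------

def fit_ln(stim, current, cfg: FitConfig | None = None) -> CurrentResults:
    return LN(stim, current, cfg).fit()


def fit_divs(stim, current, cfg: FitConfig | None = None, from_ln=None) -> CurrentResults:
    return DivS(stim, current, cfg).fit(from_ln=from_ln)


def fit_adds(stim, current, cfg: FitConfig | None = None) -> CurrentResults:
    return AddS(stim, current, cfg).fit()


def fit_2d(stim, current, filters, cfg: FitConfig | None = None,
           refine_filters: bool = True) -> CurrentResults:
    return Surface2D(stim, current, filters, cfg).fit(refine_filters=refine_filters)


def predict_current(params, stim: Stimulus) -> np.ndarray:
    """Deterministic model output at the stimulus resolution."""
    return params.predict(stim)
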