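"""Model parameter containers: temporal filters, nonlinearities, fit settings.

Parameter objects are plain dataclasses with prediction methods; estimation
lives in the model classes (:mod:`divs.current`, :mod:`divs.kinetics`,
:mod:`divs.spiking`), whose ``fit()`` methods return Results objects wrapping
these containers — the same division of labor as statsmodels'
``Model.fit() -> Results`` with ``results.params``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .basis import TemporalBasis, TentBasis, temporal_basis, tent_basis
from .stimulus import Stimulus

__all__ = [
    "FitConfig",
    "TemporalFilter",
    "Nonlinearity1D",
    "LNParams",
    "DivSParams",
    "AddSParams",
    "Surface2DParams",
    "apply_filter",
]

MONOTONE = "monotone_increasing"
SUPPRESSIVE = "suppressive_unit"
NONPOSITIVE = "nonpositive"


@dataclass
class FitConfig:
    """Settings shared by the fitting routines.

    Defaults: 12 temporal basis functions over 200 ms at 1-ms bins, 21 tent
    knots spanning ±3 SD of the generator-signal distribution, 15×15 vertices
    for 2-D surfaces, block-coordinate descent until the relative MSE (or LL)
    change falls below ``rel_tol`` or ``max_outer_iters`` is reached, with the
    data-driven initialization plus ``n_random_inits`` seeded random restarts.
    """

    dt: float = 1.0
    t_max: float = 200.0
    n_basis: int = 12
    n_knots: int = 21
    grid_n: int = 15
    max_outer_iters: int = 100
    rel_tol: float = 1e-6
    n_random_inits: int = 5
    seed: int = 0
    inner_maxiter: int = 60
    n_history_basis: int = 8
    history_t_max: float = 100.0

    def __post_init__(self):
        if self.max_outer_iters < 1 or self.n_basis < 1 or self.n_knots < 3:
            raise ValueError("counts must be positive (n_knots >= 3)")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")

    def make_temporal_basis(self) -> TemporalBasis:
        return temporal_basis(self.n_basis, self.t_max, self.dt)


@dataclass
class TemporalFilter:
    """A temporal kernel expressed as basis coefficients, one column per channel.

    When ``unit_norm`` is set the L2 norm of the concatenated multi-channel
    kernel is fixed to 1 (the basis is orthonormal, so this equals the
    coefficient norm); the paired nonlinearity then carries all gain, which
    resolves the amplitude degeneracy of LN-type cascades.
    """

    basis: TemporalBasis
    coeffs: np.ndarray
    unit_norm: bool = True

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        self.coeffs = c

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def kernel(self) -> np.ndarray:
        """Expanded discrete kernel, shape (n_lags, n_channels)."""
        return self.basis.expand(self.coeffs)

    @property
    def n_lags(self) -> int:
        return self.basis.n_bins

    def norm(self) -> float:
        return float(np.linalg.norm(self.coeffs))

    def normalized(self) -> tuple["TemporalFilter", float]:
        """Unit-norm copy and the scale that was removed."""
        scale = self.norm()
        if scale == 0:
            raise ValueError("cannot normalize a zero filter")
        return replace(self, coeffs=self.coeffs / scale), scale

    def peak_lag_ms(self, channel: int = 0) -> float:
        k = self.kernel[:, channel]
        return float(np.argmax(np.abs(k)) * self.basis.dt)

    def apply(self, stim: Stimulus) -> np.ndarray:
        return apply_filter(self, stim)


def apply_filter(filt: TemporalFilter, stim: Stimulus) -> np.ndarray:
    """Causal convolution g(t) = sum_ch sum_tau k(tau) s_ch(t - tau).

    The first ``t_max`` of output is filter burn-in (it sees zero-padded
    history); fitting routines mask it via :meth:`Stimulus.mask`.
    """
    if stim.n_channels != filt.n_channels:
        raise ValueError(
            f"stimulus has {stim.n_channels} channels but filter has {filt.n_channels}"
        )
    kern = filt.kernel
    g = np.zeros(stim.n_bins)
    for c in range(filt.n_channels):
        g += fftconvolve(stim.values[:, c], kern[:, c])[: stim.n_bins]
    return g


def lagged_design(s: np.ndarray, n_lags: int) -> np.ndarray:
    """Matrix D with D[t, tau] = s[t - tau] (zero-padded), shape (T, n_lags)."""
    s = np.asarray(s, dtype=float).ravel()
    padded = np.concatenate([np.zeros(n_lags - 1), s])
    return np.lib.stride_tricks.sliding_window_view(padded, n_lags)[:, ::-1]


def basis_design(stim: Stimulus, basis: TemporalBasis) -> np.ndarray:
    """Design matrix mapping filter coefficients to the generator signal.

    Shape (T, n_funcs * n_channels): columns are the stimulus convolved with
    each basis function, channel blocks concatenated, so that
    ``design @ coeffs.ravel(order='F')`` equals ``apply_filter``.
    """
    blocks = []
    for c in range(stim.n_channels):
        D = lagged_design(stim.values[:, c], basis.n_bins)
        blocks.append(D @ basis.matrix)
    return np.concatenate(blocks, axis=1)


def shifted_coeffs(basis: TemporalBasis, coeffs: np.ndarray, shift_ms: float) -> np.ndarray:
    """Coefficients of the kernel delayed by ``shift_ms`` (unit-normalized)."""
    a = np.asarray(coeffs, dtype=float)
    flat = a.ndim == 1
    if flat:
        a = a[:, None]
    t = basis.lags_ms
    k = basis.expand(a)
    shifted = np.column_stack(
        [np.interp(t - shift_ms, t, k[:, c], left=0.0) for c in range(k.shape[1])]
    )
    out = basis.project(shifted)
    nrm = np.linalg.norm(out)
    if nrm > 0:
        out = out / nrm
    return out.ravel(order="F") if flat else out


@dataclass
class Nonlinearity1D:
    """Piecewise-linear nonlinearity: tent-basis weights with an optional constraint.

    ``constraint`` is one of ``None``, ``"monotone_increasing"``,
    ``"suppressive_unit"`` (values in [0, 1], value 1 at x = 0) or
    ``"nonpositive"`` (values <= 0, value 0 at x = 0; the additive analogue of
    a suppressive unit).
    """

    basis: TentBasis
    weights: np.ndarray
    constraint: str | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.weights) != self.basis.n_funcs:
            raise ValueError("one weight per knot required")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.basis.interp(x, self.weights)

    def deriv(self, x: np.ndarray) -> np.ndarray:
        return self.basis.deriv(x, self.weights)

    def check_constraint(self, atol: float = 1e-9) -> bool:
        w = self.weights
        if self.constraint == MONOTONE:
            return bool(np.all(np.diff(w) >= -atol))
        if self.constraint == SUPPRESSIVE:
            at0 = self.basis.interp(np.array([0.0]), w)[0]
            return bool(w.min() >= -atol and w.max() <= 1 + atol and abs(at0 - 1) <= atol)
        if self.constraint == NONPOSITIVE:
            at0 = self.basis.interp(np.array([0.0]), w)[0]
            return bool(w.max() <= atol and abs(at0) <= atol)
        return True


def symmetric_knots(g: np.ndarray, n_knots: int) -> TentBasis:
    """Tent basis on a symmetric grid covering |mean| + 3 SD of the generator.

    A symmetric grid always contains x = 0 (odd knot count), which anchors the
    suppressive-unit and nonpositive constraints exactly at a knot, and makes
    sign-flips of the paired filter equivalent to reversing the weights.
    """
    g = np.asarray(g, dtype=float)
    m = abs(float(g.mean())) + 3.0 * float(g.std())
    if m <= 0:
        raise ValueError("degenerate generator signal (zero variance)")
    if n_knots % 2 == 0:
        n_knots += 1
    knots = np.linspace(-m, m, n_knots)
    knots[n_knots // 2] = 0.0  # exact zero anchor for the fs(0) constraints
    return tent_basis(knots)


@dataclass
class LNParams:
    """LN cascade: c(t) = f[k . s(t)] + c0."""

    filter: TemporalFilter
    nonlinearity: Nonlinearity1D
    offset: float = 0.0
    kind: str = field(default="ln", init=False)

    def predict(self, stim: Stimulus) -> np.ndarray:
        return self.nonlinearity(self.filter.apply(stim)) + self.offset


@dataclass
class DivSParams:
    """Divisive suppression: c(t) = fe[ke . s] * fs[ks . s] + c0.

    ``fs`` is bounded in [0, 1] with fs(0) = 1, so suppression can only scale
    the excitatory drive down and is inactive at zero suppressive input.
    """

    exc_filter: TemporalFilter
    exc_nl: Nonlinearity1D
    sup_filter: TemporalFilter
    sup_nl: Nonlinearity1D
    offset: float = 0.0
    kind: str = field(default="divs", init=False)

    def predict(self, stim: Stimulus) -> np.ndarray:
        ge = self.exc_filter.apply(stim)
        gs = self.sup_filter.apply(stim)
        return self.exc_nl(ge) * self.sup_nl(gs) + self.offset

    def delay_ms(self, channel: int = 0) -> float:
        """Suppressive minus excitatory kernel peak latency (ms)."""
        return self.sup_filter.peak_lag_ms(channel) - self.exc_filter.peak_lag_ms(channel)


@dataclass
class AddSParams:
    """Additive suppression: c(t) = fe[ke . s] + fs[ks . s] + c0 with fs <= 0."""

    exc_filter: TemporalFilter
    exc_nl: Nonlinearity1D
    sup_filter: TemporalFilter
    sup_nl: Nonlinearity1D
    offset: float = 0.0
    kind: str = field(default="adds", init=False)

    def predict(self, stim: Stimulus) -> np.ndarray:
        ge = self.exc_filter.apply(stim)
        gs = self.sup_filter.apply(stim)
        return self.exc_nl(ge) + self.sup_nl(gs) + self.offset


@dataclass
class Surface2DParams:
    """2-D nonlinearity model: c(t) = F[ke . s, ks . s] on a pyramid basis.

    F is constrained monotonically non-decreasing along the first (excitatory)
    axis, which pins down the otherwise-degenerate mixing of the two filters.
    """

    exc_filter: TemporalFilter
    sup_filter: TemporalFilter
    surface_basis: object  # PyramidBasis2D
    weights: np.ndarray
    kind: str = field(default="2d", init=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).reshape(
            self.surface_basis.shape
        )

    def predict(self, stim: Stimulus) -> np.ndarray:
        ge = self.exc_filter.apply(stim)
        gs = self.sup_filter.apply(stim)
        return self.surface_basis.interp(ge, gs, self.weights)

    def check_monotone(self, atol: float = 1e-8) -> bool:
        return bool(np.all(np.diff(self.weights, axis=0) >= -atol))
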