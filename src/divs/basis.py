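"""Function bases for temporal filters and nonparametric nonlinearities.

Three bases parameterize everything in the package:

* :class:`TemporalBasis` — orthonormalized sinusoids
  ``zeta_n(t) = sin[pi * n * (2 t/tF - (t/tF)^2)]`` on ``[0, tF]``; these vanish
  at both ends and concentrate resolution at short latencies, which suits
  retinal temporal receptive fields.
* :class:`TentBasis` — piecewise-linear "hat" functions on a knot grid; a weight
  vector on the hats is exactly a piecewise-linear function interpolating the
  weights at the knots.
* :class:`PyramidBasis2D` — piecewise-planar pyramids on a rectangular grid with
  each square split into two triangles; the 2-D analogue of the tent basis.

All three are exact interpolators at their knots/vertices and are evaluated with
constant (clamped) extrapolation outside their range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "TemporalBasis",
    "TentBasis",
    "PyramidBasis2D",
    "temporal_basis",
    "tent_basis",
    "pyramid_basis_2d",
]


@dataclass(frozen=True)
class TemporalBasis:
    """Orthonormalized half-sine family on ``[0, t_max]`` sampled at ``dt``.

    Attributes
    ----------
    n_funcs : int
        Number of basis functions.
    t_max : float
        Filter duration in ms (``tF``).
    dt : float
        Bin width in ms.
    matrix : ndarray, shape (n_bins, n_funcs)
        One orthonormal function per column; ``n_bins = round(t_max / dt)``.
        The columns span the same space as the raw sinusoids and satisfy
        ``matrix.T @ matrix == I``.
    """

    n_funcs: int
    t_max: float
    dt: float
    matrix: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.dt

    def expand(self, coeffs: np.ndarray) -> np.ndarray:
        """Expand coefficients into a discrete kernel (n_bins[, ...])."""
        return self.matrix @ np.asarray(coeffs)

    def project(self, kernel: np.ndarray) -> np.ndarray:
        """Least-squares coefficients for a sampled kernel (orthonormal: B^T k)."""
        return self.matrix.T @ np.asarray(kernel)


def raw_temporal_functions(n_funcs: int, t_max: float, dt: float) -> np.ndarray:
    """Un-orthonormalized ``sin[pi n (2t/tF - (t/tF)^2)]``, one per column."""
    t = np.arange(int(round(t_max / dt))) * dt
    x = 2.0 * t / t_max - (t / t_max) ** 2
    n = np.arange(1, n_funcs + 1)
    return np.sin(np.pi * n[None, :] * x[:, None])


def temporal_basis(n_funcs: int, t_max: float = 200.0, dt: float = 1.0) -> TemporalBasis:
    """Build the orthonormalized temporal basis.

    Orthonormalization is ordered Gram–Schmidt over ``n = 1..n_funcs`` at the
    working ``dt`` (realized as a thin QR with positive diagonal, which is the
    same map and deterministic).

    Raises
    ------
    ValueError
        If any argument is non-positive or ``dt`` does not divide ``t_max`` to
        within one bin.
    """
    if n_funcs < 1:
        raise ValueError(f"n_funcs must be >= 1, got {n_funcs}")
    if t_max <= 0 or dt <= 0:
        raise ValueError("t_max and dt must be positive")
    n_bins = int(round(t_max / dt))
    if abs(n_bins * dt - t_max) > dt:
        raise ValueError(f"dt={dt} does not divide t_max={t_max} to within one bin")
    if n_funcs > n_bins:
        raise ValueError("n_funcs exceeds the number of time bins")
    raw = raw_temporal_functions(n_funcs, t_max, dt)
    q, r = np.linalg.qr(raw)
    # fix signs so the map equals classical Gram-Schmidt (positive diagonal of R)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return TemporalBasis(n_funcs=n_funcs, t_max=float(t_max), dt=float(dt), matrix=q)


@dataclass(frozen=True)
class TentBasis:
    """Piecewise-linear hat functions on an ordered knot grid.

    Evaluation outside ``[knots[0], knots[-1]]`` clamps to the boundary knot
    (constant extrapolation), so a weight vector defines a bounded piecewise
    linear function on the whole real line.
    """

    knots: np.ndarray

    @property
    def n_funcs(self) -> int:
        return len(self.knots)

    def _clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.knots[0], self.knots[-1])

    def design(self, x: np.ndarray) -> np.ndarray:
        """Dense evaluation matrix of shape ``(len(x), n_knots)``.

        Rows sum to one (partition of unity); at a knot the row is an
        indicator for that knot.
        """
        x = self._clamp(np.atleast_1d(np.asarray(x, dtype=float)))
        k = self.knots
        idx = np.clip(np.searchsorted(k, x, side="right") - 1, 0, len(k) - 2)
        u = (x - k[idx]) / (k[idx + 1] - k[idx])
        out = np.zeros((len(x), len(k)))
        rows = np.arange(len(x))
        out[rows, idx] = 1.0 - u
        out[rows, idx + 1] += u
        return out

    def interp(self, x: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Evaluate the piecewise-linear function with values `weights` at knots."""
        x = self._clamp(np.asarray(x, dtype=float))
        return np.interp(x, self.knots, np.asarray(weights, dtype=float))

    def deriv(self, x: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Slope of the interpolant at ``x`` (0 outside the knot range)."""
        x = np.asarray(x, dtype=float)
        k = self.knots
        w = np.asarray(weights, dtype=float)
        slopes = np.diff(w) / np.diff(k)
        idx = np.clip(np.searchsorted(k, x, side="right") - 1, 0, len(k) - 2)
        out = slopes[idx]
        out = np.where((x < k[0]) | (x > k[-1]), 0.0, out)
        return out


def tent_basis(knots: np.ndarray) -> TentBasis:
    """Build a tent basis; knots must be strictly increasing with >= 3 knots."""
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need a 1-D grid of at least 3 knots")
    if not np.all(np.diff(knots) > 0):
        raise ValueError("knots must be strictly increasing")
    return TentBasis(knots=knots)


@dataclass(frozen=True)
class PyramidBasis2D:
    """Piecewise-planar pyramid functions on a rectangular grid.

    Each grid square is split into two triangles by the diagonal from
    ``(i+1, j)`` to ``(i, j+1)``; every vertex carries a "hexagonal pyramid"
    basis function that is 1 at the vertex, 0 at all other vertices, and planar
    on each triangle. Any plane ``a x + b y + c`` is reproduced exactly by the
    weights ``a x_i + b y_j + c``.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.grid_x), len(self.grid_y)

    @property
    def n_funcs(self) -> int:
        return len(self.grid_x) * len(self.grid_y)

    def vertex_index(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return i * len(self.grid_y) + j

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """True where (x, y) falls inside the grid rectangle."""
        gx, gy = self.grid_x, self.grid_y
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= gx[0]) & (x <= gx[-1]) & (y >= gy[0]) & (y <= gy[-1])

    def _triangle(self, x, y):
        gx, gy = self.grid_x, self.grid_y
        x = np.clip(np.atleast_1d(np.asarray(x, dtype=float)), gx[0], gx[-1])
        y = np.clip(np.atleast_1d(np.asarray(y, dtype=float)), gy[0], gy[-1])
        i = np.clip(np.searchsorted(gx, x, side="right") - 1, 0, len(gx) - 2)
        j = np.clip(np.searchsorted(gy, y, side="right") - 1, 0, len(gy) - 2)
        u = (x - gx[i]) / (gx[i + 1] - gx[i])
        v = (y - gy[j]) / (gy[j + 1] - gy[j])
        return i, j, u, v

    def design(self, x: np.ndarray, y: np.ndarray) -> sparse.csr_matrix:
        """Sparse evaluation matrix (n_points, n_vertices); <= 3 nonzero per row.

        Points outside the grid are clamped; use :meth:`contains` to flag them.
        """
        i, j, u, v = self._triangle(x, y)
        n = len(i)
        lower = u + v <= 1.0
        cols = np.empty((n, 3), dtype=np.int64)
        vals = np.empty((n, 3))
        # lower triangle: vertices (i,j), (i+1,j), (i,j+1); barycentric (1-u-v, u, v)
        cols[lower, 0] = self.vertex_index(i[lower], j[lower])
        cols[lower, 1] = self.vertex_index(i[lower] + 1, j[lower])
        cols[lower, 2] = self.vertex_index(i[lower], j[lower] + 1)
        vals[lower, 0] = 1.0 - u[lower] - v[lower]
        vals[lower, 1] = u[lower]
        vals[lower, 2] = v[lower]
        up = ~lower
        # upper triangle: vertices (i+1,j+1), (i,j+1), (i+1,j); barycentric (u+v-1, 1-u, 1-v)
        cols[up, 0] = self.vertex_index(i[up] + 1, j[up] + 1)
        cols[up, 1] = self.vertex_index(i[up], j[up] + 1)
        cols[up, 2] = self.vertex_index(i[up] + 1, j[up])
        vals[up, 0] = u[up] + v[up] - 1.0
        vals[up, 1] = 1.0 - u[up]
        vals[up, 2] = 1.0 - v[up]
        rows = np.repeat(np.arange(n), 3)
        return sparse.csr_matrix(
            (vals.ravel(), (rows, cols.ravel())), shape=(n, self.n_funcs)
        )

    def interp(self, x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> np.ndarray:
        w = np.asarray(weights, dtype=float).reshape(-1)
        return np.asarray(self.design(x, y) @ w)

    def gradient(
        self, x: np.ndarray, y: np.ndarray, weights: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(dF/dx, dF/dy) of the interpolant; constant within each triangle."""
        w = np.asarray(weights, dtype=float).reshape(self.shape)
        gx, gy = self.grid_x, self.grid_y
        i, j, u, v = self._triangle(x, y)
        dx = gx[i + 1] - gx[i]
        dy = gy[j + 1] - gy[j]
        lower = u + v <= 1.0
        fx = np.where(
            lower,
            (w[i + 1, j] - w[i, j]) / dx,
            (w[i + 1, j + 1] - w[i, j + 1]) / dx,
        )
        fy = np.where(
            lower,
            (w[i, j + 1] - w[i, j]) / dy,
            (w[i + 1, j + 1] - w[i + 1, j]) / dy,
        )
        return fx, fy


def pyramid_basis_2d(grid_x: np.ndarray, grid_y: np.ndarray) -> PyramidBasis2D:
    """Build the 2-D pyramid basis; both grids strictly increasing, >= 3 points."""
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    for name, g in (("grid_x", grid_x), ("grid_y", grid_y)):
        if g.ndim != 1 or len(g) < 3:
            raise ValueError(f"{name} must be a 1-D grid with at least 3 points")
        if not np.all(np.diff(g) > 0):
            raise ValueError(f"{name} must be strictly increasing")
    return PyramidBasis2D(grid_x=grid_x, grid_y=grid_y)


def history_basis(
    n_funcs: int = 8, t_max: float = 100.0, dt: float = 1.0, t_min: float = 1.0
) -> np.ndarray:
    """Log-spaced raised-cosine bumps for spike-history filters.

    Returns a matrix of shape ``(n_lags, n_funcs)`` covering lags
    ``[t_min, t_max]`` ms; lag 0 is excluded by construction (the first row
    corresponds to a 1-bin lag), so a history filter never sees the current
    bin's own spike. Bumps are raised cosines in log time, giving fine
    resolution at 1–2 ms (absolute refractoriness) and coarse resolution out
    to ~100 ms (relative refractoriness).
    """
    if n_funcs < 1 or t_max <= t_min:
        raise ValueError("need n_funcs >= 1 and t_max > t_min")
    lags = np.arange(dt, t_max + 0.5 * dt, dt)
    log_t = np.log(lags + 0.5)
    centers = np.linspace(np.log(t_min + 0.5), np.log(t_max + 0.5), n_funcs)
    width = (centers[-1] - centers[0]) / max(n_funcs - 1, 1) * 1.5
    arg = np.clip((log_t[:, None] - centers[None, :]) / width, -1.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * arg))
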