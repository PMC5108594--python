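"""Small shared solvers for the block-coordinate fits.

Every nonlinearity/surface block update is a linear least-squares problem in
the tent or pyramid weights, possibly under bound constraints after a change
of variables (monotone functions are parameterized by nonnegative increments
between knots). Each problem is first reduced to its normal equations, so the
bounded solve runs on an (n_params x n_params) system regardless of the
number of time samples.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import lsq_linear

_JITTER = 1e-9


def reduce_normal(A, y):
    """Return (R, z) with ||A w - y||^2 = ||R w - z||^2 + const.

    Works for dense or sparse A; a small ridge keeps the reduction defined for
    rank-deficient designs (e.g. unvisited knots).
    """
    G = A.T @ A
    if sparse.issparse(G):
        G = G.toarray()
    G = np.asarray(G)
    b = np.asarray(A.T @ y).ravel()
    scale = max(np.trace(G) / len(b), 1.0)
    R = cholesky(G + _JITTER * scale * np.eye(len(b)), lower=False)
    z = np.linalg.solve(R.T, b)
    return R, z


def solve_lsq(A, y):
    """Unconstrained least squares via the reduced normal equations."""
    G = A.T @ A
    if sparse.issparse(G):
        G = G.toarray()
    G = np.asarray(G)
    b = np.asarray(A.T @ y).ravel()
    scale = max(np.trace(G) / len(b), 1.0)
    c, low = cho_factor(G + _JITTER * scale * np.eye(len(b)))
    return cho_solve((c, low), b)


def solve_bounded(A, y, lb, ub):
    """Bound-constrained least squares on the reduced system."""
    R, z = reduce_normal(A, y)
    res = lsq_linear(R, z, bounds=(lb, ub), method="bvls" if R.shape[0] <= 400 else "trf")
    return res.x


def monotone_map(n: int, anchor_first_zero: bool = True) -> np.ndarray:
    """Linear map from increment parameters to monotone knot weights.

    With ``anchor_first_zero`` the first weight is pinned to 0 and the map is
    the (n, n-1) cumulative-sum matrix over nonnegative increments; otherwise
    the first parameter is the free base level.
    """
    C = np.tril(np.ones((n, n)))
    if anchor_first_zero:
        return C[:, 1:]
    return C


def solve_monotone(A, y, anchor_first_zero: bool = True):
    """Monotone-nondecreasing weights minimizing ||A w - y||^2.

    Returns the weight vector; increments are constrained nonnegative, the
    base level is free unless anchored at zero.
    """
    n = A.shape[1]
    C = monotone_map(n, anchor_first_zero)
    lb = np.zeros(C.shape[1])
    ub = np.full(C.shape[1], np.inf)
    if not anchor_first_zero:
        lb[0] = -np.inf
    d = solve_bounded(A @ C, y, lb, ub)
    return C @ d
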