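"""Response-weighted covariance analysis of currents and spike trains.

The spike-triggered average / covariance machinery, applied with arbitrary
nonnegative-mean weights so that one code path serves both spike counts
(classical STA/STC) and continuous synaptic currents (response-weighted
cross-correlation and covariance). The "covariance-difference" matrix is the
response-weighted second moment minus the prior (unweighted) stimulus
covariance; its leading eigenvectors span the stimulus subspace that drives
the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import Stimulus

__all__ = [
    "CovarianceResult",
    "response_weighted_moments",
    "subspace_projection",
    "bandlimited",
]

_CHUNK = 20_000


@dataclass
class CovarianceResult:
    """Weighted first/second stimulus moments and their eigendecomposition.

    ``mean_kernel`` is the response-weighted cross-correlation
    ``(1/T) sum_t w(t) s(t - tau)`` on the mean-centered stimulus;
    ``covdiff`` is the weighted covariance minus ``mean(w)`` times the prior
    stimulus covariance, so an unmodulated response gives a zero matrix.
    Eigen-pairs are sorted by eigenvalue magnitude, eigenvectors are unit-norm
    columns with the largest-magnitude element made positive.
    """

    lags_ms: np.ndarray
    mean_kernel: np.ndarray
    covdiff: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)
    weight_mean: float = 0.0

    def top_filters(self, n: int = 2) -> list[np.ndarray]:
        return [self.eigenvectors[:, i] for i in range(n)]

    def significant_eigenvalues(
        self, stim, response, n_surrogates: int = 100, q: float = 0.01, seed: int = 0
    ) -> np.ndarray:
        """Boolean mask of eigenvalues outside the shuffled-response band.

        Surrogates permute the response against the stimulus; an eigenvalue is
        significant if it falls outside the [q, 1-q] percentile band of the
        pooled surrogate spectra.
        """
        rng = np.random.default_rng(seed)
        response = np.asarray(response, dtype=float).ravel()
        pool = []
        for _ in range(n_surrogates):
            shuffled = rng.permutation(response)
            res = response_weighted_moments(stim, shuffled, n_lags=len(self.lags_ms))
            pool.append(res.eigenvalues)
        pool = np.concatenate(pool)
        lo, hi = np.quantile(pool, [q, 1.0 - q])
        return (self.eigenvalues < lo) | (self.eigenvalues > hi)


def bandlimited(kernel: np.ndarray, dt: float = 1.0, cutoff_hz: float = 30.0) -> np.ndarray:
    """Project a kernel onto the sub-cutoff frequency band of its window.

    A stimulus with no power above ``cutoff_hz`` cannot constrain kernel
    structure outside that band, so subspace comparisons between filters
    estimated from such stimuli are meaningful only after this projection.
    """
    k = np.asarray(kernel, dtype=float).ravel()
    spec = np.fft.rfft(k)
    freqs = np.fft.rfftfreq(len(k), d=dt / 1000.0)
    spec[freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=len(k))


def response_weighted_moments(
    stim: Stimulus | np.ndarray,
    response: np.ndarray,
    n_lags: int = 200,
    channel: int = 0,
    mask: np.ndarray | None = None,
) -> CovarianceResult:
    """Response-weighted stimulus moments with the prior covariance subtracted.

    Parameters
    ----------
    stim : Stimulus or 1-D array
        Stimulus time series (one channel is used); it is mean-centered
        internally.
    response : array
        Weights per time bin — binned spike counts or a synaptic current
        trace. Must not be identically zero-sum (weights could not be
        interpreted); a constant response yields a zero covdiff.
    n_lags : int
        Number of stimulus lags (default 200 bins at the stimulus dt).
    mask : bool array, optional
        Restrict the analysis to these time bins (e.g. the unique stimulus
        segments — the frozen repeat waveform, reused every cycle, otherwise
        biases the second moments and never averages out).
    """
    if isinstance(stim, Stimulus):
        s = stim.values[:, channel].astype(float)
        dt = stim.dt
    else:
        s = np.asarray(stim, dtype=float).ravel()
        dt = 1.0
    w = np.asarray(response, dtype=float).ravel()
    if len(w) != len(s):
        raise ValueError("response and stimulus must have equal length")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        s = s[mask]
        w = w[mask]
    if np.ptp(w) == 0 and w[0] == 0:
        raise ValueError("degenerate weighting: response is identically zero")
    s = s - s.mean()
    T = len(s)
    w_mean = float(w.mean())
    mean_kernel = np.zeros(n_lags)
    W2 = np.zeros((n_lags, n_lags))
    C0 = np.zeros((n_lags, n_lags))
    for start in range(0, T, _CHUNK):
        stop = min(start + _CHUNK, T)
        # build the lag block from padded history so chunking is exact
        lo = max(start - (n_lags - 1), 0)
        seg = s[lo:stop]
        if lo == 0:
            seg = np.concatenate([np.zeros(n_lags - 1 - start + lo), seg])
        S = np.lib.stride_tricks.sliding_window_view(seg, n_lags)[:, ::-1]
        wc = w[start:stop]
        mean_kernel += wc @ S
        W2 += (S * wc[:, None]).T @ S
        C0 += S.T @ S
    mean_kernel /= T
    W2 /= T
    C0 /= T
    covdiff = W2 - w_mean * C0
    covdiff = 0.5 * (covdiff + covdiff.T)
    evals, evecs = np.linalg.eigh(covdiff)
    order = np.argsort(-np.abs(evals))
    evals = evals[order]
    evecs = evecs[:, order]
    # canonical sign: largest-magnitude element positive
    for i in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, i]))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    return CovarianceResult(
        lags_ms=np.arange(n_lags) * dt,
        mean_kernel=mean_kernel,
        covdiff=covdiff,
        eigenvalues=evals,
        eigenvectors=evecs,
        weight_mean=w_mean,
    )


def subspace_projection(filters, basis_filters) -> np.ndarray:
    """Norm of each unit-normalized filter's projection onto span(basis_filters).

    Returns one value in [0, 1] per filter; 1 means the filter lies entirely
    inside the span, 0 means it is orthogonal to it.
    """
    B = np.column_stack([np.asarray(b, dtype=float).ravel() for b in basis_filters])
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("basis filters are linearly dependent")
    Q, _ = np.linalg.qr(B)
    out = []
    for f in filters:
        f = np.asarray(f, dtype=float).ravel()
        f = f / np.linalg.norm(f)
        out.append(float(np.linalg.norm(Q.T @ f)))
    return np.array(out)
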