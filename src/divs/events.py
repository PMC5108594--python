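"""Spike-event analysis: segmentation into firing events and precision stats.

Events are episodes of firing separated by silence. They are found on the
across-trial PSTH at 1-ms resolution: any run of >= 8 ms with zero spikes
(summed over trials) separates events. Each candidate event is then tested
for multimodality with a two-component Gaussian mixture on the pooled spike
times and split (recursively, up to depth 3) when the component means differ
by more than twice the sum of their standard deviations. Final event windows
are bounded by midpoints between neighboring event centers. Events in which
fewer than half the trials spike are flagged as excluded (spontaneous
activity). Per event the analysis reports the first-spike jitter (SD of each
trial's first spike), the event time scale (SD of all spike times) and the
Fano factor of the per-trial spike counts.

At low contrast, events are scored inside the windows obtained from the
high-contrast data (the stimulus repeat is shared up to contrast scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .containers import SpikeTrainSet

__all__ = ["EventTable", "event_analysis"]


@dataclass
class EventTable:
    """Per-event windows and precision/reliability statistics.

    ``table`` columns: event id, window start/end (ms), center, n_trials_with
    spikes, first_spike_sd, all_spike_sd, fano, excluded, reason.
    """

    windows: list
    table: pd.DataFrame = field(repr=False)

    @property
    def n_events(self) -> int:
        return int((~self.table["excluded"]).sum())

    def included(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]


def _silence_spans(psth_counts: np.ndarray, dt: float, min_silence_ms: float):
    """Contiguous nonzero spans of the PSTH separated by >= min_silence_ms zeros."""
    nz = psth_counts > 0
    if not nz.any():
        return []
    idx = np.flatnonzero(nz)
    min_gap = int(round(min_silence_ms / dt))
    spans = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev > min_gap:
            spans.append((start, prev + 1))
            start = i
        prev = i
    spans.append((start, prev + 1))
    return [(s * dt, e * dt) for s, e in spans]


def _split_event(times: np.ndarray, depth: int = 0, max_depth: int = 3):
    """Recursive mixture-based splitting; returns a list of time arrays."""
    if depth >= max_depth or len(times) < 4 or np.ptp(times) < 1e-9:
        return [times]
    X = times.reshape(-1, 1)
    q25, q75 = np.quantile(times, [0.25, 0.75])
    if q75 - q25 < 1e-9:
        return [times]
    gm = GaussianMixture(
        n_components=2,
        means_init=[[q25], [q75]],
        weights_init=[0.5, 0.5],
        precisions_init=[[[1.0 / max(times.var(), 1e-6)]]] * 2,
        max_iter=200,
        reg_covar=1e-3,
        random_state=0,
    )
    try:
        gm.fit(X)
    except ValueError:
        return [times]
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    if abs(mu[0] - mu[1]) <= 2.0 * (sd[0] + sd[1]):
        return [times]
    cut = 0.5 * (mu.min() + mu.max())
    left = times[times < cut]
    right = times[times >= cut]
    if len(left) == 0 or len(right) == 0:
        return [times]
    return _split_event(left, depth + 1, max_depth) + _split_event(right, depth + 1, max_depth)


def _event_windows(spikes: SpikeTrainSet, min_silence_ms: float, max_depth: int):
    psth = spikes.binned().sum(axis=0)
    spans = _silence_spans(psth, spikes.dt, min_silence_ms)
    pooled = np.concatenate(spikes.trials) if spikes.total_spikes() else np.array([])
    centers = []
    for s, e in spans:
        in_span = pooled[(pooled >= s) & (pooled < e + spikes.dt)]
        if len(in_span) == 0:
            continue
        for part in _split_event(np.sort(in_span), max_depth=max_depth):
            centers.append(float(np.mean(part)))
    centers = sorted(centers)
    if not centers:
        return []
    # boundaries at midpoints between neighboring centers; outermost at the
    # start/end of the silence-delimited spans
    bounds = [spans[0][0]]
    for c0, c1 in zip(centers[:-1], centers[1:]):
        bounds.append(0.5 * (c0 + c1))
    bounds.append(spans[-1][1])
    return [(bounds[i], bounds[i + 1], centers[i]) for i in range(len(centers))]


def _score_events(spikes: SpikeTrainSet, windows, min_trial_frac: float) -> pd.DataFrame:
    rows = []
    n_trials = spikes.n_trials
    for ev_id, (w0, w1, center) in enumerate(windows):
        per_trial = [t[(t >= w0) & (t < w1)] for t in spikes.trials]
        counts = np.array([len(t) for t in per_trial])
        firsts = np.array([t[0] for t in per_trial if len(t)])
        with_spike = int((counts > 0).sum())
        all_times = np.concatenate([t for t in per_trial if len(t)]) if with_spike else np.array([])
        excluded = with_spike <= min_trial_frac * n_trials
        reason = "spikes on <= 50% of trials" if excluded else ""
        rows.append(
            {
                "event": ev_id,
                "start_ms": w0,
                "end_ms": w1,
                "center_ms": center,
                "n_trials_with_spikes": with_spike,
                "first_spike_sd": float(np.std(firsts)) if len(firsts) > 1 else (0.0 if len(firsts) else np.nan),
                "all_spike_sd": float(np.std(all_times)) if len(all_times) > 1 else (0.0 if len(all_times) else np.nan),
                "fano": float(counts.var(ddof=1) / counts.mean()) if counts.mean() > 0 and n_trials > 1 else np.nan,
                "excluded": bool(excluded),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def event_analysis(
    spikes: SpikeTrainSet,
    spikes_lc: SpikeTrainSet | None = None,
    min_silence_ms: float = 8.0,
    min_trial_frac: float = 0.5,
    max_split_depth: int = 3,
) -> dict:
    """Segment spike trains into events and compute precision statistics.

    Parameters
    ----------
    spikes : SpikeTrainSet
        High-contrast repeat trials; event boundaries are derived here.
    spikes_lc : SpikeTrainSet, optional
        Low-contrast repeat trials, scored inside the HC event windows.

    Returns
    -------
    dict mapping contrast label ("HC", and "LC" when given) to
    :class:`EventTable`. With no spikes at all, the tables are empty.
    """
    windows = _event_windows(spikes, min_silence_ms, max_split_depth)
    hc_table = _score_events(spikes, windows, min_trial_frac)
    out = {"HC": EventTable(windows, hc_table)}
    if spikes_lc is not None:
        lc_table = _score_events(spikes_lc, windows, min_trial_frac)
        # event definition *and* inclusion come from the high-contrast data;
        # a low-contrast event is only dropped when it was dropped at HC or
        # carries no spikes at all
        lc_excluded = hc_table["excluded"].to_numpy() | (
            lc_table["n_trials_with_spikes"].to_numpy() == 0
        )
        lc_table = lc_table.assign(
            excluded=lc_excluded,
            reason=np.where(
                hc_table["excluded"], "excluded at HC",
                np.where(lc_table["n_trials_with_spikes"] == 0, "no LC spikes", ""),
            ),
        )
        out["LC"] = EventTable(windows, lc_table)
    return out
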