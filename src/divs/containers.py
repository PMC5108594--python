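"""Trial-structured response containers.

Recordings are continuous: one current trace and/or one spike train spans the
whole stimulus. Trials arise from the protocol's repeat windows — the slices
of the response aligned to the repeated stimulus segment of each cycle form a
:class:`TrialSet` (currents) or :class:`SpikeTrainSet` (spikes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import Stimulus

__all__ = ["TrialSet", "SpikeTrainSet", "Recording"]


@dataclass
class TrialSet:
    """Aligned per-trial continuous traces (n_trials, n_bins) at bin width dt (ms)."""

    trials: np.ndarray
    dt: float = 1.0
    label: str | None = None

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_bins(self) -> int:
        return self.trials.shape[1]

    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)


@dataclass
class SpikeTrainSet:
    """Per-trial spike-time lists (ms, relative to trial start).

    Spike times live in ``[0, duration)`` and are strictly increasing within a
    trial; ``dt`` is the analysis bin width (1 ms throughout the package).
    """

    trials: list
    duration: float
    dt: float = 1.0
    label: str | None = None

    def __post_init__(self):
        clean = []
        for t in self.trials:
            t = np.asarray(t, dtype=float).ravel()
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError("spike times must be increasing within a trial")
            clean.append(t)
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))

    def binned(self) -> np.ndarray:
        """Per-trial spike counts, shape (n_trials, n_bins)."""
        edges = np.arange(self.n_bins + 1) * self.dt
        return np.stack([np.histogram(t, bins=edges)[0] for t in self.trials])

    def psth(self) -> np.ndarray:
        """Across-trial mean rate in spikes per bin."""
        return self.binned().mean(axis=0)

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.trials))


@dataclass
class Recording:
    """A stimulus paired with continuous responses and provenance metadata."""

    stimulus: Stimulus
    current: np.ndarray | None = None
    spike_times: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.current is not None:
            self.current = np.asarray(self.current, dtype=float).ravel()
            if len(self.current) != self.stimulus.n_bins:
                raise ValueError("current trace length must match the stimulus")
        if self.spike_times is not None:
            self.spike_times = np.asarray(self.spike_times, dtype=float).ravel()

    def current_repeat_trials(self, label: str | None = "HC") -> TrialSet:
        """Current slices aligned to the repeat windows of one contrast."""
        if self.current is None:
            raise ValueError("recording has no current trace")
        windows = self.stimulus.repeat_windows_for(label)
        if not windows:
            raise ValueError(f"no repeat windows for label {label!r}")
        rows = [self.current[self.stimulus.window_slice(w)] for w in windows]
        return TrialSet(np.stack(rows), dt=self.stimulus.dt, label=label)

    def spike_repeat_trials(self, label: str | None = "HC") -> SpikeTrainSet:
        """Spike-time slices aligned to the repeat windows of one contrast."""
        if self.spike_times is None:
            raise ValueError("recording has no spike train")
        windows = self.stimulus.repeat_windows_for(label)
        if not windows:
            raise ValueError(f"no repeat windows for label {label!r}")
        dur = windows[0][1] - windows[0][0]
        trials = []
        for start, end in windows:
            sel = (self.spike_times >= start) & (self.spike_times < end)
            trials.append(self.spike_times[sel] - start)
        return SpikeTrainSet(trials, duration=dur, dt=self.stimulus.dt, label=label)

    def binned_spikes(self) -> np.ndarray:
        """Continuous spike counts at the stimulus resolution."""
        if self.spike_times is None:
            raise ValueError("recording has no spike train")
        edges = np.arange(self.stimulus.n_bins + 1) * self.stimulus.dt
        return np.histogram(self.spike_times, bins=edges)[0].astype(float)
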