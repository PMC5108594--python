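"""Stimulus protocols: contrast-switching noise spot and spot/annulus noise.

The canonical protocol is a full-field flickering spot whose intensity is
Gaussian noise low-pass filtered at 30 Hz, with temporal contrast (SD/mean)
alternating between 0.3 (high contrast, HC) and 0.1 (low contrast, LC) every
10 s. Each 10-s cycle consists of 7 s of unique noise (used for fitting) and a
3-s segment repeated across cycles of the same contrast (used for
cross-validation). The two-channel variant modulates a center spot and a
surround annulus with independent sample-and-hold Gaussian noise at a 60-Hz
update rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stimulus",
    "contrast_switching_stimulus",
    "single_contrast_stimulus",
    "spot_annulus_stimulus",
]


@dataclass
class Stimulus:
    """A sampled stimulus with contrast schedule and repeat-window bookkeeping.

    Attributes
    ----------
    values : ndarray, shape (n_bins, n_channels)
        Channel 0 is the spot/center; channel 1 (when present) the annulus.
    dt : float
        Bin width, ms.
    mean_level : float
        Mean luminance in normalized units.
    schedule : list of (start_ms, end_ms, label)
        Contrast blocks, tiling the duration without overlap; label is
        ``"HC"`` or ``"LC"``.
    repeat_windows : list of (start_ms, end_ms)
        The repeated segment of each cycle. Within one contrast label the
        stimulus values in these windows are identical.
    """

    values: np.ndarray
    dt: float
    mean_level: float = 1.0
    schedule: list = field(default_factory=list)
    repeat_windows: list = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_bins * self.dt

    def index(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt))

    def window_slice(self, window) -> slice:
        start, end = window[0], window[1]
        return slice(self.index(start), self.index(end))

    def label_of(self, t_ms: float) -> str:
        for start, end, label in self.schedule:
            if start <= t_ms < end:
                return label
        raise ValueError(f"time {t_ms} ms not covered by the schedule")

    def repeat_windows_for(self, label: str | None = None) -> list:
        """Repeat windows, optionally restricted to one contrast label."""
        if label is None:
            return list(self.repeat_windows)
        return [w for w in self.repeat_windows if self.label_of(w[0]) == label]

    def mask(self, *, exclude_repeats: bool = False, label: str | None = None,
             burn_in_ms: float = 0.0) -> np.ndarray:
        """Boolean time mask selecting bins for fitting or evaluation."""
        m = np.ones(self.n_bins, dtype=bool)
        m[: self.index(burn_in_ms)] = False
        if exclude_repeats:
            for w in self.repeat_windows:
                m[self.window_slice(w)] = False
        if label is not None:
            keep = np.zeros(self.n_bins, dtype=bool)
            for start, end, lab in self.schedule:
                if lab == label:
                    keep[self.index(start): self.index(end)] = True
            m &= keep
        return m


def bandlimited_noise(n: int, dt_ms: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian noise with no power above ``cutoff_hz``.

    White Gaussian noise is masked in the Fourier domain (sharp spectral
    truncation) and rescaled, so the result is exactly band-limited.
    """
    fs = 1000.0 / dt_ms
    if cutoff_hz >= fs / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz violates Nyquist at dt={dt_ms} ms (fs/2={fs / 2} Hz)"
        )
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt_ms / 1000.0)
    spec[freqs > cutoff_hz] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate noise segment (zero variance)")
    return x / sd


def contrast_switching_stimulus(
    n_cycles: int = 10,
    cycle_s: float = 10.0,
    unique_s: float = 7.0,
    dt: float = 1.0,
    mean_level: float = 1.0,
    hc_frac: float = 0.3,
    lc_frac: float = 0.1,
    cutoff_hz: float = 30.0,
    seed: int = 0,
    first_label: str = "HC",
) -> Stimulus:
    """Contrast-switching low-pass noise spot (single channel).

    ``n_cycles`` cycles per contrast, alternating HC/LC blocks of ``cycle_s``
    seconds. Within each cycle the first ``unique_s`` seconds are fresh noise
    and the remainder is a repeat segment: the same normalized waveform is
    reused in every cycle (scaled by each contrast's SD), so repeats are
    bit-identical within a contrast and differ only in contrast across labels.
    """
    if not (0 < unique_s < cycle_s):
        raise ValueError("need 0 < unique_s < cycle_s")
    for name, frac in (("hc_frac", hc_frac), ("lc_frac", lc_frac)):
        if not 0 < frac < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_unique = int(round(unique_s * 1000.0 / dt))
    n_cycle = int(round(cycle_s * 1000.0 / dt))
    n_rep = n_cycle - n_unique
    repeat_wave = bandlimited_noise(n_rep, dt, cutoff_hz, rng)
    labels = ([first_label, "LC" if first_label == "HC" else "HC"]) * n_cycles
    frac_of = {"HC": hc_frac, "LC": lc_frac}
    chunks, schedule, repeat_windows = [], [], []
    t = 0.0
    for label in labels:
        sd = frac_of[label] * mean_level
        unique = bandlimited_noise(n_unique, dt, cutoff_hz, rng)
        block = mean_level + sd * np.concatenate([unique, repeat_wave])
        chunks.append(block)
        schedule.append((t, t + cycle_s * 1000.0, label))
        repeat_windows.append((t + unique_s * 1000.0, t + cycle_s * 1000.0))
        t += cycle_s * 1000.0
    return Stimulus(
        values=np.concatenate(chunks),
        dt=dt,
        mean_level=mean_level,
        schedule=schedule,
        repeat_windows=repeat_windows,
    )


def single_contrast_stimulus(
    n_cycles: int = 7,
    cycle_s: float = 10.0,
    unique_s: float = 7.0,
    dt: float = 1.0,
    mean_level: float = 1.0,
    frac: float = 0.3,
    cutoff_hz: float = 30.0,
    seed: int = 0,
    label: str = "HC",
) -> Stimulus:
    """Fixed-contrast version of the cycle protocol (all blocks one label)."""
    if not (0 < unique_s < cycle_s):
        raise ValueError("need 0 < unique_s < cycle_s")
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_unique = int(round(unique_s * 1000.0 / dt))
    n_cycle = int(round(cycle_s * 1000.0 / dt))
    n_rep = n_cycle - n_unique
    repeat_wave = bandlimited_noise(n_rep, dt, cutoff_hz, rng)
    sd = frac * mean_level
    chunks, schedule, repeat_windows = [], [], []
    t = 0.0
    for _ in range(n_cycles):
        unique = bandlimited_noise(n_unique, dt, cutoff_hz, rng)
        chunks.append(mean_level + sd * np.concatenate([unique, repeat_wave]))
        schedule.append((t, t + cycle_s * 1000.0, label))
        repeat_windows.append((t + unique_s * 1000.0, t + cycle_s * 1000.0))
        t += cycle_s * 1000.0
    return Stimulus(
        values=np.concatenate(chunks),
        dt=dt,
        mean_level=mean_level,
        schedule=schedule,
        repeat_windows=repeat_windows,
    )


def spot_annulus_stimulus(
    duration_s: float = 100.0,
    dt: float = 1.0,
    update_hz: float = 60.0,
    mean_level: float = 1.0,
    contrast_frac: float = 0.3,
    seed: int = 0,
) -> Stimulus:
    """Two-channel spot/annulus stimulus with independent 60-Hz Gaussian noise.

    Each channel is a frozen-frame (sample-and-hold) Gaussian sequence: a new
    value is drawn every ``1/update_hz`` seconds and held constant within the
    frame. Channels are statistically independent.
    """
    frame_ms = 1000.0 / update_hz
    frame_bins = int(round(frame_ms / dt))
    if frame_bins < 1:
        raise ValueError(f"dt={dt} ms too coarse for a {update_hz} Hz update rate")
    n_bins = int(round(duration_s * 1000.0 / dt))
    n_frames = int(np.ceil(n_bins / frame_bins))
    rng = np.random.default_rng(seed)
    frames = rng.standard_normal((n_frames, 2))
    values = mean_level * (1.0 + contrast_frac * np.repeat(frames, frame_bins, axis=0))
    return Stimulus(
        values=values[:n_bins],
        dt=dt,
        mean_level=mean_level,
        schedule=[(0.0, n_bins * dt, "HC")],
        repeat_windows=[],
    )
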