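"""SpikeTrain: the ordered series of spike times shared by simulator,
analysis, and fitter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered series of spike times over a finite recording.

    Parameters
    ----------
    times:
        Strictly increasing spike times in milliseconds, within
        ``[0, duration]``.
    duration:
        Recording length in milliseconds.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return self.n / (self.duration / 1000.0)

    @property
    def isis(self) -> np.ndarray:
        """Interspike intervals in ms (empty for < 2 spikes)."""
        return np.diff(self.times)

    def crop(self, t_start: float = 0.0, t_stop: float | None = None) -> "SpikeTrain":
        """Restrict to [t_start, t_stop] and shift the origin to t_start."""
        if t_stop is None:
            t_stop = self.duration
        if not 0 <= t_start < t_stop <= self.duration:
            raise ValueError("invalid crop window")
        sel = self.times[(self.times >= t_start) & (self.times <= t_stop)]
        return SpikeTrain(sel - t_start, t_stop - t_start)

    def shift(self, offset: float) -> "SpikeTrain":
        """Time-shift all spikes, extending the duration as needed."""
        if offset < 0 and self.times.size and self.times[0] + offset < 0:
            raise ValueError("shift would move spikes before time 0")
        return SpikeTrain(self.times + offset, self.duration + max(offset, 0.0))

    def binned_counts(self, binwidth_ms: float, n_bins: int | None = None) -> np.ndarray:
        """Spike counts in successive bins of ``binwidth_ms``, tiling from 0.

        A trailing partial bin is discarded unless ``n_bins`` forces the
        length.
        """
        if n_bins is None:
            n_bins = int(self.duration // binwidth_ms)
        edges = np.arange(n_bins + 1) * binwidth_ms
        counts, _ = np.histogram(self.times, bins=edges)
        return counts
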