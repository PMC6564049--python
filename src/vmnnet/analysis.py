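"""Spike-pattern statistics.

Three statistics jointly characterise spike patterning and form the fitting
target triple:

* the ISI histogram (5-ms bins, optionally normalised and scaled so bin
  counts total 10000, which makes records of different length comparable);
* the hazard function, the conditional firing probability per bin given
  survival to that bin:  h[t, t+5) = N(ISI in [t, t+5)) / N(ISI > t);
* the index of dispersion (IoD) of firing rate — variance/mean of spike
  counts in successive bins — evaluated over binwidths 0.5, 1, 2, 4, 6, 8
  and 10 s (the "IoD range").  Poisson spiking gives IoD = 1 at every
  timescale; regular spiking < 1; clustered spiking > 1 with strong
  timescale dependence.

Population-level tools (summed activity, simulated postsynaptic signal,
spike-triggered average, cross-correlogram, dominant oscillation frequency,
bistable-state segmentation) support the network experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .spiketrain import SpikeTrain

__all__ = [
    "ISIHistogram",
    "HazardFunction",
    "IoDRange",
    "PatternSummary",
    "IOD_BINWIDTHS_S",
    "isi_histogram",
    "isi_modes",
    "isi_mode_spacing",
    "pooled_isi_histogram",
    "hazard",
    "iod",
    "iod_range",
    "compute_summary",
    "population_rate",
    "postsynaptic_signal",
    "spike_triggered_average",
    "crosscorrelogram",
    "oscillation_frequency",
    "segment_bistable_states",
]

IOD_BINWIDTHS_S = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

NORMALISED_TOTAL = 10000.0


class EmptyTrainError(ValueError):
    """Raised for statistics that need at least two spikes (silent cells
    are reported, not crashed on, by callers that catch this)."""


@dataclass(frozen=True)
class ISIHistogram:
    """Interval counts in fixed-width bins covering every interval."""

    binwidth: float
    counts: np.ndarray          # raw interval counts per bin
    n_intervals: int

    @property
    def normalised(self) -> np.ndarray:
        """Counts scaled so they total 10000."""
        return self.counts * (NORMALISED_TOTAL / self.n_intervals)

    @property
    def bin_left_edges(self) -> np.ndarray:
        return np.arange(self.counts.size) * self.binwidth

    @property
    def bin_centres(self) -> np.ndarray:
        return self.bin_left_edges + self.binwidth / 2.0

    def padded(self, n_bins: int, normalised: bool = True) -> np.ndarray:
        """First ``n_bins`` values, zero-padded beyond the data range."""
        src = self.normalised if normalised else self.counts.astype(float)
        out = np.zeros(n_bins)
        m = min(n_bins, src.size)
        out[:m] = src[:m]
        return out


@dataclass(frozen=True)
class HazardFunction:
    binwidth: float
    values: np.ndarray          # conditional probability per bin, in [0, 1]
    survivors: np.ndarray       # denominator: intervals longer than left edge
    valid: np.ndarray           # False where the denominator was 0

    def padded(self, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
        vals = np.zeros(n_bins)
        surv = np.zeros(n_bins)
        m = min(n_bins, self.values.size)
        vals[:m] = self.values[:m]
        surv[:m] = self.survivors[:m]
        return vals, surv


@dataclass(frozen=True)
class IoDRange:
    binwidths_s: tuple
    values: np.ndarray


@dataclass(frozen=True)
class PatternSummary:
    """The fit-target triple plus mean rate, all from one train."""

    isi: ISIHistogram
    hazard: HazardFunction
    iod: IoDRange
    mean_rate: float
    duration: float


def isi_histogram(train: SpikeTrain, binwidth: float = 5.0) -> ISIHistogram:
    """Histogram of all interspike intervals in ``binwidth``-ms bins.

    Interval j = t[j+1] - t[j] falls in bin floor(isi / binwidth); bins
    cover every interval, so raw counts total n_spikes - 1.
    """
    if train.n < 2:
        raise EmptyTrainError(
            f"ISI histogram needs >= 2 spikes, train has {train.n}")
    isis = train.isis
    idx = np.floor(isis / binwidth).astype(np.int64)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    return ISIHistogram(binwidth, counts, int(isis.size))


def hazard(hist: ISIHistogram) -> HazardFunction:
    """Hazard from raw interval counts.

    h[b] = counts[b] / (number of intervals with length > left edge of b);
    the denominator is the survivor count, total minus all counts in
    earlier bins.  Bins whose denominator is 0 are marked invalid.
    """
    counts = hist.counts.astype(float)
    survivors = hist.n_intervals - np.concatenate(([0.0], np.cumsum(counts)[:-1]))
    valid = survivors > 0
    values = np.zeros_like(counts)
    values[valid] = counts[valid] / survivors[valid]
    return HazardFunction(hist.binwidth, values, survivors, valid)


def iod(train: SpikeTrain, binwidth_s: float) -> float:
    """Index of dispersion of firing rate at one binwidth.

    Bins tile the record from t = 0; a trailing partial bin is discarded.
    Sample variance (ddof=1) over the bin counts divided by their mean.
    """
    if train.n == 0:
        raise EmptyTrainError("IoD undefined for an empty train")
    if train.duration < 10 * binwidth_s * 1000.0:
        raise ValueError("duration must be at least 10x the IoD binwidth")
    counts = train.binned_counts(binwidth_s * 1000.0)
    mean = counts.mean()
    if mean == 0:
        raise EmptyTrainError("IoD undefined: no spikes in complete bins")
    return float(counts.var(ddof=1) / mean)


def iod_range(train: SpikeTrain,
              binwidths_s: tuple = IOD_BINWIDTHS_S) -> IoDRange:
    return IoDRange(tuple(binwidths_s),
                    np.array([iod(train, bw) for bw in binwidths_s]))


def compute_summary(train: SpikeTrain, isi_binwidth: float = 5.0,
                    discard_ms: float = 0.0,
                    iod_binwidths_s: tuple = IOD_BINWIDTHS_S) -> PatternSummary:
    """ISI histogram + hazard + IoD range + mean rate from one train.

    ``discard_ms`` drops an initial transient before computing statistics.
    """
    if discard_ms > 0:
        train = train.crop(discard_ms)
    hist = isi_histogram(train, isi_binwidth)
    return PatternSummary(hist, hazard(hist), iod_range(train, iod_binwidths_s),
                          train.rate, train.duration)


def isi_modes(hist: ISIHistogram, smooth_bins: int = 5,
              min_separation_ms: float = 150.0,
              prominence_frac: float = 0.05) -> np.ndarray:
    """Locations (bin-centre ms) of the modal peaks of an ISI histogram.

    The normalised histogram is smoothed with a ``smooth_bins`` moving
    average and local maxima are detected with a minimum separation and a
    prominence threshold relative to the tallest smoothed bin.  Multimodal
    histograms of network "oscillatory"-type cells yield peaks spaced at
    the network rhythm period.
    """
    smooth = np.convolve(hist.normalised, np.ones(smooth_bins) / smooth_bins,
                         mode="same")
    distance = max(1, int(round(min_separation_ms / hist.binwidth)))
    # zero-pad so modes in the first/last bin are detectable
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = signal.find_peaks(padded, distance=distance,
                                 prominence=prominence_frac * smooth.max())
    return hist.bin_centres[peaks - 1]


def isi_mode_spacing(hist: ISIHistogram, min_ms: float = 100.0,
                     max_ms: float = 1000.0, **kwargs) -> float:
    """Mean spacing (ms) between successive late modal peaks in
    (``min_ms``, ``max_ms``) — the per-cell signature of an underlying
    population rhythm.  The upper bound keeps the estimate inside the
    well-populated histogram range."""
    peaks = isi_modes(hist, **kwargs)
    late = peaks[(peaks > min_ms) & (peaks < max_ms)]
    if late.size < 2:
        raise ValueError("fewer than two late ISI modes detected")
    return float(np.mean(np.diff(late)))


def pooled_isi_histogram(trains, binwidth: float = 5.0) -> ISIHistogram:
    """ISI histogram pooled over a set of statistically identical cells
    (silent or single-spike trains are skipped)."""
    parts = [tr.isis for tr in trains if tr.n >= 2]
    if not parts:
        raise EmptyTrainError("no train has two or more spikes")
    isis = np.concatenate(parts)
    idx = np.floor(isis / binwidth).astype(np.int64)
    counts = np.bincount(idx)
    return ISIHistogram(binwidth, counts, int(isis.size))


# ---------------------------------------------------------------------------
# Population-level signals
# ---------------------------------------------------------------------------

def population_rate(trains, binwidth_ms: float = 1.0) -> np.ndarray:
    """Element-wise sum of per-neuron binned spike counts."""
    trains = list(trains)
    if not trains:
        raise ValueError("need at least one train")
    duration = trains[0].duration
    n_bins = int(duration // binwidth_ms)
    total = np.zeros(n_bins)
    for tr in trains:
        if tr.duration != duration:
            raise ValueError("trains must share the same duration")
        total += tr.binned_counts(binwidth_ms, n_bins)
    return total


def postsynaptic_signal(trains, amplitude: float = 3.0,
                        half_life: float = 7.5,
                        binwidth_ms: float = 1.0) -> np.ndarray:
    """Simulated input potential in a downstream target neuron.

    Each spike contributes an EPSP of the given amplitude decaying with the
    given half-life — an exponential-kernel filtering of the summed 1-ms
    population count (a smoothed version of the population signal).
    """
    counts = population_rate(trains, binwidth_ms)
    decay = 0.5 ** (binwidth_ms / half_life)
    return signal.lfilter([amplitude], [1.0, -decay], counts)


def spike_triggered_average(trace: np.ndarray, train: SpikeTrain,
                            window_ms: float, dt: float = 1.0
                            ) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean of trace segments aligned on spike times.

    ``trace`` is sampled every ``dt`` ms with sample k covering time
    (k+1)*dt (simulator convention).  Returns (lags_ms, mean_waveform,
    n_dropped) where spikes whose window leaves the record are dropped.
    """
    half = int(round(window_ms / dt))
    n = trace.shape[0]
    segments = []
    dropped = 0
    for t in train.times:
        c = int(round(t / dt)) - 1  # sample index of the spike time
        if c - half < 0 or c + half >= n:
            dropped += 1
            continue
        segments.append(trace[c - half:c + half + 1])
    if not segments:
        raise ValueError("no spike window fits inside the trace")
    lags = np.arange(-half, half + 1) * dt
    return lags, np.mean(segments, axis=0), dropped


def crosscorrelogram(train_a: SpikeTrain, train_b: SpikeTrain,
                     lag_window_ms: float = 50.0, binwidth_ms: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of lags t_b - t_a over all spike pairs within the window.

    Returns (bin_centres_ms, counts) with bins symmetric about zero lag.
    """
    edges = np.arange(-lag_window_ms, lag_window_ms + binwidth_ms, binwidth_ms)
    counts = np.zeros(edges.size - 1)
    tb = train_b.times
    for ta in train_a.times:
        lo = np.searchsorted(tb, ta - lag_window_ms)
        hi = np.searchsorted(tb, ta + lag_window_ms)
        if hi > lo:
            c, _ = np.histogram(tb[lo:hi] - ta, bins=edges)
            counts += c
    centres = (edges[:-1] + edges[1:]) / 2.0
    return centres, counts


def oscillation_frequency(counts: np.ndarray, binwidth_ms: float = 1.0,
                          f_lo: float = 0.5, f_hi: float = 20.0,
                          segment_s: float = 50.0,
                          significance_ratio: float = 4.0
                          ) -> tuple[float, bool, float]:
    """Dominant frequency of a binned population count series.

    Averaged periodogram (Welch, ``segment_s`` segments, half overlap) of
    the mean-removed series; the peak is searched in [f_lo, f_hi] Hz and
    flagged significant when its power exceeds ``significance_ratio`` times
    the median spectral power in that band.

    Returns (frequency_hz, significant, peak_to_median_ratio).
    """
    fs = 1000.0 / binwidth_ms
    if counts.size * binwidth_ms < 100_000.0:
        raise ValueError("need at least 100 s of data")
    nperseg = min(int(segment_s * fs), counts.size)
    freqs, power = signal.welch(counts - counts.mean(), fs=fs,
                                nperseg=nperseg, noverlap=nperseg // 2,
                                detrend=False)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    f_band, p_band = freqs[band], power[band]
    peak = int(np.argmax(p_band))
    ratio = float(p_band[peak] / np.median(p_band))
    return float(f_band[peak]), ratio >= significance_ratio, ratio


def segment_bistable_states(rate_hz: np.ndarray, sample_s: float,
                            threshold_hz: float = 3.0,
                            min_duration_s: float = 10.0,
                            smooth_s: float = 10.0) -> list:
    """Two-state segmentation of a mean-rate series into slow/fast epochs.

    The series (per-neuron mean rate in spikes/s, sampled every
    ``sample_s``) is smoothed with a moving average of width ``smooth_s``
    and thresholded; runs shorter than ``min_duration_s`` are merged into
    their predecessor.  Returns [(t_start_s, t_end_s, "slow"|"fast"), ...].
    """
    w = max(1, int(round(smooth_s / sample_s)))
    kernel = np.ones(w) / w
    smooth = np.convolve(rate_hz, kernel, mode="same")
    fast = smooth > threshold_hz
    # run-length encode
    segments = []
    start = 0
    for i in range(1, fast.size + 1):
        if i == fast.size or fast[i] != fast[start]:
            segments.append([start * sample_s, i * sample_s,
                             "fast" if fast[start] else "slow"])
            start = i
    # merge short runs into the previous state
    merged = []
    for seg in segments:
        if merged and (seg[1] - seg[0]) < min_duration_s:
            merged[-1][1] = seg[1]
        elif merged and merged[-1][2] == seg[2]:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)
    # a leading short run merges forward
    if len(merged) > 1 and (merged[0][1] - merged[0][0]) < min_duration_s:
        merged[1][0] = merged[0][0]
        merged = merged[1:]
    return [tuple(s) for s in merged]
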