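"""Synthetic spike-train generators with known statistical structure.

These provide analysis-module ground truth: Poisson (IoD = 1, exponential
ISIs), regular (constant ISIs, IoD << 1), gamma renewal (tunable
regularity), burst-epoch trains (IoD > 1, rising with binwidth), and
sinusoid-modulated inhomogeneous Poisson trains (a known population rhythm).
They are stand-ins for the patterning regimes seen in vivo, not surrogates
for real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spiketrain import SpikeTrain

__all__ = [
    "FixtureSpec",
    "generate",
    "poisson_train",
    "regular_train",
    "gamma_train",
    "burst_train",
    "sinusoid_train",
]


@dataclass(frozen=True)
class FixtureSpec:
    """kind in {poisson, regular, gamma, burst, sinusoid} plus its knobs."""

    kind: str
    rate_hz: float = 5.0
    duration_s: float = 1000.0
    seed: int = 0
    # gamma renewal
    shape: float = 4.0
    # burst-epoch
    epoch_s: float = 5.0
    burst_rate_hz: float = 10.0
    # sinusoid modulation
    mod_depth: float = 0.8
    mod_freq_hz: float = 3.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration must be > 0")


def generate(spec: FixtureSpec) -> SpikeTrain:
    """Dispatch on ``spec.kind``; deterministic per seed."""
    if spec.kind == "poisson":
        return poisson_train(spec.rate_hz, spec.duration_s, spec.seed)
    if spec.kind == "regular":
        return regular_train(spec.rate_hz, spec.duration_s)
    if spec.kind == "gamma":
        return gamma_train(spec.rate_hz, spec.shape, spec.duration_s, spec.seed)
    if spec.kind == "burst":
        return burst_train(spec.burst_rate_hz, spec.epoch_s, spec.duration_s,
                           spec.seed)
    if spec.kind == "sinusoid":
        return sinusoid_train(spec.rate_hz, spec.mod_depth, spec.mod_freq_hz,
                              spec.duration_s, spec.seed)
    raise ValueError(f"unknown fixture kind: {spec.kind!r}")


def poisson_train(rate_hz: float, duration_s: float, seed) -> SpikeTrain:
    """Homogeneous Poisson: iid exponential ISIs."""
    duration_ms = duration_s * 1000.0
    rng = np.random.default_rng(seed)
    if rate_hz == 0:
        return SpikeTrain(np.empty(0), duration_ms)
    mean_isi_ms = 1000.0 / rate_hz
    n_guess = int(duration_s * rate_hz * 1.2) + 100
    times = np.cumsum(rng.exponential(mean_isi_ms, size=n_guess))
    while times.size and times[-1] < duration_ms:
        times = np.concatenate(
            [times, times[-1] + np.cumsum(rng.exponential(mean_isi_ms, 100))])
    return SpikeTrain(times[times <= duration_ms], duration_ms)


def regular_train(rate_hz: float, duration_s: float,
                  phase_ms: float = 0.0) -> SpikeTrain:
    """Perfectly periodic spiking (ISI = 1000/rate ms exactly)."""
    duration_ms = duration_s * 1000.0
    isi = 1000.0 / rate_hz
    times = np.arange(phase_ms + isi, duration_ms + 1e-9, isi)
    return SpikeTrain(times, duration_ms)


def gamma_train(rate_hz: float, shape: float, duration_s: float,
                seed) -> SpikeTrain:
    """Gamma-renewal process with the given mean rate; shape > 1 is more
    regular than Poisson, shape < 1 burstier."""
    duration_ms = duration_s * 1000.0
    rng = np.random.default_rng(seed)
    scale = 1000.0 / (rate_hz * shape)
    n_guess = int(duration_s * rate_hz * 1.2) + 100
    times = np.cumsum(rng.gamma(shape, scale, size=n_guess))
    while times.size and times[-1] < duration_ms:
        times = np.concatenate(
            [times, times[-1] + np.cumsum(rng.gamma(shape, scale, 100))])
    return SpikeTrain(times[times <= duration_ms], duration_ms)


def burst_train(burst_rate_hz: float, epoch_s: float, duration_s: float,
                seed) -> SpikeTrain:
    """Alternating silent / Poisson-active epochs of equal length —
    clustered spiking whose IoD rises with binwidth."""
    duration_ms = duration_s * 1000.0
    rng = np.random.default_rng(seed)
    times = []
    t = epoch_s  # start silent, alternate
    while t < duration_s:
        stop = min(t + epoch_s, duration_s)
        seg = poisson_train(burst_rate_hz, stop - t, rng)
        times.append(seg.times + t * 1000.0)
        t += 2 * epoch_s
    all_times = np.concatenate(times) if times else np.empty(0)
    return SpikeTrain(all_times, duration_ms)


def sinusoid_train(base_rate_hz: float, depth: float, freq_hz: float,
                   duration_s: float, seed) -> SpikeTrain:
    """Inhomogeneous Poisson with rate r(t) = base * (1 + depth sin(2πft)),
    generated by thinning (exact for this bounded rate)."""
    if not 0 <= depth <= 1:
        raise ValueError("modulation depth must be in [0, 1]")
    duration_ms = duration_s * 1000.0
    rng = np.random.default_rng(seed)
    r_max = base_rate_hz * (1.0 + depth)
    candidate = poisson_train(r_max, duration_s, rng)
    t_s = candidate.times / 1000.0
    accept_p = (1.0 + depth * np.sin(2.0 * np.pi * freq_hz * t_s)) / (1.0 + depth)
    keep = rng.random(t_s.size) < accept_p
    return SpikeTrain(candidate.times[keep], duration_ms)
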