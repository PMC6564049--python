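"""Ornstein-Uhlenbeck modulation of the external input rate.

Most simulations drive each neuron with a fixed-rate Poisson input; for
noisier drive the EPSP rate ``i_re`` itself becomes an OU variable::

    I_re' = I_re + (mu - I_re)/tau * dt + k * sqrt(dt) * g,   g ~ N(0, 1)

(Euler-Maruyama form, dt in seconds), clamped at zero because Poisson rates
cannot be negative.  The amplitude can be given either as a fraction of the
mean (``relative=True``, matching the "amp = 0.05" usage of the bistable
simulations) or as an absolute value in Hz per sqrt(s).

The trajectory is a single shared signal: when a network is driven by a
noisy rate, all neurons see the same I_re(t) (each still draws its own
Poisson event counts from it), so slow excursions act coherently on the
population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = ["OUParams", "ou_step", "ou_trajectory"]


@dataclass(frozen=True)
class OUParams:
    """mu_noise (Hz), tau_noise (s), and noise amplitude.

    ``amp`` is k_noise in Hz/sqrt(s) when ``relative`` is False, otherwise a
    dimensionless fraction of ``mu`` (k_noise = amp * mu).
    """

    mu: float = 100.0
    tau_s: float = 120.0
    amp: float = 0.05
    relative: bool = True

    def __post_init__(self) -> None:
        if not self.tau_s > 0:
            raise ValueError("tau_noise must be > 0")
        if self.amp < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.mu < 0:
            raise ValueError("noise mean must be >= 0")

    @property
    def k_noise(self) -> float:
        return self.amp * self.mu if self.relative else self.amp


def ou_step(i_re: float, params: OUParams, dt_ms: float,
            rng: np.random.Generator) -> float:
    """One Euler-Maruyama update of the rate variable (clamped at 0 Hz)."""
    dt_s = dt_ms / 1000.0
    g = rng.standard_normal()
    x = i_re + (params.mu - i_re) / params.tau_s * dt_s \
        + params.k_noise * np.sqrt(dt_s) * g
    return max(x, 0.0)


def ou_trajectory(params: OUParams, n_steps: int, dt_ms: float,
                  rng: np.random.Generator,
                  x0: float | None = None) -> np.ndarray:
    """Full rate trajectory (Hz), initialised to the mean by default."""
    if x0 is None:
        x0 = params.mu
    gauss = rng.standard_normal(n_steps)
    return _kernels.ou_kernel(gauss, params.mu, params.tau_s,
                              params.k_noise, dt_ms / 1000.0, x0)
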