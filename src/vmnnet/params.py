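"""Model parameter containers and the published default parameter sets.

The single-neuron model is a leaky integrate-and-fire neuron driven by twin
Poisson streams of fixed-amplitude EPSPs and IPSPs, extended with up to three
cumulative post-spike potentials:

* HAP — a large, brief hyperpolarising afterpotential that produces the
  relative refractory period;
* AHP — a small, slow afterhyperpolarisation (activity-dependent negative
  feedback);
* DAP — a slow depolarising afterpotential (activity-dependent positive
  feedback).

Each potential is incremented by its ``k`` amplitude at every spike and
decays exponentially with its half-life ``lambda``; unlike the classic
integrate-and-fire model, nothing is reset at a spike, so the slow
potentials accumulate across interspike intervals.

All times are in milliseconds, rates in Hz (events/s), voltages in mV.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


LN2 = math.log(2.0)


def half_life_to_tau(lambda_x: float) -> float:
    """Convert an exponential half-life (ms) to a decay time constant (ms).

    tau = lambda / ln 2, so that decay by ``exp(-t/tau)`` halves a quantity
    after exactly ``lambda_x`` milliseconds.

    Raises
    ------
    ValueError
        If ``lambda_x`` is not strictly positive.
    """
    if not lambda_x > 0:
        raise ValueError(f"half-life must be > 0, got {lambda_x}")
    return lambda_x / LN2


@dataclass(frozen=True)
class NeuronParams:
    """Intrinsic parameters of the modified integrate-and-fire neuron.

    Defaults are the published single-neuron model defaults (random-input
    drive with balanced EPSP/IPSP rates, fast 30-mV HAP, AHP and DAP off).
    """

    i_re: float = 300.0        # external EPSP rate (Hz)
    i_ratio: float = 1.0       # IPSP rate / EPSP rate
    e_h: float = 3.0           # EPSP amplitude (mV)
    i_h: float = -3.0          # IPSP amplitude (mV, <= 0)
    lambda_syn: float = 7.5    # PSP half-life (ms)
    k_hap: float = 30.0        # HAP amplitude per spike (mV)
    lambda_hap: float = 8.0    # HAP half-life (ms)
    k_ahp: float = 0.0         # AHP amplitude per spike (mV)
    lambda_ahp: float = 500.0  # AHP half-life (ms)
    k_dap: float = 0.0         # DAP amplitude per spike (mV)
    lambda_dap: float = 1000.0  # DAP half-life (ms)
    v_rest: float = -62.0      # resting potential (mV)
    v_thresh: float = -50.0    # spike threshold (mV)
    t_refabs: float = 2.0      # absolute refractory period (ms)
    dt: float = 1.0            # integration step (ms)
    # Start HAP/AHP/DAP at their k values (published initialisation); set
    # False to start all state at zero for steady-state analyses.
    init_at_k: bool = True
    # Per-step decay convention.  False (default): forward Euler of the
    # differential form, factor (1 - dt/tau) — the convention that
    # reproduces the published network operating points at dt = 1 ms.
    # True: exact factor exp(-dt/tau), which makes half-lives
    # dt-independent.
    exact_decay: bool = False

    def __post_init__(self) -> None:
        for name in ("lambda_syn", "lambda_hap", "lambda_ahp", "lambda_dap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k_hap < 0 or self.k_ahp < 0 or self.k_dap < 0:
            raise ValueError("post-spike potential amplitudes must be >= 0")
        if self.i_re < 0 or self.i_ratio < 0:
            raise ValueError("input rates must be >= 0")
        if self.e_h < 0 or self.i_h > 0:
            raise ValueError("require i_h <= 0 <= e_h")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.t_refabs < 0:
            raise ValueError("t_refabs must be >= 0")

    @property
    def i_ri(self) -> float:
        """IPSP rate (Hz), defined as i_ratio * i_re."""
        return self.i_ratio * self.i_re

    @property
    def tau_syn(self) -> float:
        return half_life_to_tau(self.lambda_syn)

    @property
    def tau_hap(self) -> float:
        return half_life_to_tau(self.lambda_hap)

    @property
    def tau_ahp(self) -> float:
        return half_life_to_tau(self.lambda_ahp)

    @property
    def tau_dap(self) -> float:
        return half_life_to_tau(self.lambda_dap)

    def replace(self, **changes) -> "NeuronParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the random excitatory network.

    The network holds one or two neuron populations.  Type-1 neurons are
    mutually connected (each ordered pair independently with probability
    ``esyn_1``); type-1 neurons project to type-2 neurons with probability
    ``esyn_12``; type-2 neurons send no connections.  Every connection
    carries a frozen transmission delay ``delta_min + delta_range * u`` and
    every spike-triggered transmission succeeds independently with
    probability ``syntrans``.  A successful delivery adds an EPSP of
    amplitude ``synweight_1 * k_syn`` to the target's synaptic potential.
    """

    neuron1: NeuronParams = field(default_factory=NeuronParams)
    neuron2: NeuronParams | None = None
    n_type1: int = 50
    n_type2: int = 0
    esyn_1: float = 0.5       # type1 -> type1 connection probability
    esyn_12: float = 0.0      # type1 -> type2 connection probability
    synweight_1: float = 1.0  # network PSP weighting
    syntrans: float = 0.5     # transmission success probability
    delta_min: float = 5.0    # minimum transmission delay (ms)
    delta_range: float = 10.0  # random delay component (ms)
    k_syn: float = 3.0        # network EPSP amplitude (mV)
    queue_horizon: float = 20.0  # network input queue length (ms)
    # Redraw the delay for every transmission event instead of using the
    # frozen per-connection delay (both behave the same statistically).
    per_event_delay: bool = False

    def __post_init__(self) -> None:
        for name in ("esyn_12", "syntrans"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.esyn_1 > 1.0:
            raise ValueError(f"esyn_1 must be <= 1, got {self.esyn_1}")
        if self.n_type1 < 0 or self.n_type2 < 0:
            raise ValueError("population sizes must be >= 0")
        if self.delta_min < 0 or self.delta_range < 0:
            raise ValueError("delays must be >= 0")
        if self.delta_min + self.delta_range > self.queue_horizon:
            raise ValueError(
                "maximum delay exceeds the network input queue horizon "
                f"({self.delta_min + self.delta_range} > {self.queue_horizon} ms)"
            )
        if self.n_type2 > 0 and self.neuron2 is None:
            raise ValueError("n_type2 > 0 requires neuron2 parameters")

    @property
    def n_total(self) -> int:
        return self.n_type1 + self.n_type2

    def replace(self, **changes) -> "NetworkParams":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Published parameter sets
# ---------------------------------------------------------------------------

def fast_hap_neuron(**overrides) -> NeuronParams:
    """'Fast HAP' network building-block cell (k_HAP=40 mV, half-life 10 ms)."""
    base = dict(i_re=200.0, i_ratio=0.5, k_hap=40.0, lambda_hap=10.0)
    base.update(overrides)
    return NeuronParams(**base)


def slow_hap_neuron(**overrides) -> NeuronParams:
    """'Slow HAP' network building-block cell (k_HAP=20 mV, half-life 40 ms)."""
    base = dict(i_re=200.0, i_ratio=0.5, k_hap=20.0, lambda_hap=40.0)
    base.update(overrides)
    return NeuronParams(**base)


def single_type_network(cell: str = "slow", n: int = 50, **overrides) -> NetworkParams:
    """The 50-neuron single-cell-type network (connectivity sweep setting)."""
    neuron = slow_hap_neuron() if cell == "slow" else fast_hap_neuron()
    base = dict(neuron1=neuron, n_type1=n, esyn_1=0.5)
    base.update(overrides)
    return NetworkParams(**base)


def signal_generator_network(i_re: float = 130.0, n: int = 100,
                             esyn_1: float = 0.35, **overrides) -> NetworkParams:
    """100 slow-HAP neurons at esyn_1 = 0.35: the rhythm-generator network."""
    base = dict(neuron1=slow_hap_neuron(i_re=i_re), n_type1=n, esyn_1=esyn_1)
    base.update(overrides)
    return NetworkParams(**base)


def two_type_network(**overrides) -> NetworkParams:
    """Two cell-type oscillator: 100 slow-HAP generators driving 100 fast-HAP
    receivers, with a widened 5-20 ms delay range to soften synchrony."""
    base = dict(
        neuron1=NeuronParams(i_re=180.0, i_ratio=0.5, k_hap=60.0, lambda_hap=50.0),
        neuron2=NeuronParams(i_re=80.0, i_ratio=0.5, k_hap=60.0, lambda_hap=5.0),
        n_type1=100,
        n_type2=100,
        esyn_1=0.35,
        esyn_12=0.2,
        delta_range=15.0,
    )
    base.update(overrides)
    return NetworkParams(**base)


def bistable_network(i_re: float = 100.0, **overrides) -> NetworkParams:
    """100 slow-HAP + DAP neurons at esyn_1 = 0.25: the bistable network.

    At i_re = 100 Hz the network rests in a stable slow-spiking state
    (~0.85 spikes/s); at 110 Hz it switches to a stable fast state
    (~6 spikes/s).  Both the DAP and the excitatory connections are required.
    """
    base = dict(
        neuron1=NeuronParams(i_re=i_re, i_ratio=0.5, k_hap=30.0, lambda_hap=40.0,
                             k_dap=0.75, lambda_dap=750.0),
        n_type1=100,
        esyn_1=0.25,
        delta_range=10.0,
    )
    base.update(overrides)
    return NetworkParams(**base)
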