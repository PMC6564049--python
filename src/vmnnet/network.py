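"""Random directed excitatory network over model neurons.

Connections are static and generated before the run: each ordered pair of
neurons of the appropriate type pair becomes an edge independently with the
type-pair probability (no self-connections).  Each edge carries a frozen
transmission delay ``delta_min + delta_range * u``; each spike-triggered
transmission succeeds independently with probability ``syntrans``.  Delivery
is implemented with a per-neuron ring-buffer input queue spanning the 20-ms
delay horizon: a delivery scheduled with delay d is read d steps later, the
head count n_n giving the current network input
``I_net = synweight_1 * k_syn * n_n`` (summation within a step is linear).

All neurons update synchronously; a spike fired at step t is eligible for
delivery from step t + delay, never in its own step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core_neuron import NeuronState, generate_external_input, _decay_factors
from .params import NetworkParams, NeuronParams
from .spiketrain import SpikeTrain

__all__ = [
    "Connectivity",
    "Heterogeneity",
    "NetworkResult",
    "build_network",
    "transmit",
    "network_input",
    "simulate_network",
]


@dataclass(frozen=True)
class Connectivity:
    """Directed edge list with per-edge delays (ms)."""

    n_neurons: int
    sources: np.ndarray
    targets: np.ndarray
    delays_ms: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sources", "targets"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.int64))
        object.__setattr__(self, "delays_ms",
                           np.asarray(self.delays_ms, dtype=float))
        if not (self.sources.shape == self.targets.shape == self.delays_ms.shape):
            raise ValueError("edge arrays must have equal length")
        if np.any(self.sources == self.targets):
            raise ValueError("self-connections are not allowed")

    @property
    def n_edges(self) -> int:
        return int(self.sources.size)

    def csr(self, dt: float, queue_len: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR layout by source neuron, delays rounded to steps in
        [1, queue_len - 1]."""
        order = np.argsort(self.sources, kind="stable")
        src = self.sources[order]
        tgt = self.targets[order]
        steps = np.rint(self.delays_ms[order] / dt).astype(np.int64)
        steps = np.clip(steps, 1, queue_len - 1)
        indptr = np.zeros(self.n_neurons + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        indptr = np.cumsum(indptr)
        return indptr, tgt, steps

    def in_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_neurons, dtype=np.int64)
        np.add.at(deg, self.targets, 1)
        return deg

    def to_file(self, path) -> None:
        """Write an edge-list text file: ``source<TAB>target<TAB>delay_ms``."""
        with open(path, "w") as fh:
            fh.write(f"# n_neurons={self.n_neurons}\n")
            for s, t, d in zip(self.sources, self.targets, self.delays_ms):
                fh.write(f"{s}\t{t}\t{d:.6f}\n")

    @classmethod
    def from_file(cls, path) -> "Connectivity":
        n = None
        src, tgt, dly = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if "n_neurons=" in line:
                        n = int(line.split("n_neurons=")[1])
                    continue
                if not line:
                    continue
                a, b, d = line.split("\t")
                src.append(int(a))
                tgt.append(int(b))
                dly.append(float(d))
        if n is None:
            n = max(max(src, default=-1), max(tgt, default=-1)) + 1
        return cls(n, np.array(src), np.array(tgt), np.array(dly))


@dataclass(frozen=True)
class Heterogeneity:
    """Optional per-neuron overrides (arrays over the full population).

    ``esyn_recv`` overrides the inbound connection probability per type-1
    receiver; values <= 0 mean the neuron receives no network connections
    but can still project to others.
    """

    lambda_hap: np.ndarray | None = None
    i_re: np.ndarray | None = None
    esyn_recv: np.ndarray | None = None


def build_network(params: NetworkParams, seed,
                  heterogeneity: Heterogeneity | None = None) -> Connectivity:
    """Randomly generate the static connectivity.

    Type-1 receivers draw inbound edges from every other type-1 neuron with
    probability ``esyn_1`` (or their per-neuron override); type-2 receivers
    draw inbound edges from type-1 neurons with probability ``esyn_12``.
    Per-edge delays are frozen uniform draws in
    [delta_min, delta_min + delta_range].
    """
    rng = np.random.default_rng(seed)
    n1, n2 = params.n_type1, params.n_type2
    n = n1 + n2
    esyn_recv = None
    if heterogeneity is not None and heterogeneity.esyn_recv is not None:
        esyn_recv = np.asarray(heterogeneity.esyn_recv, dtype=float)
        if esyn_recv.shape[0] != n:
            raise ValueError("esyn_recv must cover the full population")
    src_list, tgt_list = [], []
    for j in range(n1):  # type-1 receivers
        p = params.esyn_1 if esyn_recv is None else esyn_recv[j]
        if p <= 0:
            continue
        mask = rng.random(n1) < p
        mask[j] = False
        srcs = np.nonzero(mask)[0]
        src_list.append(srcs)
        tgt_list.append(np.full(srcs.size, j, dtype=np.int64))
    for j in range(n1, n):  # type-2 receivers, inbound from type 1 only
        if params.esyn_12 <= 0:
            continue
        mask = rng.random(n1) < params.esyn_12
        srcs = np.nonzero(mask)[0]
        src_list.append(srcs)
        tgt_list.append(np.full(srcs.size, j, dtype=np.int64))
    if src_list:
        sources = np.concatenate(src_list)
        targets = np.concatenate(tgt_list)
    else:
        sources = np.empty(0, dtype=np.int64)
        targets = np.empty(0, dtype=np.int64)
    delays = params.delta_min + params.delta_range * rng.random(sources.size)
    return Connectivity(n, sources, targets, delays)


def transmit(spiking_neurons, connectivity: Connectivity, queue: np.ndarray,
             qhead: int, params: NetworkParams, rng: np.random.Generator,
             dt: float = 1.0) -> int:
    """Reference transmission step: for each outgoing edge of each spiking
    neuron, a Bernoulli(syntrans) trial decides delivery; on success the
    target queue is incremented at the edge's delay offset.

    Returns the number of successful deliveries.  (The compiled network
    kernel performs the identical update internally.)
    """
    qlen = queue.shape[1]
    delivered = 0
    spiking = set(int(i) for i in spiking_neurons)
    for s, t, d_ms in zip(connectivity.sources, connectivity.targets,
                          connectivity.delays_ms):
        if int(s) not in spiking:
            continue
        if rng.random() < params.syntrans:
            d = int(np.clip(round(d_ms / dt), 1, qlen - 1))
            queue[t, (qhead + d) % qlen] += 1
            delivered += 1
    return delivered


def network_input(head_counts, params: NetworkParams):
    """Network input I_net (mV) from queue-head EPSP counts n_n."""
    return params.synweight_1 * params.k_syn * np.asarray(head_counts, dtype=float)


@dataclass
class NetworkResult:
    """Per-neuron spike trains plus optional voltage traces."""

    trains: list
    duration: float
    dt: float
    connectivity: Connectivity
    v_traces: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def mean_rate(self, t_start: float = 0.0, t_stop: float | None = None) -> float:
        """Mean per-neuron firing rate (spikes/s) over a window."""
        if t_stop is None:
            t_stop = self.duration
        span_s = (t_stop - t_start) / 1000.0
        counts = [np.count_nonzero((tr.times >= t_start) & (tr.times <= t_stop))
                  for tr in self.trains]
        return float(np.mean(counts) / span_s)


def _per_neuron_params(params: NetworkParams,
                       heterogeneity: Heterogeneity | None) -> list[NeuronParams]:
    base1, base2 = params.neuron1, params.neuron2
    per = [base1] * params.n_type1 + [base2] * params.n_type2
    if heterogeneity is not None:
        n = params.n_total
        lam = heterogeneity.lambda_hap
        ire = heterogeneity.i_re
        out = []
        for i in range(n):
            p = per[i]
            changes = {}
            if lam is not None:
                changes["lambda_hap"] = float(lam[i])
            if ire is not None:
                changes["i_re"] = float(ire[i])
            out.append(p.replace(**changes) if changes else p)
        per = out
    return per


def _chunk_steps(n_neurons: int) -> int:
    # bound the pre-generated external-input block to ~100 MB
    return max(5_000, int(12_500_000 / max(n_neurons, 1)))


def simulate_network(params: NetworkParams, duration: float, seed,
                     connectivity: Connectivity | None = None,
                     heterogeneity: Heterogeneity | None = None,
                     rate_offset: np.ndarray | None = None,
                     record: tuple = (),
                     ) -> NetworkResult:
    """Synchronous forward simulation of the full network.

    Parameters
    ----------
    duration:
        Run length in ms.
    seed:
        Master seed; per-neuron external-input streams, connectivity
        generation, and transmission trials are all derived from it, so
        identical arguments give bit-identical results.
    connectivity:
        Pre-built connectivity (built from ``seed`` when omitted).
    heterogeneity:
        Optional per-neuron parameter overrides.
    rate_offset:
        Optional per-step offset (Hz) added to every neuron's external EPSP
        rate (perturbation pulses, shared OU drive); length must be the
        number of steps.
    record:
        Neuron indices whose voltage traces are recorded every step.
    """
    neurons = _per_neuron_params(params, heterogeneity)
    n = params.n_total
    if n == 0:
        raise ValueError("network must contain at least one neuron")
    dt = params.neuron1.dt
    if params.neuron2 is not None and params.neuron2.dt != dt:
        raise ValueError("both neuron types must share dt")
    for p in (params.neuron1, params.neuron2):
        if p is not None and (p.v_rest != params.neuron1.v_rest
                              or p.v_thresh != params.neuron1.v_thresh
                              or p.t_refabs != params.neuron1.t_refabs):
            raise ValueError("v_rest/v_thresh/t_refabs must match across types")
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration must cover at least one step")
    if rate_offset is not None and rate_offset.shape[0] != n_steps:
        raise ValueError("rate_offset length must equal the number of steps")

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n + 2)
    neuron_rngs = [np.random.default_rng(c) for c in child[:n]]
    if connectivity is None:
        connectivity = build_network(params, child[n], heterogeneity)
    elif connectivity.n_neurons != n:
        raise ValueError("connectivity size does not match the population")
    kernel_seed = int(child[n + 1].generate_state(1, dtype=np.uint32)[0])
    _kernels.seed_kernel_rng(kernel_seed)

    queue_len = int(round(params.queue_horizon / dt)) + 1
    indptr, edge_targets, edge_delay_steps = connectivity.csr(dt, queue_len)
    queue = np.zeros((n, queue_len), dtype=np.int64)
    qhead = 0

    d_syn = np.empty(n)
    d_hap = np.empty(n)
    d_ahp = np.empty(n)
    d_dap = np.empty(n)
    k_hap = np.empty(n)
    k_ahp = np.empty(n)
    k_dap = np.empty(n)
    vsyn = np.zeros(n)
    hap = np.zeros(n)
    ahp = np.zeros(n)
    dap = np.zeros(n)
    t_last = np.full(n, -np.inf)
    for i, p in enumerate(neurons):
        d_syn[i], d_hap[i], d_ahp[i], d_dap[i] = _decay_factors(p)
        k_hap[i], k_ahp[i], k_dap[i] = p.k_hap, p.k_ahp, p.k_dap
        init = NeuronState.initial(p)
        vsyn[i], hap[i], ahp[i], dap[i] = init.v_syn, init.hap, init.ahp, init.dap

    ref = params.neuron1
    syn_amp = params.synweight_1 * params.k_syn
    delay_min_steps = int(np.clip(round(params.delta_min / dt), 1, queue_len - 1))
    delay_span_steps = int(round(params.delta_range / dt))
    record_idx = np.asarray(record, dtype=np.int64)

    chunk = _chunk_steps(n)
    all_times: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    v_chunks: list[np.ndarray] = []
    start = 0
    while start < n_steps:
        steps = min(chunk, n_steps - start)
        i_ext = np.empty((n, steps))
        off = None if rate_offset is None else rate_offset[start:start + steps]
        for i, p in enumerate(neurons):
            i_ext[i] = generate_external_input(p, steps, neuron_rngs[i], off)
        spike_times = np.empty(n * (steps // 3 + 1), dtype=np.float64)
        spike_neurons = np.empty(n * (steps // 3 + 1), dtype=np.int64)
        n_sp, qhead, v_traces = _kernels.network_kernel(
            i_ext, dt, d_syn, d_hap, d_ahp, d_dap, k_hap, k_ahp, k_dap,
            ref.v_rest, ref.v_thresh, ref.t_refabs,
            indptr, edge_targets, edge_delay_steps,
            syn_amp, params.syntrans,
            params.per_event_delay, delay_min_steps, delay_span_steps,
            queue, qhead,
            vsyn, hap, ahp, dap, t_last,
            start * dt, record_idx,
            spike_times, spike_neurons)
        all_times.append(spike_times[:n_sp].copy())
        all_ids.append(spike_neurons[:n_sp].copy())
        if record_idx.size:
            v_chunks.append(v_traces)
        start += steps

    times = np.concatenate(all_times) if all_times else np.empty(0)
    ids = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=np.int64)
    total_ms = n_steps * dt
    trains = [SpikeTrain(times[ids == i], total_ms) for i in range(n)]
    v_out = {}
    if record_idx.size:
        joined = np.concatenate(v_chunks, axis=1)
        v_out = {int(idx): joined[r] for r, idx in enumerate(record_idx)}
    return NetworkResult(trains, total_ms, dt, connectivity, v_out)
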