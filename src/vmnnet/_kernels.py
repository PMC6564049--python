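"""Numba-compiled integration kernels.

The per-step update is inherently sequential (spike-triggered increments feed
back into the next step), so the inner loops are compiled.  All stochastic
external input is pre-generated with seeded numpy Generators outside the
kernels; only the network transmission Bernoulli trials (and optional
per-event delay draws) use numba's internal RNG, seeded explicitly per run.

Per-step order of operations (a spike's own afterpotentials act from the
next step, consistent with "post-spike" potentials):

1. read the network input queue head (network kernel only),
2. decay V_syn / HAP / AHP / DAP by their exact per-step factors exp(-dt/tau),
3. add this step's summed input to V_syn,
4. compute V = V_rest + V_syn - HAP - AHP + DAP,
5. if V >= V_thresh and the time since the last spike exceeds the absolute
   refractory period, emit a spike and add the k increments (no reset).

Spike times are stamped at the end of the step: t = (step_index + 1) * dt.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed numba's internal RNG (used for transmission trials)."""
    np.random.seed(seed)


@njit(cache=True)
def single_neuron_kernel(i_in, dt, d_syn, d_hap, d_ahp, d_dap,
                         k_hap, k_ahp, k_dap, v_rest, v_thresh, t_refabs,
                         vsyn0, hap0, ahp0, dap0, t_last0, t0,
                         record_v):
    """Integrate one neuron over len(i_in) steps.

    ``i_in`` is the pre-generated total input (mV) added to V_syn at each
    step.  Returns (spike_times, n_spikes, state, v_trace); ``state`` is the
    final (vsyn, hap, ahp, dap, t_last) for chunked continuation.
    """
    n = i_in.shape[0]
    spikes = np.empty(n // 3 + 1, dtype=np.float64)
    n_spikes = 0
    if record_v:
        v_trace = np.empty(n, dtype=np.float64)
    else:
        v_trace = np.empty(0, dtype=np.float64)

    vsyn = vsyn0
    hap = hap0
    ahp = ahp0
    dap = dap0
    t_last = t_last0

    for step in range(n):
        vsyn = vsyn * d_syn + i_in[step]
        hap *= d_hap
        ahp *= d_ahp
        dap *= d_dap
        v = v_rest + vsyn - hap - ahp + dap
        if record_v:
            v_trace[step] = v
        t = t0 + (step + 1) * dt
        if v >= v_thresh and (t - t_last) > t_refabs:
            spikes[n_spikes] = t
            n_spikes += 1
            t_last = t
            hap += k_hap
            ahp += k_ahp
            dap += k_dap

    state = np.array([vsyn, hap, ahp, dap, t_last])
    return spikes[:n_spikes], n_spikes, state, v_trace


@njit(cache=True)
def network_kernel(i_ext, dt, d_syn, d_hap, d_ahp, d_dap,
                   k_hap, k_ahp, k_dap, v_rest, v_thresh, t_refabs,
                   indptr, edge_targets, edge_delay_steps,
                   syn_amp, syntrans,
                   per_event_delay, delay_min_steps, delay_span_steps,
                   queue, qhead,
                   vsyn, hap, ahp, dap, t_last,
                   t0, record_idx,
                   spike_times, spike_neurons):
    """Advance all neurons synchronously over one chunk of steps.

    Parameters are per-neuron arrays except the scalars documented inline.
    ``i_ext`` is (n_neurons, n_steps) pre-generated external input in mV.
    Connectivity is CSR by source: edges of neuron i are
    ``edge_targets[indptr[i]:indptr[i+1]]`` with frozen delays (in steps)
    ``edge_delay_steps``.  ``queue`` is the (n_neurons, qlen) ring buffer of
    pending network-EPSP counts and ``qhead`` its current read position.

    Spikes fired at step t schedule deliveries at offsets >= 1 step, so a
    neuron never receives a same-step spike.  Returns
    (n_spikes, qhead, v_traces).
    """
    n_neurons, n_steps = i_ext.shape
    qlen = queue.shape[1]
    n_rec = record_idx.shape[0]
    if n_rec > 0:
        v_traces = np.empty((n_rec, n_steps), dtype=np.float64)
    else:
        v_traces = np.empty((0, 0), dtype=np.float64)

    n_spikes = 0
    for step in range(n_steps):
        t = t0 + (step + 1) * dt
        # spiking neurons this step, collected for transmission afterwards
        for i in range(n_neurons):
            i_net = syn_amp * queue[i, qhead]
            vsyn[i] = vsyn[i] * d_syn[i] + i_ext[i, step] + i_net
            hap[i] *= d_hap[i]
            ahp[i] *= d_ahp[i]
            dap[i] *= d_dap[i]
            v = v_rest + vsyn[i] - hap[i] - ahp[i] + dap[i]
            if v >= v_thresh and (t - t_last[i]) > t_refabs:
                spike_times[n_spikes] = t
                spike_neurons[n_spikes] = i
                n_spikes += 1
                t_last[i] = t
                hap[i] += k_hap[i]
                ahp[i] += k_ahp[i]
                dap[i] += k_dap[i]
                # transmit along outgoing connections
                for e in range(indptr[i], indptr[i + 1]):
                    if np.random.random() < syntrans:
                        if per_event_delay:
                            d = delay_min_steps + int(
                                np.random.random() * (delay_span_steps + 1))
                            if d > delay_span_steps + delay_min_steps:
                                d = delay_span_steps + delay_min_steps
                        else:
                            d = edge_delay_steps[e]
                        queue[edge_targets[e], (qhead + d) % qlen] += 1
            queue[i, qhead] = 0
        for r in range(n_rec):
            i = record_idx[r]
            v_traces[r, step] = v_rest + vsyn[i] - hap[i] - ahp[i] + dap[i]
        qhead = (qhead + 1) % qlen

    return n_spikes, qhead, v_traces


@njit(cache=True)
def ou_kernel(gauss, mu, tau_s, k_noise, dt_s, x0):
    """Euler-Maruyama Ornstein-Uhlenbeck recursion with clamping at 0.

    ``gauss`` holds pre-drawn standard-normal increments; returns the
    trajectory sampled after each step.
    """
    n = gauss.shape[0]
    out = np.empty(n, dtype=np.float64)
    x = x0
    sq = np.sqrt(dt_s)
    for i in range(n):
        x = x + (mu - x) / tau_s * dt_s + k_noise * sq * gauss[i]
        if x < 0.0:
            x = 0.0
        out[i] = x
    return out
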