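"""Config-driven in-silico experiments.

Each experiment wires the network simulator, the noise driver, and the
pattern statistics into one reproducible run:

* ``connectivity_sweep`` — single-cell-type 50-neuron networks across a
  range of connection probabilities; rising connectivity raises the firing
  rate and, in slow-HAP networks, grows a second early ISI mode (doublets).
* ``signal_generator`` — 100 slow-HAP neurons at esyn_1 = 0.35 across input
  rates; the summed activity turns into a coherent low-theta oscillation
  whose frequency grows with the input rate (~2.3 Hz near threshold drive,
  ~6 Hz at the highest rates).
* ``two_type_oscillator`` — 100 interconnected slow-HAP neurons drive 100
  fast-HAP receivers; the generator population synchronises at ~3 Hz, the
  receivers show the multimodal ISI signature of "oscillatory" cells.
* ``bistable`` — slow-HAP + DAP network that rests in a slow (~0.85
  spikes/s) or fast (~6 spikes/s) state depending on drive, switchable by
  2-s rate perturbations or by slow OU rate noise.
* ``heterogeneous`` — 200 neurons with normally distributed half-life,
  input-rate, and connectivity parameters, reproducing the co-existing
  in-vivo patterning phenotypes in one network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .analysis import EmptyTrainError
from .network import Heterogeneity, NetworkResult, build_network, simulate_network
from .noise import OUParams, ou_trajectory
from .params import (NetworkParams, bistable_network, signal_generator_network,
                     single_type_network, two_type_network)

__all__ = [
    "Perturbation",
    "ExperimentSpec",
    "run_experiment",
    "connectivity_sweep",
    "signal_generator_sweep",
    "two_type_oscillator",
    "run_bistable",
    "heterogeneous_network",
    "EXPERIMENTS",
]


@dataclass(frozen=True)
class Perturbation:
    """A transient change to the external input rate (a simulated injected
    signal such as CCK or ghrelin): onset and duration in s, size in Hz."""

    onset_s: float
    duration_s: float = 2.0
    delta_hz: float = 50.0


def _offset_from_perturbations(perturbations, n_steps: int, dt: float
                               ) -> np.ndarray | None:
    if not perturbations:
        return None
    offset = np.zeros(n_steps)
    for p in perturbations:
        i0 = int(round(p.onset_s * 1000.0 / dt))
        i1 = int(round((p.onset_s + p.duration_s) * 1000.0 / dt))
        if i1 > n_steps:
            raise ValueError("perturbation extends beyond the run")
        offset[i0:i1] += p.delta_hz
    return offset


def connectivity_sweep(esyn_values=(0.1, 0.3, 0.5, 0.7), cell: str = "slow",
                       n: int = 50, duration_s: float = 500.0,
                       seed: int = 0) -> dict:
    """One network run per connection probability.

    Returns {esyn: {"mean_rate", "isi_hist", "result"}}; the mean rate rises
    monotonically with esyn_1 and the single-neuron ISI histogram of the
    slow-HAP network develops a second (short-interval, doublet) mode at
    high connectivity.
    """
    out = {}
    for esyn in esyn_values:
        params = single_type_network(cell=cell, n=n, esyn_1=esyn)
        res = simulate_network(params, duration_s * 1000.0, seed)
        entry = {"mean_rate": res.mean_rate(t_start=5000.0), "result": res}
        try:
            entry["isi_hist"] = analysis.isi_histogram(res.trains[0])
        except EmptyTrainError:
            entry["isi_hist"] = None
        out[esyn] = entry
    return out


def signal_generator_sweep(i_re_values=(100.0, 130.0, 200.0, 300.0, 450.0, 600.0),
                           n: int = 100, esyn_1: float = 0.35,
                           duration_s: float = 500.0, seed: int = 0) -> dict:
    """Oscillation frequency of the summed activity across input rates."""
    out = {}
    for i_re in i_re_values:
        params = signal_generator_network(i_re=i_re, n=n, esyn_1=esyn_1)
        res = simulate_network(params, duration_s * 1000.0, seed)
        counts = analysis.population_rate(res.trains, binwidth_ms=1.0)
        freq, significant, ratio = analysis.oscillation_frequency(counts)
        out[i_re] = {"frequency_hz": freq, "significant": significant,
                     "peak_ratio": ratio, "mean_rate": res.mean_rate(),
                     "result": res}
    return out


def two_type_oscillator(duration_s: float = 500.0, seed: int = 0,
                        record: tuple = (), **overrides) -> dict:
    """The slow-HAP -> fast-HAP oscillator network.

    Returns the network result split by type plus the generator-population
    oscillation frequency.
    """
    params = two_type_network(**overrides)
    res = simulate_network(params, duration_s * 1000.0, seed, record=record)
    n1 = params.n_type1
    counts1 = analysis.population_rate(res.trains[:n1], binwidth_ms=1.0)
    freq, significant, ratio = analysis.oscillation_frequency(counts1)
    return {
        "params": params,
        "result": res,
        "type1_trains": res.trains[:n1],
        "type2_trains": res.trains[n1:],
        "frequency_hz": freq,
        "significant": significant,
        "peak_ratio": ratio,
    }


def run_bistable(i_re: float = 100.0, duration_s: float = 500.0, seed: int = 0,
                 perturbations: tuple = (), ou: OUParams | None = None,
                 k_dap: float | None = None, esyn_1: float | None = None,
                 threshold_hz: float = 3.0) -> dict:
    """Run the bistable (slow-HAP + DAP) network and segment its states.

    ``k_dap`` / ``esyn_1`` override the published values (used for the
    ablation controls: either mechanism alone fails to sustain the fast
    state).  ``perturbations`` inject transient rate steps; ``ou`` replaces
    the fixed rate with a shared noisy rate of the given mean.
    """
    params = bistable_network(i_re=i_re)
    if k_dap is not None:
        params = params.replace(neuron1=params.neuron1.replace(k_dap=k_dap))
    if esyn_1 is not None:
        params = params.replace(esyn_1=esyn_1)
    dt = params.neuron1.dt
    n_steps = int(round(duration_s * 1000.0 / dt))
    offset = _offset_from_perturbations(perturbations, n_steps, dt)
    if ou is not None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0E]))
        traj = ou_trajectory(ou, n_steps, dt, rng)
        ou_off = traj - params.neuron1.i_re
        offset = ou_off if offset is None else offset + ou_off
    res = simulate_network(params, duration_s * 1000.0, seed,
                           rate_offset=offset)
    counts = analysis.population_rate(res.trains, binwidth_ms=1000.0)
    rate_hz = counts / params.n_total
    segments = analysis.segment_bistable_states(rate_hz, sample_s=1.0,
                                                threshold_hz=threshold_hz)
    return {
        "params": params,
        "result": res,
        "rate_hz": rate_hz,
        "segments": segments,
        "rate_offset": offset,
    }


def heterogeneous_network(n: int = 200, duration_s: float = 2000.0,
                          seed: int = 0,
                          lambda_hap_mean: float = 40.0,
                          lambda_hap_sd: float = 20.0,
                          i_re_mean: float = 150.0, i_re_sd: float = 45.0,
                          esyn_mean: float = 0.12, esyn_sd: float = 0.15
                          ) -> dict:
    """Randomly heterogeneous slow-HAP network.

    Per-neuron lambda_HAP, I_re and esyn_1 are normal draws; lambda_HAP is
    clamped to the 2-ms physiological lower bound and I_re at 0, while
    esyn_1 <= 0 is kept as drawn and means "receives no network input"
    (such neurons still project).  Returns per-neuron ISI histograms (None
    for cells with < 2 spikes, reported as silent).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    lam = np.clip(rng.normal(lambda_hap_mean, lambda_hap_sd, n), 2.0, None)
    ire = np.clip(rng.normal(i_re_mean, i_re_sd, n), 0.0, None)
    esyn = rng.normal(esyn_mean, esyn_sd, n)
    params = single_type_network(cell="slow", n=n, esyn_1=min(esyn_mean, 1.0))
    het = Heterogeneity(lambda_hap=lam, i_re=ire, esyn_recv=esyn)
    res = simulate_network(params, duration_s * 1000.0, seed,
                           heterogeneity=het)
    hists = []
    silent = []
    for i, tr in enumerate(res.trains):
        try:
            hists.append(analysis.isi_histogram(tr))
        except EmptyTrainError:
            hists.append(None)
            silent.append(i)
    return {
        "result": res,
        "heterogeneity": het,
        "isi_hists": hists,
        "silent": silent,
    }


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experiment plus keyword options, the unit of CLI dispatch."""

    name: str
    options: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; "
                f"known: {sorted(EXPERIMENTS)}")


EXPERIMENTS = {
    "connectivity_sweep": connectivity_sweep,
    "signal_generator": signal_generator_sweep,
    "two_type_oscillator": two_type_oscillator,
    "bistable": run_bistable,
    "heterogeneous": heterogeneous_network,
}


def run_experiment(spec: ExperimentSpec) -> dict:
    """Dispatch a named experiment; deterministic per (spec, seed)."""
    fn = EXPERIMENTS[spec.name]
    return fn(seed=spec.seed, **spec.options)
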