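# vmnnet

A spiking-network model of the ventromedial nucleus of the hypothalamus
(VMN), for computational neuroscientists studying how heterogeneous spike
patterning, slow rhythms, and bistable state switching can emerge from a
purely excitatory recurrent network of simple neurons.

The VMN is densely interconnected and almost entirely glutamatergic, yet
its neurons display in vivo a zoo of spike-patterning phenotypes — random,
regular, long-tailed, doublet-firing, oscillatory, and bistable cells.
This package implements the modelling toolchain that explains that zoo
with minimal ingredients:

* a **modified integrate-and-fire neuron** driven by Poisson EPSP/IPSP
  input, with cumulative post-spike potentials — a large brief
  hyperpolarising afterpotential (HAP), an optional slow
  afterhyperpolarisation (AHP), and an optional slow depolarising
  afterpotential (DAP):

      V = V_rest + V_syn − HAP − AHP + DAP,
      dX/dt = −X/τ_X + k_X δ(spike)      for X ∈ {HAP, AHP, DAP}

  with no post-spike reset, so the slow potentials accumulate;
* **random excitatory networks** with unreliable (P = 0.5) delayed
  (5–15 ms) synaptic transmission between one or two cell types;
* **spike-pattern statistics** — ISI histograms, hazard functions, and the
  index of dispersion (IoD = variance/mean of binned spike counts) across
  binwidths 0.5–10 s — plus population-rate, spectral, spike-triggered
  average, cross-correlogram, and bistable-state segmentation tools;
* a **genetic-algorithm fitter** that recovers neuron parameters from
  spike-pattern statistics with a weighted four-component score;
* **scripted experiments** reproducing the emergent phenomena: doublet
  firing with rising connectivity, a ~2–6 Hz population rhythm generator,
  a two-cell-type oscillator with multimodal "oscillatory"-cell ISIs, and
  a DAP-dependent bistable network switchable by 2-s input perturbations.

## Worked example

Simulate the published bistable network (100 slow-HAP neurons with a DAP,
`esyn_1 = 0.25`) just above its switching threshold and watch a 2-s input
pulse flip it between self-sustained states:

```python
from vmnnet.experiments import Perturbation, run_bistable

out = run_bistable(i_re=100.0, duration_s=300.0, seed=2,
                   perturbations=(Perturbation(onset_s=60.0, delta_hz=50.0),
                                  Perturbation(onset_s=200.0, delta_hz=-50.0)))
for t0, t1, state in out["segments"]:
    rate = out["rate_hz"][int(t0):int(t1)].mean()
    print(f"{state:>4}  {t0:5.0f}-{t1:5.0f} s   {rate:.2f} spikes/s")
```

prints

```
slow      0-   61 s   0.97 spikes/s
fast     61-  201 s   5.29 spikes/s
slow    201-  300 s   1.00 spikes/s
```

The network rests at ~0.9 spikes/s per neuron; the +50-Hz pulse at 60 s
ignites a fast state (~6 spikes/s) that self-sustains for minutes through
the combined positive feedback of the DAP and the recurrent excitation;
the −50-Hz pulse at 200 s switches it back.  Removing either mechanism
(`k_dap=0.0` or `esyn_1=0.0`) abolishes the sustained fast state.

Each `examples/` script exercises one capability the same way — single
neuron phenotypes, network rhythm generation, the two-cell-type
oscillator, GA fitting, and spike-train analysis — and prints what the
numbers mean.  A thin CLI wraps the same functions
(`vmnnet experiment bistable --seed 2`, `vmnnet analyze --in spikes.txt`,
`vmnnet fit --target spikes.txt --mode HAP`, ...).

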