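# Methods

## The neuron model

Each cell is a leaky integrate-and-fire unit whose membrane potential is
assembled additively from a resting potential, a synaptic component, and up
to three cumulative post-spike potentials:

    V(t) = V_rest + V_syn(t) − HAP(t) − AHP(t) + DAP(t)

`V_syn` integrates fixed-amplitude EPSPs (`e_h` = 3 mV) and IPSPs
(`i_h` = −3 mV) arriving as two independent Poisson streams with rates
`I_re` and `I_ratio · I_re`, and decays with half-life `lambda_syn`
(7.5 ms).  When `V ≥ V_thresh` outside the 2-ms absolute refractory period
a spike is emitted (the waveform is not modelled) and each post-spike
potential is incremented by its per-spike amplitude `k`:

* **HAP** (hyperpolarising afterpotential) — large and brief (defaults
  30 mV, half-life 8 ms); produces the relative refractory period that
  dominates the ISI distribution's left edge.
* **AHP** (afterhyperpolarisation) — small and slow (≤ 5 mV, half-lives of
  hundreds of ms); activity-dependent negative feedback that pushes the
  index of dispersion (IoD) of firing rate below 1 at long binwidths.
* **DAP** (depolarising afterpotential) — slow positive feedback that makes
  cells burstier, raising the IoD at long binwidths.

Nothing is reset at a spike, so the slow potentials accumulate across
interspike intervals — this accumulation is what lets a DAP plus recurrent
excitation sustain a network state.

### Integration convention

The state variables decay per 1-ms step by the forward-Euler factor
`(1 − dt/τ)` of the underlying differential form, with `τ = λ/ln 2`; inputs
are then added to `V_syn` and the increments applied after the threshold
test, so a spike's own afterpotentials act from the next step.  We chose
Euler over the exact factor `exp(−dt/τ)` deliberately: the two differ by
under 1 % per step, but the network operating points are fluctuation-driven
and knife-edge sensitive, and only the Euler convention reproduces the
published bistable behaviour quantitatively (slow state ≈ 0.9 spikes/s at
I_re = 100 Hz, switching near 105, fast ≈ 6.3 at 110).  With exact decay
the same network is a few Hz of I_re more excitable and escapes the slow
state at 100 Hz.  The exact factor remains available
(`NeuronParams(exact_decay=True)`) and is the right choice when
dt-independent half-life semantics matter more than matching the published
operating points; at dt → 0 the two conventions converge.

Spike times are stamped at the end of the step in which threshold is
crossed, `t = (step+1)·dt`, so a train over a run of length `T` lies in
`(0, T]`.  At `t = 0`, `V_syn` starts at 0 and the three post-spike
potentials start at their `k` amplitudes; statistics routines discard an
initial transient (5 s in the fitting pipeline) before summarising.

The threshold test uses `V ≥ V_thresh` (measure-zero difference from `>`
under Poisson drive).  `dt` is configurable down to 0.1 ms; all defaults
are for 1 ms.

## The network model

Populations of these neurons are wired by static random directed excitatory
connections: each ordered type-1→type-1 pair becomes an edge independently
with probability `esyn_1`, type-1→type-2 pairs with `esyn_12`; no
self-connections; type-2 cells never project.  Every spike triggers, per
outgoing edge, an independent Bernoulli(0.5) transmission trial; successful
deliveries arrive after the edge's frozen delay, uniform in
`[delta_min, delta_min + delta_range]` (usually 5–15 ms), implemented as a
per-neuron 20-ms ring-buffer queue at dt resolution.  The queue head count
`n_n` yields the network input `I_net = synweight_1 · k_syn · n_n`
(3-mV EPSPs, linear summation within a step) which joins the external input
in `V_syn`.  Per-event delay redraws are available
(`NetworkParams(per_event_delay=True)`) and change nothing statistically.

Delay steps are rounded to the grid and clipped to ≥ 1 step, so a neuron
never receives a spike in the step it was fired — the update is fully
synchronous.

Each neuron draws its external input from its own independent, seedable
stream (numpy `SeedSequence` spawning); transmission trials use a separate
compiled-RNG stream seeded from the same master seed.  Identical
(parameters, duration, seed) therefore give bit-identical spike output.

## Noisy drive

For slow rate fluctuations the EPSP rate becomes an Ornstein–Uhlenbeck
variable, `dI_re = ((μ − I_re)/τ) dt + k √dt g`, Euler–Maruyama with dt in
seconds, clamped at 0 Hz.  The amplitude may be absolute (Hz/√s) or a
fraction of the mean; the fractional reading is the default because, at the
documented setting (mean 100 Hz, τ = 120 s, amp = 0.05), it is the
interpretation that produces spontaneous switching of the bistable network
within a 2000-s run.  The OU trajectory is a single shared signal applied
to every neuron's rate: coherent slow excursions are what move the network
between states; independent per-neuron noise of this size would average out
across 100 cells.

## Spike-pattern statistics

* **ISI histogram** — intervals in 5-ms bins (10-ms for display);
  optionally normalised so counts total 10000, making records of different
  length comparable.
* **Hazard function** — `h[b] = count[b] / N(ISI > left edge of b)`, the
  conditional firing probability per bin given survival; undefined bins
  (zero denominator) are flagged.
* **IoD range** — variance/mean (sample variance, ddof = 1) of spike counts
  in successive bins, over binwidths 0.5–10 s, bins tiling from t = 0 with
  a trailing partial bin discarded.  Poisson spiking gives 1 at every
  timescale; regularity < 1; clustering > 1 rising with binwidth.  Note the
  estimator's own null sampling error: with n count bins,
  `IoD·(n−1) ~ χ²(n−1)`, so a 1000-s record at the 10-s binwidth has
  SD ≈ 0.14 — tests and tolerance checks account for this rather than
  expecting 1.0 ± a few percent from a single record.
* **Population tools** — summed 1-ms counts; a simulated downstream
  postsynaptic trace (exponential-kernel filtering of the summed counts);
  spike-triggered averages of recorded voltage; cross-correlograms; the
  dominant population frequency (Welch periodogram, 50-s segments, half
  overlap, peak in 0.5–20 Hz, flagged significant when ≥ 4× the band's
  median power); and a two-state slow/fast segmentation of the smoothed
  (10-s window) mean rate with a 3-spikes/s threshold — the geometric
  midpoint of the two published state rates (0.85 and ~6 spikes/s) — and a
  10-s minimum state duration.
* **ISI mode detection** — peaks of the lightly smoothed (5-bin moving
  average) histogram with 150-ms minimum separation; the late-mode spacing
  statistic restricts to the well-populated 100–1000 ms range.  For
  populations of statistically identical cells the per-type pooled
  histogram gives the same modal structure with far less tail noise than a
  single cell, and the reproduction script uses the pooled form.

## Genetic-algorithm fitting

Candidates are parameter vectors within physiological bounds (I_re
100–2000 Hz; k_HAP 0–100 mV, λ_HAP 2–100 ms; k_AHP 0–5 mV, λ_AHP
50–1500 ms; k_DAP 0–10 mV, λ_DAP 20–2000 ms), in one of three modes: HAP
only, HAP+AHP, HAP+DAP.  Each candidate is simulated (default 1000 s),
summarised, and scored against the target by

    score = 200·D(ISI head) + 100·D(ISI tail) + 100·D(hazard) + 100·D(IoD range)

where D is the mean absolute difference per bin (squared-difference
optional), the ISI head/tail ranges default to 5-ms bin indices 0–50 and
50–200 (0–250 ms and 250–1000 ms), and hazard bins are masked where either
summary has fewer than 20 surviving intervals.  Components are normalised
by bin count (means, not sums), and each D is expressed relative to the
target's mean magnitude over its range.  The relative form matters: in raw
units the normalised-to-10000 ISI counts dwarf hazard probabilities and
IoD values by orders of magnitude, leaving three of the four weighted
components numerically inert — with it, all four steer the search and the
weights mean what they say.  Raw-units scoring remains available
(`GAConfig(relative_distance=False)`).

Selection is truncation (best 32 of 128 by default); children are uniform
per-parameter crossovers of two distinct random parents with
probability-0.05 per-parameter mutation (uniform redraw in bounds); the
best candidate is copied unchanged, so the best score is non-increasing.
Candidate evaluations are seeded from (run seed, generation, index) and are
exactly reproducible.  The consensus protocol repeats the GA with distinct
seeds and takes per-parameter medians of the best runs (library default
20 runs/best 5; the published protocol's 100/10 is a config choice).

Score realisation noise still matters at desk scale: resimulating the true
parameters of a ~5-spikes/s target with a fresh seed moves the total score
by roughly its noise floor (~140 score units in relative D for a 500-s
target), so scores near that floor are equivalent.  Component-level
comparisons between fits (e.g. that the HAP+DAP mode matches a rising IoD
range better than HAP alone) are most cleanly made by re-scoring each
winner on fresh common-seed resimulations, which removes the winners' own
evaluation-seed luck from the comparison.

## Synthetic fixtures

The generator module supplies trains with known structure for testing the
statistics: homogeneous Poisson (exponential ISIs, IoD 1), perfectly
regular, gamma renewal, alternating silent/active burst epochs (IoD ≫ 1
rising below the epoch period), and sinusoid-modulated inhomogeneous
Poisson via exact thinning.  These emulate patterning regimes, not real
recordings: they have no refractoriness (except as built into their ISI
law), no nonstationarity, and no measurement artifacts, so passing tests
validates the statistics and simulator mechanics, not in-vivo realism.

## Problem sizes and reproduction

The library defaults match the published configurations (Tables of neuron,
network, and GA parameters).  The reproduction script and the test suite
run the stated network experiments at 500-s duration and 100–200 neurons —
the scale at which the published operating values are quoted — and use
shortened GA protocols where full fitting runs are not the quantity under
test.  One documented discrepancy: the single-cell-type rhythm generator's
frequency-vs-input curve matches in shape and at its high end (~6 Hz at
I_re = 600 Hz) but its low-drive coherence onset sits ~20 Hz of I_re lower
than published, so at I_re = 130 Hz this implementation already cycles at
~3.2 Hz rather than the onset value of 2.3 Hz (which it shows near
I_re = 110).  The onset of fluctuation-ignited coherence is the single most
discretisation-sensitive quantity in the model; the bistable network's
operating points, which constrain the same conventions far more tightly,
are reproduced.

Two-cell-type network parameter note: the published description gives the
type-1 input rate as 200 Hz in the text but 180 Hz in the parameter table;
we default to the table value.

## Known limitations

* No inhibitory intra-network synapses, no plasticity, no spatial
  structure, no conductance-based dynamics — by design, matching the model
  being reimplemented.
* Network-level GA fitting is not provided (the published attempt was
  reported not robust); network matches are scripted through the
  experiments module.
* Heterogeneous-network draws clamp λ_HAP at its 2-ms physiological lower
  bound and rates at 0; receivers drawn with esyn ≤ 0 take no network input
  but still project.
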