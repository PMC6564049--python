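"""Recovering neuron parameters from spike statistics with the GA.

A synthetic target is made from known HAP-only parameters; the genetic
algorithm then searches the physiological parameter box using only the
target's ISI histogram, hazard function, and IoD range.  A reduced
protocol (population 32, 12 generations, 250-s evaluations) already
recovers the dominant parameters.
"""

from vmnnet import NeuronParams, compute_summary, simulate_single
from vmnnet.fitting import GAConfig, ga_run

truth = NeuronParams(i_re=300.0, k_hap=30.0, lambda_hap=8.0)
train, _ = simulate_single(truth, 500_000.0, seed=42)
target = compute_summary(train, discard_ms=5000.0)
print(f"target: {target.mean_rate:.2f} spikes/s, "
      f"{target.isi.n_intervals} intervals")

config = GAConfig(run_time_s=250.0, population=32, parents=8, generations=12)
result = ga_run(target, config, seed=7, mode="HAP")

print(f"best score {result.score:.1f} (0 = identical summaries)")
print(f"{'parameter':>12} {'true':>8} {'fitted':>8}")
for name, true_val in (("i_re", 300.0), ("k_hap", 30.0), ("lambda_hap", 8.0)):
    print(f"{name:>12} {true_val:8.1f} {result.best.values[name]:8.1f}")
print()
print("The HAP half-life (lambda_hap) controls the refractory shoulder of")
print("the ISI histogram and is the best-constrained parameter; input rate")
print("and HAP amplitude trade off against each other along a score ridge.")
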