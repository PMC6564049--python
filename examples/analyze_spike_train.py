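"""Spike-train analysis round trip through the text-file interface.

Simulates a bursty DAP neuron, writes its spikes to the plain
one-time-per-line text format (0.1-ms resolution, as recorded data), reads
them back, and prints the summary statistics used for phenotyping and
model fitting.
"""

import tempfile
from pathlib import Path

import numpy as np

from vmnnet import NeuronParams, simulate_single
from vmnnet.analysis import compute_summary
from vmnnet.io import read_spike_file, write_spike_file, write_summary_tables

params = NeuronParams(i_re=250.0, k_hap=20.0, lambda_hap=40.0,
                      k_dap=0.8, lambda_dap=1000.0)
train, _ = simulate_single(params, 600_000.0, seed=3)

with tempfile.TemporaryDirectory() as tmp:
    spike_path = Path(tmp) / "spikes.txt"
    write_spike_file(spike_path, train)
    back = read_spike_file(spike_path, unit="ms")
    summary = compute_summary(back, discard_ms=5000.0)
    tables = write_summary_tables(Path(tmp) / "summary", summary)
    print(f"round-tripped {back.n} spikes, mean rate "
          f"{summary.mean_rate:.2f} spikes/s")
    print(f"ISI histogram mode: "
          f"{summary.isi.bin_centres[np.argmax(summary.isi.counts)]:.1f} ms")
    print("IoD range (0.5s ... 10s):", np.round(summary.iod.values, 2))
    print("wrote:", ", ".join(p.name for p in tables))

print()
print("The rising IoD range (variance/mean of counts growing with binwidth)")
print("is the burstiness signature of the slow DAP; it is invisible to the")
print("ISI histogram and hazard alone.")
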