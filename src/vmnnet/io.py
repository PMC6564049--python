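"""Readers and writers: spike-time text files, structured configs, and
delimited summary tables.

Spike files hold one event time per line, no header.  The internal unit is
milliseconds; seconds-dialect files are converted on read.  Recorded data of
this kind carries 0.1-ms resolution, which a plain decimal round-trip
preserves.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import PatternSummary
from .params import NetworkParams, NeuronParams
from .spiketrain import SpikeTrain

__all__ = [
    "read_spike_file",
    "write_spike_file",
    "neuron_from_config",
    "network_from_config",
    "load_config",
    "save_config",
    "summary_tables",
    "write_summary_tables",
]

# config keys use the field's symbol names; internal attribute names differ
# only in case
_NEURON_KEYS = {
    "I_re": "i_re", "I_ratio": "i_ratio", "e_h": "e_h", "i_h": "i_h",
    "lambda_syn": "lambda_syn", "k_HAP": "k_hap", "lambda_HAP": "lambda_hap",
    "k_AHP": "k_ahp", "lambda_AHP": "lambda_ahp", "k_DAP": "k_dap",
    "lambda_DAP": "lambda_dap", "V_rest": "v_rest", "V_thresh": "v_thresh",
    "t_refabs": "t_refabs", "dt": "dt", "init_at_k": "init_at_k",
}
_NETWORK_KEYS = {
    "vmn1": "n_type1", "vmn2": "n_type2", "esyn_1": "esyn_1",
    "esyn_12": "esyn_12", "synweight_1": "synweight_1",
    "syntrans": "syntrans", "delta_min": "delta_min",
    "delta_range": "delta_range", "k_syn": "k_syn",
    "per_event_delay": "per_event_delay",
}


def read_spike_file(path, unit: str = "auto") -> SpikeTrain:
    """Read a spike-time text file (one time per line) into ms.

    ``unit`` is "ms", "s", or "auto" (magnitude heuristic: a maximum time
    under 5000 is taken as seconds — prefer an explicit unit when known).
    Unsorted or negative times raise a validation error naming the
    offending lines.
    """
    times = []
    bad_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                t = float(line)
            except ValueError:
                bad_lines.append(f"line {lineno}: unparseable {line!r}")
                continue
            if t < 0:
                bad_lines.append(f"line {lineno}: negative time {t}")
            elif times and t <= times[-1][1]:
                bad_lines.append(f"line {lineno}: time {t} not increasing")
            times.append((lineno, t))
    if bad_lines:
        raise ValueError("invalid spike file:\n" + "\n".join(bad_lines))
    arr = np.array([t for _, t in times], dtype=float)
    if unit == "auto":
        unit = "s" if (arr.size and arr.max() < 5000.0) else "ms"
    if unit == "s":
        arr = arr * 1000.0
    elif unit != "ms":
        raise ValueError(f"unknown unit {unit!r}")
    duration = max(float(arr[-1]), 1.0) if arr.size else 1.0
    return SpikeTrain(arr, duration)


def write_spike_file(path, train: SpikeTrain, unit: str = "ms") -> None:
    """Write one spike time per line at 0.1-ms precision."""
    scale = 1.0 if unit == "ms" else 0.001
    if unit not in ("ms", "s"):
        raise ValueError(f"unknown unit {unit!r}")
    decimals = 1 if unit == "ms" else 4
    with open(path, "w") as fh:
        for t in train.times:
            fh.write(f"{t * scale:.{decimals}f}\n")


def neuron_from_config(cfg: dict) -> NeuronParams:
    """Build neuron parameters from a symbol-name config mapping."""
    kwargs = {}
    for key, value in cfg.items():
        if key not in _NEURON_KEYS:
            raise KeyError(f"unknown neuron parameter {key!r}")
        kwargs[_NEURON_KEYS[key]] = value
    return NeuronParams(**kwargs)


def network_from_config(cfg: dict) -> NetworkParams:
    """Build network parameters from a config mapping.

    Neuron blocks live under ``neuron1`` / ``neuron2`` (symbol names);
    remaining keys use the network symbol names (vmn1, esyn_1, ...).
    """
    cfg = dict(cfg)
    kwargs = {}
    if "neuron1" in cfg:
        kwargs["neuron1"] = neuron_from_config(cfg.pop("neuron1"))
    if "neuron2" in cfg:
        kwargs["neuron2"] = neuron_from_config(cfg.pop("neuron2"))
    for key, value in cfg.items():
        if key not in _NETWORK_KEYS:
            raise KeyError(f"unknown network parameter {key!r}")
        kwargs[_NETWORK_KEYS[key]] = value
    return NetworkParams(**kwargs)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, cfg: dict) -> None:
    """Serialise a resolved config next to its outputs for reproducibility."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def neuron_to_config(params: NeuronParams) -> dict:
    return {sym: getattr(params, attr) for sym, attr in _NEURON_KEYS.items()}


def network_to_config(params: NetworkParams) -> dict:
    cfg = {k: getattr(params, v) for k, v in _NETWORK_KEYS.items()}
    cfg["neuron1"] = neuron_to_config(params.neuron1)
    if params.neuron2 is not None:
        cfg["neuron2"] = neuron_to_config(params.neuron2)
    return cfg


def summary_tables(summary: PatternSummary) -> dict[str, pd.DataFrame]:
    """Delimited-table views of a pattern summary (bin, value per row)."""
    isi = pd.DataFrame({
        "bin_left_ms": summary.isi.bin_left_edges,
        "count": summary.isi.counts,
        "normalised": summary.isi.normalised,
    })
    haz = pd.DataFrame({
        "bin_left_ms": summary.isi.bin_left_edges,
        "hazard": summary.hazard.values,
        "survivors": summary.hazard.survivors,
        "valid": summary.hazard.valid,
    })
    iod = pd.DataFrame({
        "binwidth_s": list(summary.iod.binwidths_s),
        "iod": summary.iod.values,
    })
    return {"isi": isi, "hazard": haz, "iod": iod}


def write_summary_tables(outdir, summary: PatternSummary,
                         prefix: str = "summary") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in summary_tables(summary).items():
        path = outdir / f"{prefix}_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
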