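"""Result files, provenance and optional figure-style outputs.

CSV is the canonical output; every file is accompanied by a provenance
JSON embedding the experiment seed, the full parameter set and a content
hash of each group's model spec, so any results file can be traced back to
the exact configuration that produced it. Plotting needs matplotlib (the
``plot`` extra) and is headless-safe.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .paradigms import ExperimentSpec, RunResult

__all__ = ["spec_hash", "provenance", "write_results", "write_trace",
           "plot_trace", "plot_weight_history"]


def spec_hash(spec) -> str:
    """Stable content hash of a model spec (first 12 hex digits of SHA-256)."""
    payload = yaml.safe_dump(spec.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance(exp: ExperimentSpec) -> dict:
    g0 = exp.groups[0].spec
    return {
        "experiment": exp.name,
        "seed": exp.seed,
        "n_trials": exp.n_trials,
        "network_params": asdict(g0.network),
        "learning_params": asdict(g0.learning),
        "weight_defaults": asdict(g0.defaults),
        "model_spec_hashes": {g.name: spec_hash(g.spec) for g in exp.groups},
    }


def write_results(exp: ExperimentSpec, result: RunResult, outdir: str | Path) -> Path:
    """Write ``<experiment>_results.csv`` + provenance JSON; returns the CSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{exp.name}_results.csv"
    result.summaries.to_csv(csv_path, index=False, float_format="%.6f")
    meta = provenance(exp)
    meta["summaries"] = result.summaries.to_dict(orient="records")
    (outdir / f"{exp.name}_provenance.json").write_text(json.dumps(meta, indent=2))
    for name, hist in result.weight_history.items():
        hist.to_csv(outdir / f"{exp.name}_{name}_weights.csv", index=False,
                    float_format="%.6f")
    return csv_path


def write_trace(trace_frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace_frame.to_csv(path, index=False, float_format="%.6f")
    return path


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_trace(trace_frame: pd.DataFrame, units: list[str] | None = None,
               path: str | Path = "trace.png",
               threshold: float | None = None) -> Path:
    """Activation time courses of selected (default: all coding) units."""
    plt = _mpl()
    df = trace_frame
    if units is None:
        units = [u for u in df.unit_id.unique() if not u.endswith(":inh")]
    fig, ax = plt.subplots(figsize=(7, 4))
    for u in units:
        sub = df[df.unit_id == u]
        ax.plot(sub.cycle, sub.activation, label=u)
    if threshold is not None:
        ax.axhline(threshold, ls="--", c="k", lw=0.8, label="response threshold")
    ax.set_xlabel("cycle")
    ax.set_ylabel("activation")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_weight_history(history: pd.DataFrame, path: str | Path = "weights.png",
                        min_final: float = 0.05) -> Path:
    """Plastic-weight trajectories over learning trials (pairs ending above min_final)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 4))
    for (src, dst), sub in history.groupby(["src", "dst"]):
        if sub.weight.iloc[-1] >= min_final:
            ax.plot(sub.trial, sub.weight, label=f"{src}->{dst}")
    ax.set_xlabel("learning trial")
    ax.set_ylabel("association weight")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
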