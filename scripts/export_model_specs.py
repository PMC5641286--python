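"""Regenerate the shipped YAML model specs from the paradigm constructors."""
from pathlib import Path

from tecsim import experiment_spec
from tecsim.paradigms import EXPERIMENTS

out = Path(__file__).resolve().parents[1] / "src" / "tecsim" / "modelspecs"
out.mkdir(exist_ok=True)
for name in sorted(EXPERIMENTS):
    exp = experiment_spec(name)
    for group in exp.groups:
        stem = name if len(exp.groups) == 1 else f"{name}_{group.name}"
        group.spec.save(out / f"{stem}.yaml")
        print("wrote", out / f"{stem}.yaml")
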