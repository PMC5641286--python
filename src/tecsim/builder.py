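"""Declarative model specs and network construction.

A :class:`ModelSpec` describes one model instance: its layers and codes,
the hand-set sensory<->feature wiring (bottom-up voltage-independent, top-down
voltage-dependent), a task instruction, and the action-effect schedule used
by the learning phase. ``build_model`` turns a spec into a runnable
:class:`~tecsim.network.LayeredNetwork`, auto-generating the paired
inhibitory units, the within-layer competition edges, and a dense set of
plastic feature->motor connections initialised at zero — the model starts
task-capable but action-ignorant.

Task instructions are internalised as plain bidirectional excitatory wiring
between feature codes and generic task codes (T1, T2, ...): for every rule
``stimulus features -> task code -> response features`` each referenced
feature is connected to the task code in both directions, with separate
default weights for the feature->task and task->feature directions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .network import (
    Connection,
    ConnectionKind,
    Layer,
    LayeredNetwork,
    Unit,
    INHIB_SUFFIX,
)
from .params import LearningParams, NetworkParams, _from_mapping

__all__ = [
    "WeightDefaults",
    "SensoryFeatureLink",
    "TaskRule",
    "TaskInstruction",
    "ModelSpec",
    "build_model",
    "internalize_task",
    "diff_models",
    "ModelDiff",
]


@dataclass(frozen=True)
class WeightDefaults:
    """Hand-set default connection weights, overridable per edge."""

    sensory_feature: float = 0.5063   # bottom-up VI
    feature_sensory: float = 0.9098   # top-down VD
    feature_task: float = 0.7195      # stimulus feature -> task VI
    task_feature: float = 0.9437      # task -> feature VI (both roles)
    response_task: float = 0.2633    # response feature -> task VI (weak back edge)


@dataclass(frozen=True)
class SensoryFeatureLink:
    """One sensory<->feature pairing; None weights fall back to defaults."""

    sensory: str
    feature: str
    w_up: float | None = None      # sensory -> feature (VI)
    w_down: float | None = None    # feature -> sensory (VD)


@dataclass(frozen=True)
class TaskRule:
    """stimulus feature codes -> task code -> response feature codes."""

    stimulus: tuple[str, ...]
    task: str
    response: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "stimulus", tuple(self.stimulus))
        object.__setattr__(self, "response", tuple(self.response))


@dataclass(frozen=True)
class TaskInstruction:
    """Task rules plus optional overrides of the three task-edge weights.

    Feature<->task wiring is bidirectional but directional in strength:
    stimulus features drive their task code strongly (``w_feature_task``),
    the task code drives its stimulus and response features top-down
    (``w_task_feature``), and response features support their task code
    through a weaker reciprocal edge (``w_response_task``) — the
    instruction's condition is strong evidence for a task option, its
    consequence only weak evidence.
    """

    rules: tuple[TaskRule, ...]
    w_feature_task: float | None = None
    w_task_feature: float | None = None
    w_response_task: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(
            r if isinstance(r, TaskRule) else TaskRule(**r) for r in self.rules))

    def referenced_codes(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out.update(r.stimulus)
            out.add(r.task)
            out.update(r.response)
        return out


@dataclass
class ModelSpec:
    """Declarative description of one model instance."""

    name: str
    layers: list[Layer]
    links: list[SensoryFeatureLink]
    task: TaskInstruction | None = None
    effects: dict[str, list[str]] = field(default_factory=dict)
    network: NetworkParams = field(default_factory=NetworkParams)
    learning: LearningParams = field(default_factory=LearningParams)
    defaults: WeightDefaults = field(default_factory=WeightDefaults)

    # -- validation -------------------------------------------------------

    def codes_by_level(self, level: str) -> list[str]:
        return [c for l in self.layers if l.level == level for c in l.codes]

    def validate(self) -> None:
        problems: list[str] = []
        if not self.layers:
            problems.append("spec declares no layers")
        seen: set[str] = set()
        for l in self.layers:
            if l.level not in ("sensory", "feature", "task", "motor"):
                problems.append(f"layer {l.name!r} has unknown level {l.level!r}")
            for c in l.codes:
                if c in seen:
                    problems.append(f"duplicate code name {c!r}")
                seen.add(c)
        sensory = set(self.codes_by_level("sensory"))
        feature = set(self.codes_by_level("feature"))
        task = set(self.codes_by_level("task"))
        motor = set(self.codes_by_level("motor"))
        if not motor:
            problems.append("spec declares no motor codes")
        for link in self.links:
            if link.sensory not in sensory:
                problems.append(f"link references unknown sensory code {link.sensory!r}")
            if link.feature not in feature:
                problems.append(f"link references unknown feature code {link.feature!r}")
        if self.task is not None:
            for r in self.task.rules:
                if r.task not in task:
                    problems.append(f"task rule references unknown task code {r.task!r}")
                for f in (*r.stimulus, *r.response):
                    if f not in feature:
                        problems.append(f"task rule references unknown feature code {f!r}")
        for m, eff in self.effects.items():
            if m not in motor:
                problems.append(f"effect schedule references unknown motor code {m!r}")
            for s in eff:
                if s not in sensory:
                    problems.append(f"effect of {m!r} references unknown sensory code {s!r}")
        for m in motor:
            if m not in self.effects:
                problems.append(f"motor code {m!r} missing from the effect schedule")
        if problems:
            raise ValueError("invalid model spec:\n  " + "\n  ".join(problems))

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "layers": [{"name": l.name, "level": l.level, "codes": list(l.codes)}
                       for l in self.layers],
            "links": [{k: v for k, v in asdict(l).items() if v is not None}
                      for l in self.links],
            "effects": {m: list(e) for m, e in self.effects.items()},
            "defaults": asdict(self.defaults),
            "network": asdict(self.network),
            "learning": asdict(self.learning),
        }
        if self.task is not None:
            t: dict = {"rules": [{"stimulus": list(r.stimulus), "task": r.task,
                                  "response": list(r.response)} for r in self.task.rules]}
            if self.task.w_feature_task is not None:
                t["w_feature_task"] = self.task.w_feature_task
            if self.task.w_task_feature is not None:
                t["w_task_feature"] = self.task.w_task_feature
            if self.task.w_response_task is not None:
                t["w_response_task"] = self.task.w_response_task
            d["task"] = t
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        known = {"name", "layers", "links", "task", "effects", "defaults",
                 "network", "learning"}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown model-spec sections: {', '.join(unknown)}")
        task = None
        if d.get("task") is not None:
            t = dict(d["task"])
            task = TaskInstruction(
                rules=tuple(TaskRule(tuple(r["stimulus"]), r["task"], tuple(r["response"]))
                            for r in t.pop("rules")),
                w_feature_task=t.pop("w_feature_task", None),
                w_task_feature=t.pop("w_task_feature", None),
                w_response_task=t.pop("w_response_task", None),
            )
            if t:
                raise ValueError(f"unknown task keys: {sorted(t)}")
        return cls(
            name=d["name"],
            layers=[Layer(l["name"], l["level"], tuple(l["codes"])) for l in d["layers"]],
            links=[SensoryFeatureLink(**l) for l in d.get("links", [])],
            task=task,
            effects={m: list(e) for m, e in (d.get("effects") or {}).items()},
            defaults=_from_mapping(WeightDefaults, dict(d.get("defaults") or {})),
            network=_from_mapping(NetworkParams, dict(d.get("network") or {})),
            learning=_from_mapping(LearningParams, dict(d.get("learning") or {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)


# -- construction ----------------------------------------------------------

def _inh_id(code: str) -> str:
    return code + INHIB_SUFFIX


def build_model(spec: ModelSpec) -> LayeredNetwork:
    """Construct the runnable network for a spec (deterministic, idempotent).

    Generates per excitatory code one paired inhibitory unit, the
    within-layer competition edges, the hand-set sensory<->feature wiring
    and a dense zero-weight plastic feature->motor matrix; finally applies
    the spec's task instruction, if any.
    """
    spec.validate()
    units: list[Unit] = []
    connections: list[Connection] = []
    p = spec.network
    for layer in spec.layers:
        for code in layer.codes:
            units.append(Unit(code, layer.name,
                              is_sensory=layer.level == "sensory",
                              is_motor=layer.level == "motor"))
            units.append(Unit(_inh_id(code), layer.name, polarity="inhibitory"))
    # lateral competition: e -> paired inhibitory -> every competitor
    for layer in spec.layers:
        for code in layer.codes:
            connections.append(Connection(code, _inh_id(code), p.w_exc_inh,
                                          ConnectionKind.PAIR))
            for other in layer.codes:
                if other != code:
                    connections.append(Connection(_inh_id(code), other, p.w_inh,
                                                  ConnectionKind.INH))
    # hand-set sensory<->feature wiring
    d = spec.defaults
    for link in spec.links:
        w_up = d.sensory_feature if link.w_up is None else link.w_up
        w_down = d.feature_sensory if link.w_down is None else link.w_down
        connections.append(Connection(link.sensory, link.feature, w_up, ConnectionKind.VI))
        connections.append(Connection(link.feature, link.sensory, w_down, ConnectionKind.VD))
    # dense plastic feature -> motor matrix at zero
    for f in spec.codes_by_level("feature"):
        for m in spec.codes_by_level("motor"):
            connections.append(Connection(f, m, 0.0, ConnectionKind.LEARNED))
    net = LayeredNetwork(spec.layers, units, connections, p)
    net.spec = spec  # provenance back-reference
    if spec.task is not None:
        internalize_task(net, spec.task, spec.defaults)
    return net


def internalize_task(
    net: LayeredNetwork,
    instruction: TaskInstruction,
    defaults: WeightDefaults | None = None,
) -> LayeredNetwork:
    """Rewire the feature<->task connections in place, per the instruction.

    All existing feature<->task edges are removed first; every other
    connection — including the plastic feature->motor weights — is left
    untouched, so a model can be re-instructed after learning without
    forgetting its action effects.
    """
    if defaults is None:
        defaults = getattr(getattr(net, "spec", None), "defaults", None) or WeightDefaults()
    levels = {l.name: l.level for l in net.layers}
    missing = sorted(c for c in instruction.referenced_codes() if c not in net.units)
    if missing:
        raise ValueError(f"task instruction references unknown codes: {', '.join(missing)}")
    for c in instruction.referenced_codes():
        lvl = levels[net.units[c].layer_id]
        for r in instruction.rules:
            if c == r.task and lvl != "task":
                raise ValueError(f"{c!r} is not a task code")
            if c in r.stimulus + r.response and lvl != "feature":
                raise ValueError(f"{c!r} is not a feature code")

    def is_task_edge(c: Connection) -> bool:
        pair = {levels[net.units[c.src].layer_id], levels[net.units[c.dst].layer_id]}
        return pair == {"feature", "task"}

    kept = [c for c in net.connections if not is_task_edge(c)]
    w_ft = instruction.w_feature_task
    if w_ft is None:
        w_ft = defaults.feature_task
    w_tf = instruction.w_task_feature
    if w_tf is None:
        w_tf = defaults.task_feature
    w_rt = instruction.w_response_task
    if w_rt is None:
        w_rt = defaults.response_task
    new_edges: list[Connection] = []
    seen: set[tuple[str, str]] = set()

    def add(src: str, dst: str, w: float) -> None:
        if (src, dst) not in seen:
            seen.add((src, dst))
            new_edges.append(Connection(src, dst, w, ConnectionKind.VI))

    for r in instruction.rules:
        for f in r.stimulus:
            add(f, r.task, w_ft)
            add(r.task, f, w_tf)
        for f in r.response:
            add(f, r.task, w_rt)
            add(r.task, f, w_tf)
    net.connections = kept + new_edges
    net._compile()
    net.reset()
    return net


# -- structural comparison -------------------------------------------------

@dataclass
class ModelDiff:
    """Edge-level difference between two networks with one code inventory."""

    only_in_a: list[tuple[str, str, str, float]]
    only_in_b: list[tuple[str, str, str, float]]
    reweighted: list[tuple[str, str, str, float, float]]

    @property
    def empty(self) -> bool:
        return not (self.only_in_a or self.only_in_b or self.reweighted)


def diff_models(a: LayeredNetwork, b: LayeredNetwork) -> ModelDiff:
    """Compare two networks edge by edge; raises on unit-inventory mismatch."""
    if set(a.units) != set(b.units):
        raise ValueError("networks have different code inventories")
    ea = {(c.src, c.dst, c.kind.value): c.weight for c in a.connections}
    eb = {(c.src, c.dst, c.kind.value): c.weight for c in b.connections}
    only_a = sorted((s, d, k, ea[(s, d, k)]) for (s, d, k) in set(ea) - set(eb))
    only_b = sorted((s, d, k, eb[(s, d, k)]) for (s, d, k) in set(eb) - set(ea))
    rew = sorted((s, d, k, ea[key], eb[key]) for key in set(ea) & set(eb)
                 if ea[key] != eb[key] for (s, d, k) in [key])
    return ModelDiff(only_a, only_b, rew)
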