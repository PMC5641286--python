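"""The five stimulus-response compatibility experiments as seeded configs.

Each paradigm is expressed as an :class:`ExperimentSpec`: one or more model
groups (instances differing only in task instruction or effect schedule)
plus named stimulus conditions. Running an experiment always follows the
same two-phase protocol: build the model with its learning-phase task
wiring in place, run the motor-babbling learning phase, optionally re-wire
the task codes for the test phase, then run every condition for n seeded
trials and summarise cycles-to-threshold.

Paradigms
---------
``elsner_hommel``
    Action-effect learning: keypresses produce tones during learning; at
    test the tones signal either the key that produced them (non-reversal)
    or the other key (reversal).
``kunde``
    Response-effect compatibility: keypress intensity is paired with a tone
    whose loudness either matches (consistent) or mismatches (inconsistent)
    the press force; groups differ only in the effect schedule.
``simon``
    Auditory Simon task: respond to pitch with a left/right key while the
    tone's task-irrelevant location matches, mismatches, or is absent.
``stroop``
    Ink-colour naming with colour words; structurally the Simon model under
    a code renaming (word features are shared by written stimuli and spoken
    responses).
``hommel_inversion``
    Inverted Simon task: each keypress flashes a light on the opposite
    side; instruction frames the same movements as key presses or as light
    flashes, which inverts the compatibility effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .builder import (
    Layer,
    WeightDefaults,
    ModelSpec,
    SensoryFeatureLink,
    TaskInstruction,
    TaskRule,
    build_model,
    internalize_task,
)
from .learning import learning_phase
from .network import LayeredNetwork, run_trial, trial_rng
from .params import LearningParams, NetworkParams

__all__ = [
    "ConditionSummary",
    "Group",
    "ExperimentSpec",
    "RunResult",
    "run_condition",
    "run_experiment",
    "EXPERIMENTS",
    "experiment_spec",
    "TEST_STREAM",
]

#: seed-stream tag for test-phase trials (learning uses LEARNING_STREAM = 0)
TEST_STREAM = 1


@dataclass(frozen=True)
class ConditionSummary:
    """Cycles-to-threshold statistics over the non-omitted trials of one condition."""

    condition: str
    mean_cycles: float
    sd_cycles: float
    n: int
    omissions: int
    ties: int


@dataclass
class Group:
    """One model instance of an experiment.

    ``spec.task`` is the instruction in place during the learning phase;
    ``test_task``, when given, replaces the feature<->task wiring before
    the test phase (re-instruction with learned weights intact).
    """

    name: str
    spec: ModelSpec
    conditions: dict[str, list[list[str]]]
    test_task: TaskInstruction | None = None


@dataclass
class ExperimentSpec:
    name: str
    groups: list[Group]
    n_trials: int = 100
    seed: int = 0


def run_condition(
    net: LayeredNetwork,
    stimuli: Sequence[Sequence[str]],
    n_trials: int,
    seed: int | None,
    group_index: int = 0,
    cond_index: int = 0,
    condition: str = "",
) -> ConditionSummary:
    """Run ``n_trials`` seeded trials of one condition and summarise them.

    ``stimuli`` lists the alternative stimulus code-sets of the condition
    (e.g. the high-tone and low-tone variants); trials cycle through them
    so each variant contributes equally. Trial i draws its own generator
    from ``(seed, group_index, TEST_STREAM + cond_index, i)``, so any
    condition is reproducible in isolation.
    """
    ext = net.params.ext_input
    cycles: list[int] = []
    omissions = ties = 0
    for i in range(n_trials):
        codes = stimuli[i % len(stimuli)]
        stim = {c: ext for c in codes}
        rng = None if seed is None else trial_rng(seed, group_index, TEST_STREAM + cond_index, i)
        out = run_trial(net, stim, rng, record_trace=False)
        if out.tie:
            ties += 1
        elif out.winner is None:
            omissions += 1
        else:
            cycles.append(out.cycles)
    arr = np.array(cycles, dtype=float)
    mean = float(arr.mean()) if len(arr) else float("nan")
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    if n_trials and omissions / n_trials > 0.10:
        import warnings

        warnings.warn(
            f"condition {condition or '<unnamed>'!r}: omission rate "
            f"{omissions / n_trials:.0%} exceeds 10%", stacklevel=2)
    return ConditionSummary(condition, mean, sd, n_trials, omissions, ties)


@dataclass
class RunResult:
    """Everything one experiment run produces."""

    summaries: pd.DataFrame          # experiment, group, condition, n, mean, sd, ...
    weight_history: dict[str, pd.DataFrame]
    networks: dict[str, LayeredNetwork]

    def summary(self, group: str, condition: str) -> pd.Series:
        df = self.summaries
        row = df[(df.group == group) & (df.condition == condition)]
        if row.empty:
            raise KeyError(f"no summary for group={group!r} condition={condition!r}")
        return row.iloc[0]


def run_experiment(exp: ExperimentSpec) -> RunResult:
    """Run the full two-phase protocol for every group of an experiment."""
    rows = []
    histories: dict[str, pd.DataFrame] = {}
    networks: dict[str, LayeredNetwork] = {}
    for g_idx, group in enumerate(exp.groups):
        net = build_model(group.spec)
        histories[group.name] = learning_phase(
            net, group.spec.effects, group.spec.learning,
            seed=exp.seed, group_index=g_idx)
        if group.test_task is not None:
            internalize_task(net, group.test_task, group.spec.defaults)
        networks[group.name] = net
        for c_idx, (cond, stimuli) in enumerate(group.conditions.items()):
            s = run_condition(net, stimuli, exp.n_trials, exp.seed,
                              group_index=g_idx, cond_index=c_idx, condition=cond)
            rows.append((exp.name, group.name, cond, s.n, s.mean_cycles,
                         s.sd_cycles, s.omissions, s.ties))
    df = pd.DataFrame(rows, columns=[
        "experiment", "group", "condition", "n", "mean_cycles", "sd_cycles",
        "omissions", "ties"])
    return RunResult(df, histories, networks)


# ---------------------------------------------------------------------------
# paradigm constructors
# ---------------------------------------------------------------------------

def _spec(name, layers, links, task, effects, network, learning,
          defaults=None) -> ModelSpec:
    return ModelSpec(
        name=name,
        layers=[Layer(*l) for l in layers],
        links=[SensoryFeatureLink(*l) for l in links],
        task=task,
        effects=effects,
        network=network,
        learning=learning,
        defaults=defaults or WeightDefaults(),
    )


def _rules(*triples: tuple[Sequence[str], str, Sequence[str]]) -> TaskInstruction:
    return TaskInstruction(rules=tuple(
        TaskRule(tuple(s), t, tuple(r)) for s, t, r in triples))


def elsner_hommel(network: NetworkParams, learning: LearningParams,
                  n_trials: int = 100, seed: int = 0,
                  defaults: WeightDefaults | None = None) -> ExperimentSpec:
    """Action-effect learning with reversed vs. non-reversed test mapping.

    During learning, keypresses produce tones (M1: left key + low tone,
    M2: right key + high tone) under a free-choice cue instruction. At test
    the tones become imperative stimuli: the non-reversal instruction maps
    each tone to the key that produced it, the reversal instruction to the
    other key.
    """
    layers = [
        ("vis_shape", "sensory", ("vis_square",)),
        ("aud_pitch", "sensory", ("aud_high", "aud_low")),
        ("hap_loc", "sensory", ("key_left", "key_right")),
        ("shape", "feature", ("Square",)),
        ("pitch", "feature", ("High", "Low")),
        ("location", "feature", ("Left", "Right")),
        ("kind", "feature", ("Sound", "Key")),
        ("task", "task", ("T1", "T2")),
        ("motor", "motor", ("M1", "M2")),
    ]
    links = [
        ("vis_square", "Square"),
        ("aud_high", "High"), ("aud_low", "Low"),
        ("key_left", "Left"), ("key_right", "Right"),
        ("aud_high", "Sound"), ("aud_low", "Sound"),
        ("key_left", "Key"), ("key_right", "Key"),
    ]
    # free-choice phase: the cue maps to keypressing in general, not to a
    # side, so the location codes are free to learn from the action effects
    learning_task = _rules((("Square",), "T1", ("Key",)),
                           (("Square",), "T2", ("Key",)))
    effects = {"M1": ["key_left", "aud_low"], "M2": ["key_right", "aud_high"]}
    spec = _spec("elsner_hommel", layers, links, learning_task, effects,
                 network, learning, defaults)
    tones = [["aud_low"], ["aud_high"]]
    non_reversal = _rules((("Low",), "T1", ("Left", "Key")),
                          (("High",), "T2", ("Right", "Key")))
    reversal = _rules((("High",), "T1", ("Left", "Key")),
                      (("Low",), "T2", ("Right", "Key")))
    groups = [
        Group("non_reversal", spec.copy(), {"tones": tones}, test_task=non_reversal),
        Group("reversal", spec.copy(), {"tones": tones}, test_task=reversal),
    ]
    return ExperimentSpec("elsner_hommel", groups, n_trials, seed)


def kunde(network: NetworkParams, learning: LearningParams,
          n_trials: int = 100, seed: int = 0,
          defaults: WeightDefaults | None = None) -> ExperimentSpec:
    """Response-effect compatibility: press force vs. effect-tone loudness.

    Groups share wiring and instruction; they differ only in the effect
    schedule. Consistent: forceful press -> loud tone; inconsistent:
    forceful press -> soft tone. Haptic and auditory intensity project to
    the same shared intensity feature codes.
    """
    layers = [
        ("vis_color", "sensory", ("vis_red", "vis_green")),
        ("aud_intensity", "sensory", ("aud_loud", "aud_soft")),
        ("hap_intensity", "sensory", ("press_hard", "press_soft")),
        ("color", "feature", ("Red", "Green")),
        ("intensity", "feature", ("Forceful", "Gentle")),
        ("kind", "feature", ("Key",)),
        ("task", "task", ("T1", "T2")),
        ("motor", "motor", ("M1", "M2")),
    ]
    # the imperative colour cue is a strong, well-practised visual channel:
    # its bottom-up links are hand-set above the global default
    links = [
        ("vis_red", "Red", 0.6), ("vis_green", "Green", 0.6),
        ("aud_loud", "Forceful"), ("aud_soft", "Gentle"),
        ("press_hard", "Forceful"), ("press_soft", "Gentle"),
        ("press_hard", "Key"), ("press_soft", "Key"),
    ]
    task = _rules((("Red",), "T1", ("Forceful", "Key")),
                  (("Green",), "T2", ("Gentle", "Key")))
    consistent = {"M1": ["press_hard", "aud_loud"], "M2": ["press_soft", "aud_soft"]}
    inconsistent = {"M1": ["press_hard", "aud_soft"], "M2": ["press_soft", "aud_loud"]}
    colors = [["vis_red"], ["vis_green"]]
    groups = [
        Group("consistent",
              _spec("kunde_consistent", layers, links, task, consistent,
                    network, learning, defaults),
              {"colors": colors}),
        Group("inconsistent",
              _spec("kunde_inconsistent", layers, links, task, inconsistent,
                    network, learning, defaults),
              {"colors": colors}),
    ]
    return ExperimentSpec("kunde", groups, n_trials, seed)


def simon(network: NetworkParams, learning: LearningParams,
          n_trials: int = 100, seed: int = 0,
          defaults: WeightDefaults | None = None) -> ExperimentSpec:
    """Auditory Simon task: pitch is relevant, tone location is not.

    One location feature layer encodes both the tone's side and the
    response key's side; the compatibility effect follows from that code
    overlap.
    """
    layers = [
        ("aud_pitch", "sensory", ("aud_high", "aud_low")),
        ("aud_loc", "sensory", ("aud_left", "aud_right")),
        ("hap_loc", "sensory", ("key_left", "key_right")),
        ("pitch", "feature", ("High", "Low")),
        ("location", "feature", ("Left", "Right")),
        ("kind", "feature", ("Key",)),
        ("task", "task", ("T1", "T2")),
        ("motor", "motor", ("M1", "M2")),
    ]
    links = [
        ("aud_high", "High"), ("aud_low", "Low"),
        ("aud_left", "Left"), ("aud_right", "Right"),
        ("key_left", "Left"), ("key_right", "Right"),
        ("key_left", "Key"), ("key_right", "Key"),
    ]
    task = _rules((("High",), "T1", ("Left", "Key")),
                  (("Low",), "T2", ("Right", "Key")))
    effects = {"M1": ["key_left"], "M2": ["key_right"]}
    spec = _spec("simon", layers, links, task, effects, network, learning,
                 defaults)
    conditions = {
        "compatible": [["aud_high", "aud_left"], ["aud_low", "aud_right"]],
        "neutral": [["aud_high"], ["aud_low"]],
        "incompatible": [["aud_high", "aud_right"], ["aud_low", "aud_left"]],
    }
    return ExperimentSpec("simon", [Group("all", spec, conditions)], n_trials, seed)


#: code renaming that carries the Simon model onto the Stroop model
STROOP_RENAME: dict[str, str] = {
    "aud_pitch": "vis_ink", "aud_high": "ink_red", "aud_low": "ink_green",
    "aud_loc": "vis_word", "aud_left": "word_red", "aud_right": "word_green",
    "hap_loc": "aud_speech", "key_left": "say_red", "key_right": "say_green",
    "pitch": "ink", "High": "RedInk", "Low": "GreenInk",
    "location": "word", "Left": "WordRed", "Right": "WordGreen",
    "kind": "kind", "Key": "Speech",
    "task": "task", "T1": "T1", "T2": "T2",
    "motor": "motor", "M1": "M1", "M2": "M2",
    "simon": "stroop",
}


def stroop(network: NetworkParams, learning: LearningParams,
           n_trials: int = 100, seed: int = 0,
           defaults: WeightDefaults | None = None) -> ExperimentSpec:
    """Stroop colour naming, generated from the Simon spec by code renaming.

    Word feature codes are shared between the written colour words and the
    spoken responses, exactly as location codes are shared in the Simon
    task; the two models are structurally isomorphic.
    """
    base = simon(network, learning, n_trials, seed, defaults)
    ren = STROOP_RENAME

    def r(x: str) -> str:
        return ren.get(x, x)

    g = base.groups[0]
    s = g.spec
    spec = ModelSpec(
        name=r(s.name),
        layers=[Layer(r(l.name), l.level, tuple(r(c) for c in l.codes))
                for l in s.layers],
        links=[SensoryFeatureLink(r(l.sensory), r(l.feature), l.w_up, l.w_down)
               for l in s.links],
        task=TaskInstruction(
            rules=tuple(TaskRule(tuple(r(c) for c in ru.stimulus), r(ru.task),
                                 tuple(r(c) for c in ru.response))
                        for ru in s.task.rules),
            w_feature_task=s.task.w_feature_task,
            w_task_feature=s.task.w_task_feature,
            w_response_task=s.task.w_response_task),
        effects={r(m): [r(c) for c in eff] for m, eff in s.effects.items()},
        network=s.network, learning=s.learning, defaults=s.defaults)
    conditions = {cond: [[r(c) for c in alt] for alt in alts]
                  for cond, alts in g.conditions.items()}
    return ExperimentSpec("stroop", [Group("all", spec, conditions)],
                          n_trials, seed)


def hommel_inversion(network: NetworkParams, learning: LearningParams,
                     n_trials: int = 100, seed: int = 0,
                     defaults: WeightDefaults | None = None) -> ExperimentSpec:
    """Inverted Simon task: keypresses flash a light on the opposite side.

    Both groups perform identical movements to identical stimuli; only the
    instruction differs (respond "with the keys" vs. "with the lights").
    Conditions are named by stimulus-KEY congruence for both groups, as the
    effect inversion is read off exactly this labelling.
    """
    layers = [
        ("aud_pitch", "sensory", ("aud_high", "aud_low")),
        ("aud_loc", "sensory", ("aud_left", "aud_right")),
        ("hap_loc", "sensory", ("key_left", "key_right")),
        ("vis_loc", "sensory", ("light_left", "light_right")),
        ("pitch", "feature", ("High", "Low")),
        ("location", "feature", ("Left", "Right")),
        ("kind", "feature", ("Key", "Light")),
        ("task", "task", ("T1", "T2")),
        ("motor", "motor", ("M1", "M2")),
    ]
    links = [
        ("aud_high", "High"), ("aud_low", "Low"),
        ("aud_left", "Left"), ("aud_right", "Right"),
        ("key_left", "Left"), ("key_right", "Right"),
        ("light_left", "Left"), ("light_right", "Right"),
        ("key_left", "Key"), ("key_right", "Key"),
        ("light_left", "Light"), ("light_right", "Light"),
    ]
    # M1 presses the left key and thereby flashes the right light
    effects = {"M1": ["key_left", "light_right"], "M2": ["key_right", "light_left"]}
    key_task = _rules((("High",), "T1", ("Left", "Key")),
                      (("Low",), "T2", ("Right", "Key")))
    light_task = _rules((("High",), "T1", ("Right", "Light")),
                        (("Low",), "T2", ("Left", "Light")))
    conditions = {
        "congruent_key": [["aud_high", "aud_left"], ["aud_low", "aud_right"]],
        "neutral": [["aud_high"], ["aud_low"]],
        "incongruent_key": [["aud_high", "aud_right"], ["aud_low", "aud_left"]],
    }
    groups = [
        Group("key", _spec("inversion_key", layers, links, key_task, effects,
                           network, learning, defaults), dict(conditions)),
        Group("light", _spec("inversion_light", layers, links, light_task, effects,
                             network, learning, defaults), dict(conditions)),
    ]
    return ExperimentSpec("hommel_inversion", groups, n_trials, seed)


def shipped_spec_path(name: str):
    """Path of the shipped YAML model spec for a paradigm group.

    Files are named ``<experiment>[_<group>].yaml``; single-group
    experiments drop the group suffix. They are regenerated from the
    constructors in this module and shipped for external tooling.
    """
    from importlib import resources

    return resources.files("tecsim") / "modelspecs" / f"{name}.yaml"


EXPERIMENTS: dict[str, Callable[..., ExperimentSpec]] = {
    "elsner_hommel": elsner_hommel,
    "kunde": kunde,
    "simon": simon,
    "stroop": stroop,
    "hommel_inversion": hommel_inversion,
}


def experiment_spec(name: str, network: NetworkParams | None = None,
                    learning: LearningParams | None = None,
                    n_trials: int = 100, seed: int = 0,
                    defaults: WeightDefaults | None = None) -> ExperimentSpec:
    """Build a named experiment under the given (default: shipped) parameters."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; choose from "
                       f"{', '.join(sorted(EXPERIMENTS))}")
    return EXPERIMENTS[name](network or NetworkParams(),
                             learning or LearningParams(), n_trials, seed,
                             defaults)
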