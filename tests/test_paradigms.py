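"""Structural and protocol tests of the five packaged experiments."""

from __future__ import annotations

import numpy as np
import pytest

from tecsim import (
    LearningParams,
    NetworkParams,
    build_model,
    diff_models,
    experiment_spec,
    internalize_task,
    learning_phase,
    run_condition,
    run_experiment,
)
from tecsim.paradigms import STROOP_RENAME


@pytest.fixture(scope="module")
def fast():
    """Shipped defaults but few trials, for protocol-level tests."""
    return dict(network=NetworkParams(), learning=LearningParams())


def test_unknown_experiment_name_is_rejected():
    with pytest.raises(KeyError, match="unknown experiment"):
        experiment_spec("simon_says")


@pytest.mark.parametrize("name", ["elsner_hommel", "kunde", "simon", "stroop",
                                  "hommel_inversion"])
def test_every_condition_references_existing_sensory_codes(name, fast):
    exp = experiment_spec(name, **fast)
    for group in exp.groups:
        sensory = set(group.spec.codes_by_level("sensory"))
        for cond, alts in group.conditions.items():
            for codes in alts:
                assert set(codes) <= sensory, (name, group.name, cond)
        group.spec.validate()


def test_groups_differ_only_as_designed(fast):
    """Kunde groups: same wiring, different effect schedule; inversion groups:
    same wiring and effects, different task edges only."""
    kunde = experiment_spec("kunde", **fast)
    a, b = (g.spec for g in kunde.groups)
    assert a.to_dict()["links"] == b.to_dict()["links"]
    assert a.task == b.task
    assert a.effects != b.effects

    inv = experiment_spec("hommel_inversion", **fast)
    key, light = (build_model(g.spec) for g in inv.groups)
    diff = diff_models(key, light)
    changed = {(s, d) for s, d, *_ in diff.only_in_a + diff.only_in_b}
    changed |= {(s, d) for s, d, _, _, _ in diff.reweighted}
    task_codes = {"T1", "T2"}
    assert changed, "instructions must differ"
    assert all(s in task_codes or d in task_codes for s, d in changed)


def test_stroop_is_simon_renamed(fast):
    """The Stroop and Simon models are isomorphic under the code renaming."""
    simon = experiment_spec("simon", **fast).groups[0].spec
    stroop = experiment_spec("stroop", **fast).groups[0].spec
    ren = STROOP_RENAME
    d_simon, d_stroop = simon.to_dict(), stroop.to_dict()

    def rename(obj):
        if isinstance(obj, str):
            return ren.get(obj, obj)
        if isinstance(obj, list):
            return [rename(x) for x in obj]
        if isinstance(obj, dict):
            return {rename(k): rename(v) for k, v in obj.items()}
        return obj

    assert rename(d_simon) == d_stroop


def test_rewiring_after_learning_preserves_learned_weights(fast):
    """Phase-2 re-instruction leaves every plastic weight bit-identical."""
    exp = experiment_spec("elsner_hommel", **fast)
    group = exp.groups[0]
    net = build_model(group.spec)
    learning_phase(net, group.spec.effects, group.spec.learning, seed=3)
    before = dict(net.learned_weights())
    internalize_task(net, group.test_task, group.spec.defaults)
    after = dict(net.learned_weights())
    assert before.keys() == after.keys()
    for k in before:
        assert before[k] == after[k], k  # bit-identical, not approximately


def test_run_condition_determinism_and_zero_noise_sd(fast):
    exp = experiment_spec("simon", **fast)
    group = exp.groups[0]
    spec = group.spec.copy()
    spec.network = spec.network.replace(noise_sd=0.0)
    net = build_model(spec)
    learning_phase(net, spec.effects, spec.learning)
    # a single stimulus variant: noiseless trials are strictly identical
    stimuli = [group.conditions["compatible"][0]]
    s1 = run_condition(net, stimuli, 6, seed=9, condition="compatible")
    s2 = run_condition(net, stimuli, 6, seed=9, condition="compatible")
    assert s1 == s2                       # same seed, identical summary
    assert s1.sd_cycles == 0.0            # noiseless trials are identical
    assert s1.omissions == 0


def test_run_condition_warns_on_high_omission_rate(fast):
    exp = experiment_spec("simon", **fast)
    spec = exp.groups[0].spec.copy()
    net = build_model(spec)  # no learning: motors unreachable -> omissions
    with pytest.warns(UserWarning, match="omission rate"):
        run_condition(net, [["aud_high"]], 5, seed=0, condition="x")


def test_simon_and_stroop_summaries_identical_under_matched_seeds(fast):
    """Structural isomorphism: identical cycle statistics, noise included."""
    n = 8
    res_simon = run_experiment(experiment_spec("simon", n_trials=n, seed=5, **fast))
    res_stroop = run_experiment(experiment_spec("stroop", n_trials=n, seed=5, **fast))
    a = res_simon.summaries.drop(columns=["experiment"])
    b = res_stroop.summaries.drop(columns=["experiment"])
    assert a.equals(b)


def test_inversion_key_light_symmetry_noise_free(fast):
    """Exchanging Key/Light instructions exchanges the congruency summaries.

    The two instances are exact mirror images code-for-code, so in the
    deterministic (noise-free) network the congruent-key summary of the Key
    group equals the incongruent-key summary of the Light group, cycle for
    cycle.
    """
    exp = experiment_spec("hommel_inversion", **fast)
    nets = {}
    for g in exp.groups:
        spec = g.spec.copy()
        spec.network = spec.network.replace(noise_sd=0.0)
        net = build_model(spec)
        learning_phase(net, spec.effects, spec.learning)
        nets[g.name] = net
    conds = exp.groups[0].conditions
    for key_cond, light_cond in [("congruent_key", "incongruent_key"),
                                 ("neutral", "neutral"),
                                 ("incongruent_key", "congruent_key")]:
        s_key = run_condition(nets["key"], conds[key_cond], 2, seed=None)
        s_light = run_condition(nets["light"], conds[light_cond], 2, seed=None)
        assert s_key.mean_cycles == s_light.mean_cycles, (key_cond, light_cond)
        assert s_key.omissions == s_light.omissions


def test_run_experiment_summary_table_shape(fast):
    res = run_experiment(experiment_spec("hommel_inversion", n_trials=4, seed=1,
                                         **fast))
    df = res.summaries
    assert list(df.columns) == ["experiment", "group", "condition", "n",
                                "mean_cycles", "sd_cycles", "omissions", "ties"]
    assert len(df) == 6  # 2 groups x 3 conditions
    assert set(df.group) == {"key", "light"}
    assert (df.n == 4).all()


def test_two_seed_consistency_of_condition_means(fast):
    """Means from two independent seeds agree within 2 combined SEs."""
    exp = experiment_spec("simon", **fast)
    group = exp.groups[0]
    net = build_model(group.spec)
    learning_phase(net, group.spec.effects, group.spec.learning, seed=11)
    stimuli = group.conditions["neutral"]
    a = run_condition(net, stimuli, 200, seed=101, condition="neutral")
    b = run_condition(net, stimuli, 200, seed=202, condition="neutral")
    se = np.sqrt(a.sd_cycles**2 / a.n + b.sd_cycles**2 / b.n)
    assert abs(a.mean_cycles - b.mean_cycles) <= max(2 * se, 0.5)


def test_shipped_model_specs_match_constructors(fast):
    """The packaged YAML spec files equal the in-code paradigm definitions."""
    from tecsim.builder import ModelSpec
    from tecsim.paradigms import shipped_spec_path

    for name in ("elsner_hommel", "kunde", "simon", "stroop",
                 "hommel_inversion"):
        exp = experiment_spec(name, **fast)
        for group in exp.groups:
            stem = name if len(exp.groups) == 1 else f"{name}_{group.name}"
            shipped = ModelSpec.from_dict(
                __import__("yaml").safe_load(shipped_spec_path(stem).read_text()))
            assert shipped.to_dict() == group.spec.to_dict(), stem
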