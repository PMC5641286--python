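"""Parameter calibration against the qualitative compatibility effects.

The simulator's substantive claims are directional: re-learned mappings are
slower than consistent ones, compatible trials beat neutral beat
incompatible, and the inverted-Simon instruction flips the effect. This
module searches a parameter box for sets under which all five experiments
reproduce those orderings with correct responses and zero omissions, and
reports nearest misses when the search fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .builder import WeightDefaults
from .params import LearningParams, NetworkParams
from .paradigms import experiment_spec, run_experiment

__all__ = ["ORDERINGS", "check_orderings", "calibrate_params", "CalibrationResult"]

#: The headline effect directions, one tuple per experiment:
#: (experiment, [(group, condition), ...] expected in increasing mean cycles).
ORDERINGS: list[tuple[str, list[tuple[str, str]]]] = [
    ("elsner_hommel", [("non_reversal", "tones"), ("reversal", "tones")]),
    ("kunde", [("consistent", "colors"), ("inconsistent", "colors")]),
    ("simon", [("all", "compatible"), ("all", "neutral"), ("all", "incompatible")]),
    ("stroop", [("all", "compatible"), ("all", "neutral"), ("all", "incompatible")]),
    ("hommel_inversion", [("key", "congruent_key"), ("key", "neutral"),
                          ("key", "incongruent_key")]),
    ("hommel_inversion", [("light", "incongruent_key"), ("light", "neutral"),
                          ("light", "congruent_key")]),
]


def check_orderings(
    summaries_by_experiment: Mapping[str, pd.DataFrame],
    orderings: Sequence[tuple[str, list[tuple[str, str]]]] = ORDERINGS,
) -> tuple[bool, list[str]]:
    """Check every required strict ordering of condition means.

    Returns (all_hold, list of violation messages); experiments missing
    from the mapping are skipped silently so partial checks are possible.
    """
    violations: list[str] = []
    for experiment, chain in orderings:
        df = summaries_by_experiment.get(experiment)
        if df is None:
            continue
        means = []
        for group, cond in chain:
            row = df[(df.group == group) & (df.condition == cond)]
            if row.empty:
                violations.append(f"{experiment}: missing {group}/{cond}")
                break
            means.append((f"{group}/{cond}", float(row.iloc[0].mean_cycles)))
        else:
            for (na, ma), (nb, mb) in zip(means, means[1:]):
                if not ma < mb:
                    violations.append(
                        f"{experiment}: expected {na} < {nb}, got {ma:.2f} >= {mb:.2f}")
    return (not violations, violations)


@dataclass
class CalibrationResult:
    satisfied: bool
    network: NetworkParams
    learning: LearningParams
    defaults: WeightDefaults
    log: pd.DataFrame
    violations: list[str] = field(default_factory=list)


_NET_FIELDS = {f.name for f in fields(NetworkParams)}
_LEARN_FIELDS = {f.name for f in fields(LearningParams)}
_WD_FIELDS = {f.name for f in fields(WeightDefaults)}


def _assemble(point: Mapping[str, float], base_net: NetworkParams,
              base_learn: LearningParams, base_wd: WeightDefaults):
    net = base_net.replace(**{k: v for k, v in point.items() if k in _NET_FIELDS})
    learn = base_learn.replace(**{k: v for k, v in point.items() if k in _LEARN_FIELDS})
    wd = WeightDefaults(**{**asdict(base_wd),
                           **{k: v for k, v in point.items() if k in _WD_FIELDS}})
    return net, learn, wd


def _evaluate(net, learn, wd, n_trials, seed, orderings):
    by_exp: dict[str, pd.DataFrame] = {}
    experiments = {e for e, _ in orderings}
    for name in sorted(experiments):
        exp = experiment_spec(name, net, learn, n_trials=n_trials, seed=seed,
                              defaults=wd)
        try:
            res = run_experiment(exp)
        except RuntimeError as exc:
            return False, [f"{name}: learning failed ({exc})"], 0
        by_exp[name] = res.summaries
    ok, violations = check_orderings(by_exp, orderings)
    omissions = int(sum(df.omissions.sum() for df in by_exp.values()))
    if omissions:
        ok = False
        violations.append(f"{omissions} omission(s) across experiments")
    return ok, violations, omissions


def calibrate_params(
    search_space: Mapping[str, tuple[float, float]],
    seed: int = 0,
    n_candidates: int = 50,
    n_trials: int = 10,
    orderings: Sequence[tuple[str, list[tuple[str, str]]]] = ORDERINGS,
    base_network: NetworkParams | None = None,
    base_learning: LearningParams | None = None,
    base_defaults: WeightDefaults | None = None,
) -> CalibrationResult:
    """Random search over ``search_space`` for an ordering-satisfying set.

    ``search_space`` maps parameter names (fields of NetworkParams,
    LearningParams or WeightDefaults) to (low, high) bounds; parameters not
    named keep their base (shipped-default) values. The base point itself
    is always evaluated first, so a space containing the shipped defaults
    returns a satisfying set immediately. On failure the result carries the
    nearest miss (fewest ordering violations) and the full search log.
    """
    base_net = base_network or NetworkParams()
    base_learn = base_learning or LearningParams()
    base_wd = base_defaults or WeightDefaults()
    known = _NET_FIELDS | _LEARN_FIELDS | _WD_FIELDS
    unknown = sorted(set(search_space) - known)
    if unknown:
        raise ValueError(f"unknown parameters in search space: {', '.join(unknown)}")

    rng = np.random.default_rng(seed)
    rows = []
    best: tuple[int, dict] | None = None
    base_point = {k: getattr(
        base_net, k, getattr(base_learn, k, getattr(base_wd, k, None)))
        for k in search_space}
    candidates = [base_point] + [
        {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in search_space.items()}
        for _ in range(n_candidates)]
    for i, point in enumerate(candidates):
        try:
            net, learn, wd = _assemble(point, base_net, base_learn, base_wd)
        except ValueError as exc:  # out-of-range draw rejected by validation
            rows.append({**point, "ok": False, "violations": 1000, "note": str(exc)})
            continue
        ok, violations, _ = _evaluate(net, learn, wd, n_trials, seed, orderings)
        rows.append({**point, "ok": ok, "violations": len(violations),
                     "note": "; ".join(violations[:3])})
        if ok:
            return CalibrationResult(True, net, learn, wd,
                                     pd.DataFrame(rows), [])
        if best is None or len(violations) < best[0]:
            best = (len(violations), point, violations)
    _, point, violations = best
    net, learn, wd = _assemble(point, base_net, base_learn, base_wd)
    return CalibrationResult(False, net, learn, wd, pd.DataFrame(rows),
                             list(violations))
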