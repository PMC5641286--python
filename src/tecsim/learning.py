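"""Ideomotor (action-effect) learning via thresholded Hebbian updates.

The learning phase emulates motor babbling: motor codes are driven one at a
time; once the driven code crosses the response threshold its action
effects are presented by stimulating the scheduled sensory codes, and
activation propagates toward the feature level for a fixed number of
cycles. At the end of each trial every plastic feature->motor weight is
updated from the end-of-trial activations by

    w' = (1 - d_w) * w + Act_j * Act_k * (1 - w)

with ``Act = max(0, (A - LT) / (1 - LT))`` — only the fraction of
activation above the learning threshold LT contributes, and the (1 - w)
shunting keeps every weight in [0, 1]. Learning is one-way: no
motor->feature weight exists anywhere in the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import LayeredNetwork, TrialOutcome, run_trial, step, trial_rng
from .params import LearningParams

__all__ = ["hebbian_update", "learning_trial", "learning_phase", "LEARNING_STREAM"]

#: seed-stream tag separating learning-trial RNGs from test-trial RNGs
LEARNING_STREAM = 0


def hebbian_update(w: float, a_j: float, a_k: float, params: LearningParams) -> float:
    """One thresholded Hebbian step for a single feature->motor weight.

    Repeated identical co-activation with constant Hebbian product c
    converges to the fixed point ``w* = c / (d_w + c)``.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    lt = params.LT
    act_j = max(0.0, (a_j - lt) / (1.0 - lt))
    act_k = max(0.0, (a_k - lt) / (1.0 - lt))
    return (1.0 - params.d_w) * w + act_j * act_k * (1.0 - w)


@dataclass
class LearningTrialResult:
    motor_id: str
    cycles_to_threshold: int
    weights: dict[tuple[str, str], float]  # post-update plastic weights
    trace: np.ndarray
    unit_order: tuple[str, ...]


def learning_trial(
    net: LayeredNetwork,
    motor_id: str,
    effect_schedule: Mapping[str, Sequence[str]],
    rng: np.random.Generator | None,
    params: LearningParams,
    record_trace: bool = False,
) -> LearningTrialResult:
    """Drive one motor code, present its effects, update plastic weights.

    The motor unit is driven by ordinary external input (so competition and
    decay still apply) until it crosses the response threshold; the trial
    fails loudly if it never does. Its scheduled effect sensory codes are
    then stimulated, alongside the continued motor drive, for
    ``params.effect_cycles`` cycles. Finally every plastic feature->motor
    weight is updated from the end-of-trial activations; no other weight is
    touched.
    """
    if motor_id not in net.units or not net.units[motor_id].is_motor:
        raise ValueError(f"{motor_id!r} is not a motor code")
    p = net.params
    net.reset()
    rows: list[np.ndarray] = []

    def snap() -> None:
        if record_trace:
            rows.append(np.concatenate([net.A_exc, net.A_inh]))

    snap()
    if params.clamp_motor:
        net.set_activation(motor_id, 1.0)
        drive: dict[str, float] = {}
    else:
        drive = {motor_id: p.ext_input}
    crossed_at = None
    for t in range(1, p.max_cycles + 1):
        step(net, drive, rng)
        if params.clamp_motor:
            net.set_activation(motor_id, 1.0)
        snap()
        if net.activation(motor_id) >= p.response_threshold:
            crossed_at = t
            break
    if crossed_at is None:
        raise RuntimeError(
            f"driven motor code {motor_id!r} never crossed the response threshold "
            f"within {p.max_cycles} cycles; the model cannot execute its actions")
    effect_drive = dict(drive)
    for s in effect_schedule[motor_id]:
        effect_drive[s] = p.ext_input
    for _ in range(params.effect_cycles):
        step(net, effect_drive, rng)
        if params.clamp_motor:
            net.set_activation(motor_id, 1.0)
        snap()
    # synchronous weight update from end-of-trial activations
    old = net.learned_weights()
    new = {
        (j, k): hebbian_update(w, net.activation(j), net.activation(k), params)
        for (j, k), w in old.items()
    }
    for (j, k), w in new.items():
        net.set_learned_weight(j, k, w)
    trace = np.array(rows) if record_trace else np.empty((0, net.n_units))
    return LearningTrialResult(motor_id, crossed_at, new, trace,
                               tuple(net.exc_ids + net.inh_ids))


def learning_phase(
    net: LayeredNetwork,
    effect_schedule: Mapping[str, Sequence[str]],
    params: LearningParams,
    seed: int | None = None,
    group_index: int = 0,
) -> pd.DataFrame:
    """Run the motor-babbling phase: round-robin over motor codes.

    ``n_learning_trials`` trials alternate over the motor codes in layer
    order (M1, M2, M1, ...). Each trial gets its own generator derived from
    ``(seed, group_index, LEARNING_STREAM, trial_index)``; with
    ``seed=None`` the phase is noise-free. Returns the per-trial weight
    history as a tidy frame (trial, motor, src, dst, weight).
    """
    motors = [u for u in net.exc_ids if net.units[u].is_motor]
    missing = sorted(set(motors) - set(effect_schedule))
    if missing:
        raise ValueError(f"effect schedule misses motor codes: {', '.join(missing)}")
    history: list[tuple[int, str, str, str, float]] = []
    for i in range(params.n_learning_trials):
        motor_id = motors[i % len(motors)]
        rng = None if seed is None else trial_rng(seed, group_index, LEARNING_STREAM, i)
        result = learning_trial(net, motor_id, effect_schedule, rng, params)
        for (j, k), w in sorted(result.weights.items()):
            history.append((i, motor_id, j, k, w))
    return pd.DataFrame(history, columns=["trial", "motor", "src", "dst", "weight"])
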