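"""Localist interactive-activation network with paired lateral inhibition.

Units are localist codes organised into layers at four levels (sensory,
feature, task, motor). Every excitatory coding unit owns one paired
inhibitory unit; inhibitory units receive input exclusively from their
excitatory partner and project negative weights onto the other excitatory
units of the same layer, implementing winner-take-all competition.

Dynamics are fully synchronous. On every cycle each unit's activation is
updated by the shunting rule

    A(t+1) = rest + (1 - d_a) * (A(t) - rest)
             + gamma * (Exc * (1 - A(t)) + Inh * A(t))

where the excitatory drive of a coding unit is the sum of
voltage-independent input (weighted sigmoid outputs of its afferents),
voltage-dependent top-down input (gated by the unit's own decayed
activation; sensory units only), external stimulation, and Gaussian noise;
the inhibitory drive is the negatively weighted output of competing
inhibitory units. Activations are clamped to [0, 1] after each update and
clamp events are counted in the trial trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import NetworkParams

__all__ = [
    "ConnectionKind",
    "Unit",
    "Connection",
    "Layer",
    "LayeredNetwork",
    "TrialOutcome",
    "output_function",
    "excitatory_input",
    "voltage_dependent_input",
    "inhibitory_input",
    "step",
    "run_trial",
    "trial_rng",
]

INHIB_SUFFIX = ":inh"


class ConnectionKind(str, Enum):
    """Signalling class of a directed weighted edge."""

    VI = "VI"            # voltage-independent excitatory
    VD = "VD"            # voltage-dependent excitatory (feature -> sensory)
    INH = "INH"          # within-layer inhibition (from inhibitory units)
    LEARNED = "LEARNED"  # plastic feature -> motor, one-way
    PAIR = "PAIR"        # excitatory unit -> its paired inhibitory unit


@dataclass(frozen=True)
class Unit:
    id: str
    layer_id: str
    polarity: str = "excitatory"  # or "inhibitory"
    is_sensory: bool = False
    is_motor: bool = False

    @property
    def is_excitatory(self) -> bool:
        return self.polarity == "excitatory"


@dataclass
class Connection:
    src: str
    dst: str
    weight: float
    kind: ConnectionKind

    def __post_init__(self) -> None:
        self.kind = ConnectionKind(self.kind)
        if self.kind in (ConnectionKind.VI, ConnectionKind.VD,
                         ConnectionKind.LEARNED, ConnectionKind.PAIR):
            if not 0.0 <= self.weight <= 1.0:
                raise ValueError(
                    f"{self.kind.value} weight {self.src}->{self.dst} must lie "
                    f"in [0, 1], got {self.weight}")
        elif self.weight > 0.0:
            raise ValueError(
                f"INH weight {self.src}->{self.dst} must be <= 0, got {self.weight}")


@dataclass(frozen=True)
class Layer:
    name: str
    level: str  # sensory | feature | task | motor
    codes: tuple[str, ...]


class LayeredNetwork:
    """Immutable wiring + mutable activation state of one model instance.

    The constructor takes the excitatory coding units, their layers and the
    explicit connections; paired inhibitory units and their edges are
    expected to be present already (the model builder generates them).
    Internally the wiring is compiled to dense matrices over the excitatory
    units for fast synchronous updates; the per-unit helper functions in
    this module read from the same matrices, so both views are guaranteed
    consistent.
    """

    def __init__(
        self,
        layers: Sequence[Layer],
        units: Sequence[Unit],
        connections: Sequence[Connection],
        params: NetworkParams,
    ) -> None:
        self.layers: tuple[Layer, ...] = tuple(layers)
        self.units: dict[str, Unit] = {}
        for u in units:
            if u.id in self.units:
                raise ValueError(f"duplicate unit id {u.id!r}")
            self.units[u.id] = u
        self.connections: list[Connection] = list(connections)
        self.params = params
        self._validate()
        self._compile()
        self.reset()

    # -- construction -----------------------------------------------------

    def _validate(self) -> None:
        layer_names = {l.name for l in self.layers}
        for u in self.units.values():
            if u.layer_id not in layer_names:
                raise ValueError(f"unit {u.id!r} references unknown layer {u.layer_id!r}")
        for c in self.connections:
            for end in (c.src, c.dst):
                if end not in self.units:
                    raise ValueError(f"connection references unknown unit {end!r}")
            src, dst = self.units[c.src], self.units[c.dst]
            if c.kind is ConnectionKind.VD and not dst.is_sensory:
                raise ValueError(f"VD connection must terminate on a sensory unit: {c.src}->{c.dst}")
            if c.kind is ConnectionKind.LEARNED:
                if dst.polarity != "excitatory" or not dst.is_motor:
                    raise ValueError(f"LEARNED connection must terminate on a motor unit: {c.src}->{c.dst}")
                if src.is_motor:
                    raise ValueError("LEARNED connections are one-way feature->motor")
            if c.kind is ConnectionKind.INH and src.polarity != "inhibitory":
                raise ValueError(f"INH connection must originate from an inhibitory unit: {c.src}")
            if dst.polarity == "inhibitory" and c.kind is not ConnectionKind.PAIR:
                raise ValueError(
                    f"inhibitory unit {c.dst!r} may only receive from its paired unit")

    def _compile(self) -> None:
        exc = [u.id for u in self.units.values() if u.is_excitatory]
        inh = [u.id for u in self.units.values() if not u.is_excitatory]
        self.exc_ids: list[str] = exc
        self.inh_ids: list[str] = inh
        self._exc_index = {uid: i for i, uid in enumerate(exc)}
        self._inh_index = {uid: i for i, uid in enumerate(inh)}
        n, m = len(exc), len(inh)
        self.W_vi = np.zeros((n, n))       # dst x src over excitatory units
        self.W_vd = np.zeros((n, n))
        self.W_inh = np.zeros((n, m))      # dst excitatory x src inhibitory (<= 0)
        self.w_pair = np.zeros(m)          # paired excitatory -> inhibitory weight
        self._pair_src = np.zeros(m, dtype=int)  # excitatory index feeding each inhibitory
        self._learned_edges: list[Connection] = []
        pair_seen = np.zeros(m, dtype=bool)
        for c in self.connections:
            if c.kind is ConnectionKind.PAIR:
                j = self._inh_index[c.dst]
                if pair_seen[j]:
                    raise ValueError(f"inhibitory unit {c.dst!r} has two paired inputs")
                pair_seen[j] = True
                self.w_pair[j] = c.weight
                self._pair_src[j] = self._exc_index[c.src]
            elif c.kind is ConnectionKind.INH:
                self.W_inh[self._exc_index[c.dst], self._inh_index[c.src]] = c.weight
            elif c.kind is ConnectionKind.VD:
                self.W_vd[self._exc_index[c.dst], self._exc_index[c.src]] = c.weight
            else:  # VI or LEARNED
                self.W_vi[self._exc_index[c.dst], self._exc_index[c.src]] = c.weight
                if c.kind is ConnectionKind.LEARNED:
                    self._learned_edges.append(c)
        self.sensory_mask = np.array([self.units[u].is_sensory for u in exc])
        self.motor_mask = np.array([self.units[u].is_motor for u in exc])
        self.motor_indices = np.flatnonzero(self.motor_mask)

    # -- state ------------------------------------------------------------

    def reset(self) -> None:
        """Set every unit to the resting level."""
        rest = self.params.resting_level
        self.A_exc = np.full(len(self.exc_ids), rest, dtype=float)
        self.A_inh = np.full(len(self.inh_ids), rest, dtype=float)
        self.clamp_events = 0

    @property
    def n_units(self) -> int:
        return len(self.exc_ids) + len(self.inh_ids)

    def activation(self, unit_id: str) -> float:
        if unit_id in self._exc_index:
            return float(self.A_exc[self._exc_index[unit_id]])
        return float(self.A_inh[self._inh_index[unit_id]])

    def set_activation(self, unit_id: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError("activation must lie in [0, 1]")
        if unit_id in self._exc_index:
            self.A_exc[self._exc_index[unit_id]] = value
        else:
            self.A_inh[self._inh_index[unit_id]] = value

    # -- learned weights --------------------------------------------------

    def learned_weights(self) -> dict[tuple[str, str], float]:
        """Current plastic feature->motor weights keyed by (src, dst)."""
        return {(c.src, c.dst): self.W_vi[self._exc_index[c.dst], self._exc_index[c.src]]
                for c in self._learned_edges}

    def set_learned_weight(self, src: str, dst: str, weight: float) -> None:
        if not any(c.src == src and c.dst == dst for c in self._learned_edges):
            raise KeyError(f"no LEARNED connection {src}->{dst}")
        if not 0.0 <= weight <= 1.0:
            raise ValueError("LEARNED weight must lie in [0, 1]")
        self.W_vi[self._exc_index[dst], self._exc_index[src]] = weight
        for c in self._learned_edges:
            if c.src == src and c.dst == dst:
                c.weight = weight

    # -- stimulus ---------------------------------------------------------

    def _ext_vector(self, stimulus_map: Mapping[str, float]) -> np.ndarray:
        ext = np.zeros(len(self.exc_ids))
        for uid, magnitude in stimulus_map.items():
            u = self.units.get(uid)
            if u is None:
                raise KeyError(f"stimulus references unknown unit {uid!r}")
            if not (u.is_sensory or u.is_motor):
                raise ValueError(
                    f"external input may target only sensory or motor units, not {uid!r}")
            ext[self._exc_index[uid]] = magnitude
        return ext


# -- per-unit views of the dynamics (Eqs. of the update rule) --------------

def output_function(a: float | np.ndarray, na: float, qa: float) -> float | np.ndarray:
    """Sigmoid output ``F(a) = a**na / (qa**na + a**na)``; F(0)=0, F(qa)=0.5."""
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("activation must be >= 0")
    if na <= 0 or qa <= 0:
        raise ValueError("na and qa must be > 0")
    out = a_arr ** na / (qa ** na + a_arr ** na)
    return float(out) if np.isscalar(a) else out


def _F_exc(net: LayeredNetwork) -> np.ndarray:
    p = net.params
    return np.asarray(output_function(net.A_exc, p.na, p.qa))


def voltage_dependent_input(net: LayeredNetwork, unit_id: str) -> float:
    """Top-down input gated by the receiving sensory unit's own activation.

    Returns ``sum_k w+ F(A_k) * max(A_i (1 - d_a) - VT, 0) / (1 - VT)``;
    exactly zero while the decayed activation sits at or below VT.
    """
    u = net.units[unit_id]
    if not u.is_sensory:
        raise ValueError(f"voltage-dependent input applies to sensory units only, not {unit_id!r}")
    p = net.params
    i = net._exc_index[unit_id]
    drive = float(net.W_vd[i] @ _F_exc(net))
    gate = max(net.A_exc[i] * (1.0 - p.d_a) - p.VT, 0.0) / (1.0 - p.VT)
    return drive * gate


def excitatory_input(
    net: LayeredNetwork,
    unit_id: str,
    stimulus_map: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Total excitatory drive: VI + VD + external + noise.

    With ``rng=None`` the noise term is omitted (deterministic view).
    """
    u = net.units[unit_id]
    p = net.params
    if not u.is_excitatory:
        j = net._inh_index[unit_id]
        return float(net.w_pair[j] * _F_exc(net)[net._pair_src[j]])
    i = net._exc_index[unit_id]
    total = float(net.W_vi[i] @ _F_exc(net))
    if net.W_vd[i].any():
        total += voltage_dependent_input(net, unit_id)
    if stimulus_map and unit_id in stimulus_map:
        total += stimulus_map[unit_id]
    if rng is not None and (p.noise_sd > 0 or p.noise_mean != 0):
        total += rng.normal(p.noise_mean, p.noise_sd)
    return total


def inhibitory_input(net: LayeredNetwork, unit_id: str) -> float:
    """Within-layer inhibition from the competitors' paired inhibitory units (<= 0)."""
    u = net.units[unit_id]
    if not u.is_excitatory:
        return 0.0
    p = net.params
    i = net._exc_index[unit_id]
    F_inh = np.asarray(output_function(net.A_inh, p.na, p.qa))
    return float(net.W_inh[i] @ F_inh)


# -- synchronous update ----------------------------------------------------

def step(
    net: LayeredNetwork,
    stimulus_map: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> None:
    """Advance the whole network one cycle, synchronously and in place.

    All inputs are computed from the cycle-t state before any unit commits
    its new activation; excitatory and inhibitory units update together.
    """
    p = net.params
    F_exc = _F_exc(net)
    F_inh = np.asarray(output_function(net.A_inh, p.na, p.qa))

    exc_vi = net.W_vi @ F_exc
    gate = np.maximum(net.A_exc * (1.0 - p.d_a) - p.VT, 0.0) / (1.0 - p.VT)
    exc_vd = (net.W_vd @ F_exc) * gate
    ext = net._ext_vector(stimulus_map) if stimulus_map else 0.0
    exc = exc_vi + exc_vd + ext
    if rng is not None and (p.noise_sd > 0 or p.noise_mean != 0):
        exc = exc + rng.normal(p.noise_mean, p.noise_sd, len(net.exc_ids))
    inh = net.W_inh @ F_inh  # <= 0

    rest = p.resting_level
    decay = rest + (1.0 - p.d_a) * (net.A_exc - rest)
    new_exc = decay + p.gamma * (exc * (1.0 - net.A_exc) + inh * net.A_exc)

    pair_drive = net.w_pair * F_exc[net._pair_src]
    decay_inh = rest + (1.0 - p.d_a) * (net.A_inh - rest)
    new_inh = decay_inh + p.gamma * pair_drive * (1.0 - net.A_inh)

    clamped_exc = np.clip(new_exc, 0.0, 1.0)
    clamped_inh = np.clip(new_inh, 0.0, 1.0)
    net.clamp_events += int(np.sum(clamped_exc != new_exc)) + int(np.sum(clamped_inh != new_inh))
    net.A_exc = clamped_exc
    net.A_inh = clamped_inh


# -- trials ----------------------------------------------------------------

@dataclass
class TrialOutcome:
    """Result of a single trial: winner, latency and the full trace."""

    winner: str | None
    cycles: int
    trace: np.ndarray          # (cycles + 1, n_exc + n_inh); row 0 = initial state
    unit_order: tuple[str, ...]
    tie: bool = False
    clamp_events: int = 0

    @property
    def omission(self) -> bool:
        return self.winner is None and not self.tie

    def trace_frame(self, net: LayeredNetwork) -> pd.DataFrame:
        """Tidy long-format trace: cycle, unit_id, layer_id, activation."""
        rows = []
        for cycle in range(self.trace.shape[0]):
            for j, uid in enumerate(self.unit_order):
                rows.append((cycle, uid, net.units[uid].layer_id,
                             round(float(self.trace[cycle, j]), 6)))
        return pd.DataFrame(rows, columns=["cycle", "unit_id", "layer_id", "activation"])


def trial_rng(experiment_seed: int, *indices: int) -> np.random.Generator:
    """Independent generator for one trial derived from (seed, indices)."""
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((int(experiment_seed),) + tuple(int(i) for i in indices))))


def run_trial(
    net: LayeredNetwork,
    stimulus_map: Mapping[str, float],
    rng: np.random.Generator | None = None,
    record_trace: bool = True,
) -> TrialOutcome:
    """Run one trial from rest until a motor unit crosses threshold.

    The stimulus map is held constant from cycle 0 to termination. Returns
    the winning motor code (``None`` for an omission), the cycle count at
    threshold crossing, and the full activation trace. If two motor units
    cross on the same cycle the more active one wins; an exact tie is
    flagged rather than silently broken.
    """
    if len(net.motor_indices) == 0:
        raise ValueError("network has no motor units")
    p = net.params
    net.reset()
    order = tuple(net.exc_ids + net.inh_ids)
    trace_rows = [np.concatenate([net.A_exc, net.A_inh])] if record_trace else []
    winner: str | None = None
    tie = False
    cycles = p.max_cycles
    for t in range(1, p.max_cycles + 1):
        step(net, stimulus_map, rng)
        if record_trace:
            trace_rows.append(np.concatenate([net.A_exc, net.A_inh]))
        motor_act = net.A_exc[net.motor_indices]
        crossed = motor_act >= p.response_threshold
        if crossed.any():
            cycles = t
            best = motor_act.max()
            at_best = np.flatnonzero(crossed & (motor_act == best))
            if len(at_best) > 1:
                tie = True
            else:
                winner = net.exc_ids[net.motor_indices[at_best[0]]]
            break
    trace = (np.array(trace_rows) if record_trace
             else np.empty((0, len(order))))
    return TrialOutcome(winner=winner, cycles=cycles, trace=trace,
                        unit_order=order, tie=tie, clamp_events=net.clamp_events)
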