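"""Shared fixtures: tiny hand-built networks and a small two-choice spec."""

from __future__ import annotations

import numpy as np
import pytest

from tecsim import (
    Connection,
    ConnectionKind,
    Layer,
    LayeredNetwork,
    ModelSpec,
    NetworkParams,
    LearningParams,
    SensoryFeatureLink,
    TaskInstruction,
    TaskRule,
    Unit,
)


@pytest.fixture
def params():
    """Deterministic parameters with mild dynamics for hand-built nets."""
    return NetworkParams(d_a=0.1, gamma=0.5, na=2.0, qa=0.5, VT=0.4,
                        noise_sd=0.0, ext_input=0.6, response_threshold=0.6,
                        max_cycles=100, w_exc_inh=0.8, w_inh=-0.8)


def make_chain(params: NetworkParams, with_vd: bool = False) -> LayeredNetwork:
    """s -> f -> m feed-forward chain (3 excitatory units, no inhibition).

    With ``with_vd`` a top-down voltage-dependent edge f -> s is added.
    """
    layers = [Layer("S", "sensory", ("s",)), Layer("F", "feature", ("f",)),
              Layer("M", "motor", ("m",))]
    units = [Unit("s", "S", is_sensory=True), Unit("f", "F"),
             Unit("m", "M", is_motor=True)]
    conns = [Connection("s", "f", 0.6, ConnectionKind.VI),
             Connection("f", "m", 0.7, ConnectionKind.VI)]
    if with_vd:
        conns.append(Connection("f", "s", 0.5, ConnectionKind.VD))
    return LayeredNetwork(layers, units, conns, params)


def make_pair_layer(params: NetworkParams, n: int = 2) -> LayeredNetwork:
    """One sensory layer of n excitatory units with full paired lateral inhibition."""
    codes = [f"u{i}" for i in range(n)]
    layers = [Layer("L", "sensory", tuple(codes)),
              Layer("M", "motor", ("m",))]
    units = [Unit(c, "L", is_sensory=True) for c in codes]
    units += [Unit(c + ":inh", "L", polarity="inhibitory") for c in codes]
    units.append(Unit("m", "M", is_motor=True))
    conns = []
    for c in codes:
        conns.append(Connection(c, c + ":inh", params.w_exc_inh, ConnectionKind.PAIR))
        for other in codes:
            if other != c:
                conns.append(Connection(c + ":inh", other, params.w_inh,
                                        ConnectionKind.INH))
    return LayeredNetwork(layers, units, conns, params)


@pytest.fixture
def chain(params):
    return make_chain(params)


@pytest.fixture
def chain_vd(params):
    return make_chain(params, with_vd=True)


@pytest.fixture
def two_choice_spec(params):
    """Minimal complete model spec: 2 sensory codes, 2 features, 2 tasks, 2 motors."""
    return ModelSpec(
        name="two_choice",
        layers=[
            Layer("sens", "sensory", ("s1", "s2")),
            Layer("feat", "feature", ("f1", "f2")),
            Layer("task", "task", ("T1", "T2")),
            Layer("motor", "motor", ("m1", "m2")),
        ],
        links=[SensoryFeatureLink("s1", "f1"), SensoryFeatureLink("s2", "f2")],
        task=TaskInstruction(rules=(TaskRule(("f1",), "T1", ("f1",)),
                                    TaskRule(("f2",), "T2", ("f2",)))),
        effects={"m1": ["s1"], "m2": ["s2"]},
        network=params,
        learning=LearningParams(d_w=0.1, LT=0.3, n_learning_trials=4,
                                effect_cycles=10),
    )
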