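"""Unit and property tests of the recurrent activation dynamics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tecsim import (
    Connection,
    ConnectionKind,
    Layer,
    LayeredNetwork,
    NetworkParams,
    Unit,
    excitatory_input,
    inhibitory_input,
    output_function,
    run_trial,
    step,
    trial_rng,
    voltage_dependent_input,
)
from conftest import make_chain, make_pair_layer


# ---------------------------------------------------------------------------
# output function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, na, qa, expected",
    [
        (0.0, 2.0, 0.5, 0.0),            # zero numerator
        (0.5, 2.0, 0.5, 0.5),            # a == qa gives half-saturation
        (0.3, 7.0, 0.3, 0.5),            # ... for any exponent
        (1.0, 2.0, 0.5, 0.8),            # 1 / (0.25 + 1)
    ],
)
def test_output_function_values(a, na, qa, expected):
    assert output_function(a, na, qa) == pytest.approx(expected, abs=1e-12)


def test_output_function_strictly_increasing():
    a = np.linspace(0.0, 1.0, 101)
    out = output_function(a, 3.0, 0.4)
    assert np.all(np.diff(out) > 0)
    assert np.all((out >= 0) & (out < 1))


def test_output_function_rejects_negative_activation():
    with pytest.raises(ValueError):
        output_function(-0.1, 2.0, 0.5)


# ---------------------------------------------------------------------------
# per-unit inputs
# ---------------------------------------------------------------------------

def test_excitatory_input_edge_cases(params):
    net = make_chain(params)
    # no afferents, no stimulus -> 0
    assert excitatory_input(net, "s") == 0.0
    # stimulated sensory unit -> Ext only
    assert excitatory_input(net, "s", {"s": params.ext_input}) == params.ext_input
    # one VI edge w=0.6 from a source with known F
    net.set_activation("s", 0.5)
    expected = 0.6 * output_function(0.5, params.na, params.qa)
    assert excitatory_input(net, "f") == pytest.approx(expected, abs=1e-12)


def test_voltage_dependent_input_gating(params):
    net = make_chain(params, with_vd=True)
    net.set_activation("f", 0.9)  # strong top-down source
    # receiver at rest: gated off entirely
    assert voltage_dependent_input(net, "s") == 0.0
    # receiver exactly at the gate boundary A*(1-d_a) == VT: still zero
    net.set_activation("s", params.VT / (1 - params.d_a))
    assert voltage_dependent_input(net, "s") == pytest.approx(0.0, abs=1e-15)
    # receiver above boundary: rescaled positive input
    net.set_activation("s", 1.0)
    gate = (1.0 * (1 - params.d_a) - params.VT) / (1 - params.VT)
    expected = 0.5 * output_function(0.9, params.na, params.qa) * gate
    assert voltage_dependent_input(net, "s") == pytest.approx(expected, abs=1e-12)


def test_voltage_dependent_input_rejects_non_sensory(params):
    net = make_chain(params, with_vd=True)
    with pytest.raises(ValueError):
        voltage_dependent_input(net, "m")


def test_inhibitory_input_from_competitors_only(params):
    net = make_pair_layer(params, n=2)
    # u1's inhibitory pair active: u0 receives negative input, u1 does not
    net.set_activation("u1:inh", 0.6)
    f = output_function(0.6, params.na, params.qa)
    assert inhibitory_input(net, "u0") == pytest.approx(params.w_inh * f, abs=1e-12)
    assert inhibitory_input(net, "u1") == 0.0


# ---------------------------------------------------------------------------
# synchronous update against an independent brute-force oracle
# ---------------------------------------------------------------------------

def oracle_step(units, edges, state, params, stimulus):
    """Pure-dict re-implementation of one synchronous cycle.

    ``units``: id -> dict(layer, polarity, sensory, pair_src or None)
    ``edges``: list of (src, dst, w, kind)
    """
    def F(a):
        return a ** params.na / (params.qa ** params.na + a ** params.na)

    new = {}
    for uid, u in units.items():
        a = state[uid]
        if u["polarity"] == "inhibitory":
            exc = sum(w * F(state[s]) for s, d, w, k in edges
                      if d == uid and k == "PAIR")
            inh = 0.0
        else:
            exc = sum(w * F(state[s]) for s, d, w, k in edges
                      if d == uid and k in ("VI", "LEARNED"))
            vd = sum(w * F(state[s]) for s, d, w, k in edges
                     if d == uid and k == "VD")
            gate = max(a * (1 - params.d_a) - params.VT, 0.0) / (1 - params.VT)
            exc += vd * gate
            exc += stimulus.get(uid, 0.0)
            inh = sum(w * F(state[s]) for s, d, w, k in edges
                      if d == uid and k == "INH")
        val = ((1 - params.d_a) * a
               + params.gamma * (exc * (1 - a) + inh * a))
        new[uid] = min(1.0, max(0.0, val))
    return new


def test_step_matches_bruteforce_oracle(params):
    """5-unit noiseless network: engine trace equals the dict-based recurrence."""
    layers = [Layer("S", "sensory", ("s1", "s2")), Layer("F", "feature", ("f",)),
              Layer("M", "motor", ("m",))]
    units = [Unit("s1", "S", is_sensory=True), Unit("s2", "S", is_sensory=True),
             Unit("s1:inh", "S", polarity="inhibitory"),
             Unit("f", "F"), Unit("m", "M", is_motor=True)]
    conns = [
        Connection("s1", "f", 0.55, ConnectionKind.VI),
        Connection("s2", "f", 0.35, ConnectionKind.VI),
        Connection("f", "m", 0.8, ConnectionKind.LEARNED),
        Connection("f", "s1", 0.45, ConnectionKind.VD),
        Connection("s1", "s1:inh", 0.8, ConnectionKind.PAIR),
        Connection("s1:inh", "s2", -0.7, ConnectionKind.INH),
    ]
    net = LayeredNetwork(layers, units, conns, params)
    stim = {"s1": params.ext_input, "s2": 0.3}

    ounits = {
        "s1": {"polarity": "excitatory"}, "s2": {"polarity": "excitatory"},
        "s1:inh": {"polarity": "inhibitory"},
        "f": {"polarity": "excitatory"}, "m": {"polarity": "excitatory"},
    }
    oedges = [(c.src, c.dst, c.weight, c.kind.value) for c in conns]
    state = {u: 0.0 for u in ounits}

    net.reset()
    for cycle in range(25):
        step(net, stim)
        state = oracle_step(ounits, oedges, state, params, stim)
        for uid in ounits:
            assert net.activation(uid) == pytest.approx(state[uid], abs=1e-12), (
                f"divergence at cycle {cycle}, unit {uid}")


def test_step_decay_and_saturation_limits(params):
    """Isolated unit decays by (1-d_a); a saturated unit ignores excitation."""
    net = make_chain(params)
    net.set_activation("m", 0.5)
    step(net, {})
    assert net.activation("m") == pytest.approx(0.5 * (1 - params.d_a), abs=1e-15)
    # at A=1 the excitatory term is scaled by (1-A)=0: pure decay from 1
    net.reset()
    net.set_activation("s", 1.0)
    net.set_activation("f", 1.0)
    step(net, {"s": 5.0})
    assert net.activation("s") == pytest.approx(1 - params.d_a, abs=1e-12)


def test_decay_closed_form(params):
    """With zero input, activation after k cycles is (1-d_a)^k * A0 exactly."""
    net = make_chain(params)
    a0 = 0.73
    net.set_activation("m", a0)
    for k in range(1, 30):
        step(net, {})
        assert net.activation("m") == pytest.approx(a0 * (1 - params.d_a) ** k,
                                                    rel=1e-14)


def test_no_hallucination_from_top_down_input(params):
    """VD-only input cannot lift a sensory code above VT/(1-d_a) from below."""
    net = make_chain(params, with_vd=True)
    bound = params.VT / (1 - params.d_a)
    for a0 in [0.0, 0.2, bound]:
        net.reset()
        net.set_activation("s", a0)
        net.set_activation("f", 0.95)  # strong top-down source, no Ext anywhere
        for _ in range(60):
            net.A_exc[net._exc_index["f"]] = 0.95  # hold the source active
            step(net, {})
            assert net.activation("s") <= bound + 1e-12


# ---------------------------------------------------------------------------
# boundedness property
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_activations_bounded_for_random_networks(seed):
    """Any random wiring, any noise: all activations stay in [0, 1]."""
    rng = np.random.default_rng(seed)
    n_sens, n_feat = rng.integers(1, 4), rng.integers(1, 4)
    params = NetworkParams(
        d_a=float(rng.uniform(0.01, 0.3)), gamma=float(rng.uniform(0.2, 1.5)),
        na=float(rng.uniform(1, 5)), qa=float(rng.uniform(0.2, 0.7)),
        VT=float(rng.uniform(0.1, 0.8)), noise_sd=float(rng.uniform(0, 0.3)),
        ext_input=float(rng.uniform(0.1, 1.0)), response_threshold=0.9,
        max_cycles=40)
    layers = [Layer("S", "sensory", tuple(f"s{i}" for i in range(n_sens))),
              Layer("F", "feature", tuple(f"f{i}" for i in range(n_feat))),
              Layer("M", "motor", ("m",))]
    units, conns = [], []
    for i in range(n_sens):
        units.append(Unit(f"s{i}", "S", is_sensory=True))
        units.append(Unit(f"s{i}:inh", "S", polarity="inhibitory"))
        conns.append(Connection(f"s{i}", f"s{i}:inh", float(rng.uniform(0, 1)),
                                ConnectionKind.PAIR))
        for j in range(n_sens):
            if i != j:
                conns.append(Connection(f"s{i}:inh", f"s{j}",
                                        -float(rng.uniform(0, 2)),
                                        ConnectionKind.INH))
    for i in range(n_feat):
        units.append(Unit(f"f{i}", "F"))
        for s in range(n_sens):
            conns.append(Connection(f"s{s}", f"f{i}", float(rng.uniform(0, 1)),
                                    ConnectionKind.VI))
            conns.append(Connection(f"f{i}", f"s{s}", float(rng.uniform(0, 1)),
                                    ConnectionKind.VD))
    units.append(Unit("m", "M", is_motor=True))
    for i in range(n_feat):
        conns.append(Connection(f"f{i}", "m", float(rng.uniform(0, 1)),
                                ConnectionKind.LEARNED))
    net = LayeredNetwork(layers, units, conns, params)
    stim = {f"s{i}": params.ext_input for i in range(n_sens)}
    out = run_trial(net, stim, rng=np.random.default_rng(seed + 1))
    assert np.all(out.trace >= 0.0)
    assert np.all(out.trace <= 1.0)


# ---------------------------------------------------------------------------
# winner-take-all and trials
# ---------------------------------------------------------------------------

def test_winner_take_all_with_unequal_input(params):
    """Sustained unequal drive: exactly one unit dominates from some cycle on."""
    net = make_pair_layer(params, n=3)
    stim = {"u0": 0.55, "u1": 0.45, "u2": 0.30}
    net.reset()
    traces = []
    for _ in range(80):
        step(net, stim)
        traces.append([net.activation(f"u{i}") for i in range(3)])
    arr = np.array(traces)
    winners = arr.argmax(axis=1)
    assert winners[-1] == 0
    settle = np.flatnonzero(winners != winners[-1])
    settle_cycle = settle.max() + 1 if len(settle) else 0
    late = arr[settle_cycle:]
    assert np.all(late[:, 0] > late[:, 1]) and np.all(late[:, 0] > late[:, 2])


def test_run_trial_single_route_and_omission(params):
    net = make_chain(params)
    out = run_trial(net, {"s": params.ext_input})
    assert out.winner == "m"
    assert 1 <= out.cycles < params.max_cycles
    assert out.trace.shape == (out.cycles + 1, net.n_units)
    # empty stimulus map: nothing moves, omission at max_cycles
    empty = run_trial(net, {})
    assert empty.omission and empty.winner is None
    assert empty.cycles == params.max_cycles


def test_run_trial_reports_exact_tie(params):
    """Two symmetric motor units crossing together are flagged, not broken."""
    layers = [Layer("S", "sensory", ("s",)), Layer("M", "motor", ("m1", "m2"))]
    units = [Unit("s", "S", is_sensory=True),
             Unit("m1", "M", is_motor=True), Unit("m2", "M", is_motor=True)]
    conns = [Connection("s", "m1", 0.8, ConnectionKind.VI),
             Connection("s", "m2", 0.8, ConnectionKind.VI)]
    net = LayeredNetwork(layers, units, conns, params)
    out = run_trial(net, {"s": params.ext_input})
    assert out.tie
    assert out.winner is None


def test_trial_determinism_bit_identical(params):
    """Identical (network, stimulus, seed) give bit-identical traces."""
    p = NetworkParams(**{**params.__dict__, "noise_sd": 0.05})
    runs = []
    for _ in range(2):
        net = make_pair_layer(p, n=2)
        out = run_trial(net, {"u0": 0.5, "u1": 0.4}, rng=trial_rng(42, 0, 7))
        runs.append(out)
    assert runs[0].cycles == runs[1].cycles
    assert runs[0].winner == runs[1].winner
    assert np.array_equal(runs[0].trace, runs[1].trace)


def test_trace_frame_layout(params):
    net = make_chain(params)
    out = run_trial(net, {"s": params.ext_input})
    frame = out.trace_frame(net)
    assert list(frame.columns) == ["cycle", "unit_id", "layer_id", "activation"]
    assert len(frame) == (out.cycles + 1) * net.n_units
    assert frame.activation.between(0, 1).all()
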