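# Methods

`tecsim` simulates the interaction of perception and action planning with a
localist interactive-activation network in the common-coding (Theory of
Event Coding) tradition. This note documents the model as implemented: its
dynamics, learning rule, task wiring, the packaged experiments, the
parameter calibration, and the limits of what the simulations show.

## Model

### Units and layers

Every cognitive code — a proximal sensory feature ("left tone"), a distal
feature ("Left"), a task option ("T1") or a movement ("M1") — is one
excitatory unit with an activation in [0, 1]. Units are grouped into
layers at four levels:

- **sensory** layers, one per modality/dimension (auditory pitch, auditory
  location, haptic location, ...); only sensory units receive external
  stimulation (and motor units during learning, see below);
- **feature** layers holding distal codes shared by perception and action
  (one "Left" code serves tone location, key location and light location);
- one **task** layer of generic codes T1, T2, ... whose meaning exists
  only in their instruction-wired connections;
- one **motor** layer; a trial ends when a motor unit crosses the response
  threshold.

Each excitatory unit owns one paired inhibitory unit. The pair receives
input exclusively from its excitatory partner and projects negative
weights onto all other excitatory units of the same layer: within-layer
winner-take-all competition. Inhibitory units receive no noise and no
external input.

### Dynamics

All units update synchronously once per cycle:

    A(t+1) = (1 - d_a) · A(t) + γ · [Exc · (1 - A(t)) + Inh · A(t)]

with, for excitatory coding units,

    Exc = Σ_k w⁺_k F(A_k)                (voltage-independent afferents)
        + gate · Σ_k w⁺_k F(A_k)          (voltage-dependent, sensory only)
        + Ext + Noise
    gate = max(A·(1 - d_a) - VT, 0) / (1 - VT)
    Inh = Σ_k w⁻_k F(A_k)                 (competitors' inhibitory pairs)
    F(a) = a^na / (qa^na + a^na)

The voltage-dependent (VD) gate implements top-down modulation without
top-down hallucination: feedback from feature to sensory codes is
discarded until the sensory code's own (decayed) activation exceeds the
voltage threshold VT, so imagining "Left" cannot create a left tone.
The shunting form keeps activations in [0, 1] under non-negative input;
because Gaussian noise can make the net input momentarily negative,
activations are additionally clamped to [0, 1] after each update and clamp
events are counted in the trace (they do not occur at the shipped noise
level in practice).

Noise is drawn independently per excitatory unit per cycle from
N(noise_mean, noise_sd²). Reaction time is the number of cycles from
stimulus onset (external input switches on at cycle 0 and is held
constant) to the first motor-threshold crossing; no mapping from cycles to
milliseconds is attempted. If two motor units cross on the same cycle the
more active wins; an exact tie is reported as a tie, and a trial that
never crosses within `max_cycles` is reported as an omission — neither is
silently resolved.

### Ideomotor learning

Feature→motor weights are the only plastic connections, initialised at 0
(dense: every feature code to every motor code) and updated only during
the learning phase. One learning trial emulates motor babbling: the chosen
motor code is clamped to full activation (`clamp_motor`, the default; an
external-drive mode is available instead, under which competition and
decay also act on the driven unit) until it stands at the response
threshold; its scheduled action effects are then presented by stimulating
the corresponding sensory codes for `effect_cycles` cycles while the motor
drive continues. Clamping is the default because under external drive the
growing learned weights from response features common to both actions let
the idle motor code compete with the driven one late in the trial; with
per-cycle noise this occasionally suppresses the driven code below the
learning threshold and collapses the plastic weights onto a single action. At trial end every
plastic weight is updated synchronously from the end-of-trial activations:

    w(t+1) = (1 - d_w) · w(t) + Act_j · Act_k · (1 - w(t))
    Act = max(0, (A - LT) / (1 - LT))

Only activation above the learning threshold LT counts, so weakly active
codes neither learn nor unlearn beyond ordinary decay; the (1 − w)
shunting bounds weights to [0, 1], and repeated co-activation with
constant Hebbian product c converges to the fixed point c/(d_w + c) — the
weight plateau visible after a dozen trials. End-of-trial activations are
used because effect propagation has converged by then; learning is one-way
(no motor→feature weights exist), and weights are frozen after the
learning phase.

### Task instruction

A task instruction is a set of rules `stimulus features → task code →
response features`. Internalising it wires, per rule: each stimulus
feature to the task code (weight `feature_task`), the task code to each
stimulus and response feature (`task_feature`), and each response feature
back to the task code (`response_task`). All three are plain
voltage-independent weights; re-instructing a model replaces exactly the
feature↔task edges and nothing else, which is what lets one trained
instance be re-instructed (reversal test) without forgetting its action
effects.

The back edge from response features is deliberately weaker than the
stimulus edge. The wiring is bidirectional — response features must be
able to excite their task code, since that recurrence is what lets a mere
instruction ("respond with the keys") enhance key-related sensory
processing during learning — but at equal weights the network develops an
exact structural standoff in every conflict trial: the stimulus-activated
*wrong* location feature supports the wrong task code exactly as strongly
as the relevant stimulus feature supports the correct one, and the
noise-free network deadlocks. A weaker reciprocal edge preserves the
task-set recurrence while letting conflicts resolve in finite time.

## The five experiments

Every experiment runs the same two-phase protocol per group: build the
model with its instruction already wired (task context biases learning),
run 20 alternating learning trials with 50-cycle effect propagation,
optionally re-instruct, then run each condition for n seeded trials
(default 100) and summarise cycles-to-threshold.

1. **Action–effect learning** (`elsner_hommel`): keypresses produce tones
   during learning; at test the tones are imperative stimuli mapped either
   compatibly (non-reversal) or incompatibly (reversal) to the keys.
2. **Response–effect compatibility** (`kunde`): groups differ only in the
   effect schedule — press force and effect-tone loudness match or
   mismatch; shared intensity features make consistent effects learn
   stronger anticipations.
3. **Simon task** (`simon`): tone pitch instructs a left/right key; the
   tone's irrelevant location shares the location features with the keys.
4. **Stroop task** (`stroop`): generated from the Simon spec by a literal
   code renaming (ink colour ↔ pitch, word ↔ location, speech ↔ key);
   the two models are isomorphic and, under matched seeds, produce
   identical numbers.
5. **Inverted Simon task** (`hommel_inversion`): keypresses flash a light
   on the opposite side; instruction frames the identical movements as
   key presses or as light flashes, which flips which location features
   dominate action-effect learning and thereby the direction of the
   compatibility effect. Anatomical-location coding, which breaks the
   key/light symmetry in humans, is explicitly not modelled, so the two
   groups are exact mirror images in the simulator.

Neutral conditions present the task-relevant dimension only (no
lateralised input); this is a modelling choice, as the source experiments
report neutral means without describing the stimulus construction.

## Parameters and calibration

All parameters are global across layers and shared by all five model
instances. The shipped defaults were calibrated in-house — the printed
per-condition mean cycle counts of the five experiments are the
calibration targets, with hard constraints that every effect ordering is
reproduced, every trial ends in the correct response, and no omissions or
ties occur at the shipped noise level. The calibration ran a staged random
search (Simon-task screen, then joint scoring of all experiments, then
local refinement under noise) over: decay `d_a`, gain `γ`, output
nonlinearity `(na, qa)`, voltage threshold `VT`, external input, response
threshold, pair/inhibition weights, the four hand-set connection weight
defaults, the response→task back weight, and the learning parameters
`(d_w, LT)`. `calibrate_params` exposes the ordering-constrained search as
a library function.

Two regions of parameter space proved structurally important:

- the output knee `qa` must sit above the activation a unit reaches from
  weak or indirect input, or paired inhibitory units amplify noise-level
  activity into full suppression (every near-tie then strangles both
  competitors);
- the decay `d_a` must be fast enough that inhibitory units track their
  partner instead of integrating weak drive to saturation.

Sharpness `na` ≈ 5 around that knee is what converts the small top-down
task bias into a decisive winner-take-all outcome while leaving
sub-threshold codes inert.

`noise_sd` is set so that the per-condition SD of cycle counts is small
relative to the between-condition differences; it mainly supplies
trial-to-trial variance rather than changing the means.

Shipped defaults (units: activation/input levels are dimensionless in
[0, 1]; rates are per cycle; weights are connection strengths):

| parameter | value | role |
|---|---|---|
| `d_a` | 0.082 | activation decay rate |
| `gamma` | 0.30 | global input gain |
| `na`, `qa` | 6.05, 0.594 | output sigmoid exponent / knee |
| `VT` | 0.385 | voltage threshold for top-down input |
| `noise_sd` | 0.01 | per-unit per-cycle Gaussian input noise |
| `ext_input` | 0.991 | external stimulation magnitude |
| `response_threshold` | 0.711 | motor activation ending a trial |
| `max_cycles` | 250 | omission cap |
| `w_exc_inh` | 0.752 | excitatory unit → its inhibitory pair |
| `w_inh` | −0.698 | inhibitory pair → layer competitors |
| `sensory_feature` | 0.506 | bottom-up sensory → feature |
| `feature_sensory` | 0.910 | top-down feature → sensory (VD) |
| `feature_task` | 0.720 | stimulus feature → task |
| `task_feature` | 0.944 | task → feature (both roles) |
| `response_task` | 0.263 | response feature → task back edge |
| `d_w` | 0.082 | weight decay per learning trial |
| `LT` | 0.482 | learning threshold |

Hand-set sensory↔feature weights default to the global values above but
are overridable per link in a model spec, standing for long-term
perceptual experience. One such override ships: the imperative colour-cue
links of the response-effect-compatibility model are set to 0.6, treating
the colour channel as a strongly practised one; colour layers exist in no
other model instance.

The calibration is a compromise: under one global set the spread between
the fastest (facilitated) and slowest (conflict) conditions comes out
somewhat compressed relative to the published simulations — conflict
conditions resolve a few cycles early and pure task-route conditions run
a few cycles late. Enlarging the spread requires running conflict winners
closer to their activation asymptote, which makes trials omission-prone
under noise; the shipped set prefers the omission-free, seed-stable
operating point. `scripts/acceptance.py` recomputes every reported
condition mean so the match can be inspected directly.

## What the simulations do and do not show

The experiments are self-contained synthetic paradigms: the package
generates all its own inputs (stimuli are binary external-input patterns;
there is no real psychophysical data anywhere). Passing the packaged
checks shows that the architecture reproduces the *directions* and
approximate magnitudes of the published compatibility effects from one
shared parameter set — not that it fits human RT distributions (explicitly
out of scope), predicts error rates, or generalises beyond two-choice
tasks. Known limitations, inherited from the modelled architecture: no
feature binding (two objects with interchangeable features cannot be kept
apart), no conflict monitoring or performance feedback, no episodic
memory, single one-shot actions only, and localist one-unit-per-code
representation throughout.

Numerical notes: trials are capped at `max_cycles` = 250 cycles;
condition means are computed over non-omission trials with omissions
reported alongside (a warning fires above 10%). Because motor codes are
driven alternately during learning, the last-updated motor's weights have
decayed one trial less — a deliberate consequence of applying the decay
term to all weights on every learning trial, visible as a cycle or two of
asymmetry between mirror-image stimulus variants. Per-trial RNG streams
are derived from (experiment seed, group index, stream, trial index), so
any condition or trial is reproducible in isolation and bit-identical
across runs.
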