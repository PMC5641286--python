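# tecsim

A connectionist simulator of the interaction between perception and action
planning, in the common-coding tradition of the Theory of Event Coding
(TEC). `tecsim` is for cognitive modellers who want to study
stimulus–response compatibility phenomena — the Simon effect, its
task-instruction-driven inversion, Stroop-like interference,
action–effect learning — as emergent dynamics of one recurrent localist
network rather than as fits of paradigm-specific dual-route models.

## The model in brief

Codes are localist units with activation `A ∈ [0, 1]`, organised in
sensory, feature, task and motor layers, updated synchronously:

    A(t+1) = (1 − d_a)·A(t) + γ·[Exc·(1 − A(t)) + Inh·A(t)]

Excitatory input sums voltage-independent afferents `Σ w⁺ F(A)`
(`F(a) = a^na / (qa^na + a^na)`), voltage-dependent top-down feedback to
sensory units — gated by `max(A(1 − d_a) − VT, 0)/(1 − VT)`, so imagery
cannot ignite a percept — plus external stimulation and Gaussian noise.
Each unit's paired inhibitory partner projects negative weights within its
layer (winner-take-all). Reaction time is simulated as cycles from
stimulus onset until a motor unit crosses the response threshold.

Feature→motor associations are not wired but *learned* by motor babbling
under a thresholded Hebbian rule with decay,

    w(t+1) = (1 − d_w)·w(t) + Act_j·Act_k·(1 − w(t)),
    Act = max(0, (A − LT)/(1 − LT)),

so actions come to be represented by their perceivable effects
(ideomotor learning). Task instructions are internalised as plain wiring
between feature codes and generic task codes (T1, T2, …), which both
routes stimulus information to responses and top-down enhances
task-relevant sensory processing — including during learning, which is
what makes response coding instruction-dependent.

See `docs/methods.md` for the full account, including numerical choices
and limitations.

## Worked example

```python
import tecsim as ts

exp = ts.experiment_spec("simon", n_trials=100, seed=0)
result = ts.run_experiment(exp)
print(result.summaries[["condition", "mean_cycles", "sd_cycles", "omissions"]]
      .to_string(index=False))
```

prints (exact values for seed 0)

```
   condition  mean_cycles  sd_cycles  omissions
  compatible        19.50   0.502519          0
     neutral        28.25   0.435194          0
incompatible        37.64   8.739230          0
```

Each row is one Simon-task condition after the model has learned its
action effects in 20 motor-babbling trials: mean cycles-to-threshold over
100 seeded trials is the simulated reaction time. Location-compatible
tones are answered fastest (19.5 cycles); location-incompatible tones
activate the wrong response through the shared location features and cost
roughly twice the compatible time (37.6 cycles) while top-down task wiring
competes that activation away — the classic Simon pattern, with the
neutral condition in between. The large incompatible SD reflects how
close the conflict trials run to the decision boundary: resolution time
varies strongly with the per-cycle noise.

The `examples/` directory holds one short narrative script per
capability (single-trial dynamics, learning curves, each experiment, and
building a custom model spec); each prints what it computes and what the
numbers mean. A thin CLI covers shell use:

    tecsim run --experiment simon --trials 100 --seed 0 --out results/
    tecsim trace --experiment simon --condition incompatible --trial 0
    tecsim calibrate --space space.yaml

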