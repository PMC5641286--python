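"""Motor babbling: how action-effect associations are acquired.

Runs the learning phase of the action-effect experiment (keypresses produce
tones) and prints the plastic feature->motor weight trajectory. Weights
from the features describing an action's own effects grow and plateau
(the per-trial decay balances the Hebbian gain); weights from unrelated
features stay near zero.
"""

import tecsim as ts

exp = ts.experiment_spec("elsner_hommel")
spec = exp.groups[0].spec
net = ts.build_model(spec)
history = ts.learning_phase(net, spec.effects, spec.learning, seed=0)

final = net.learned_weights()
print("final feature->motor weights after 20 learning trials:")
for (src, dst), w in sorted(final.items(), key=lambda kv: -kv[1]):
    bar = "#" * int(40 * w)
    print(f"  {src:>6s} -> {dst}: {w:5.3f} {bar}")

print("\nweight of 'Low'->M1 over M1's own learning trials:")
own = history[(history.src == "Low") & (history.dst == "M1")
              & (history.motor == "M1")]
for _, row in own.iterrows():
    print(f"  trial {int(row.trial):2d}: {row.weight:5.3f}")

print("""
M1 presses the left key and produces the low tone, so 'Left' and 'Low'
(and the generic 'Key'/'Sound' codes) become its learned anticipations;
the trajectory rises steeply at first and flattens as the weight decay
balances further gains — more learning trials would change little.""")
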