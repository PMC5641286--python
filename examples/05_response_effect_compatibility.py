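"""Response-effect compatibility: effect consistency shapes action planning.

Two groups learn with identical wiring but different action-effect
schedules: for one, press force and effect-tone loudness match (forceful
press -> loud tone); for the other they mismatch. Consistent effects drive
the same intensity feature from two senses, yielding stronger action-effect
weights and faster responding at test.
"""

import tecsim as ts

exp = ts.experiment_spec("kunde", n_trials=100, seed=0)
result = ts.run_experiment(exp)
print(result.summaries.to_string(index=False))

df = result.summaries.set_index("group")
diff = df.loc["inconsistent", "mean_cycles"] - df.loc["consistent", "mean_cycles"]
print(f"\nresponse-effect compatibility cost: {diff:.1f} cycles")

print("\nlearned intensity->motor weights per group:")
for group in ("consistent", "inconsistent"):
    w = result.networks[group].learned_weights()
    own = w[("Forceful", "M1")]
    print(f"  {group:>12s}: Forceful->M1 = {own:.3f}")
print("""
The effect is carried entirely by the learning phase: inconsistent effect
tones activate the competing intensity feature during learning, so the
action's anticipation codes end up weaker and response selection at test
is slower.""")
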