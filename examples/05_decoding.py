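"""Decoding the behavioral state of the interacting male.

Trains a decision tree on each sequence's latency and interaction
duration to predict whether the male partner was the aggressor or the
aggressed, over repeated unstratified 75/25 splits, and compares against
the temporally randomized control in which trigger times are redrawn.
"""

from baitswitch.decoding import decode, randomize_triggers, state_feature_table
from baitswitch.interactions import detect_interactions
from baitswitch.sequences import extract_triggered_sequences
from baitswitch.synthetic import GeneratorParams, generate_recording

rec, _ = generate_recording(
    GeneratorParams(seed=5, duration_s=2400, n_aggressive_events=150,
                    n_walks=0, n_investigations=0)
)
si = detect_interactions(rec, "opposite_sex")
seqs = extract_triggered_sequences(rec, si, "aggression")

observed = decode(state_feature_table(seqs), "tree", n_iterations=500, seed=1)
print(f"observed:   mean accuracy {observed.mean:.1f}% "
      f"(chance {observed.chance_pct:.0f}%), z = {observed.z:.2f}")

rand = randomize_triggers(rec, "aggression", seed=2)
rand_seqs = extract_triggered_sequences(rand, si, "aggression")
restored = decode(state_feature_table(rand_seqs), "tree", n_iterations=500, seed=3)
print(f"randomized: mean accuracy {restored.mean:.1f}%, z = {restored.z:.2f}")
# Observed decoding is far above chance because aggressed males approach
# females sooner and more briefly; breaking the temporal link between
# triggers and interactions returns accuracy to ~50%.
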