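"""Simulate a 10-minute group recording and detect social interactions.

Generates poses for 2 males + 2 females at 30 fps, then finds every bout
in which a male's and a female's social ellipses (body ellipse extended
3 cm fore and aft) overlap for at least six consecutive frames, and who
initiated each bout.
"""

from collections import Counter

from baitswitch.interactions import detect_interactions
from baitswitch.synthetic import GeneratorParams, generate_recording

rec, truth = generate_recording(GeneratorParams(seed=1))
print(f"recording: {rec.n_frames} frames, {len(rec.events)} labeled events")

si = detect_interactions(rec, pair_filter="opposite_sex")
durations = [s.duration_s(rec.fps) for s in si]
initiators = Counter(
    "male" if s.initiator.startswith("M") else
    "female" if s.initiator.startswith("F") else "mutual"
    for s in si
)
print(f"male-female interactions: {len(si)}")
print(f"mean duration: {sum(durations)/len(durations):.2f} s (minimum 6 frames = 0.2 s)")
print(f"initiators: {dict(initiators)}")
# Males initiate essentially all bouts here: the generator scripts male
# approaches toward briefly pausing females, mirroring the male-driven
# onset of post-aggression interactions.
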