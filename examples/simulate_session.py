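"""Generate a synthetic cued-eyeblink EEG session and inspect it.

The generator emulates an artifact-acquisition protocol: a beep every 5 s
cues the participant to blink, on top of background brain activity.  The
ground truth (sources, mixing, event times) is returned with the recording.
"""

import numpy as np

from icfp import SimulationConfig, simulate

cfg = SimulationConfig(
    montage_size=32,
    fs=256.0,
    duration_s=60.0,
    artifact_types=("eyeblink",),
    seed=7,
)
rec, truth = simulate(cfg)

print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples @ {rec.fs} Hz")
from collections import Counter

print(f"sources:   {dict(Counter(truth.source_labels))}")
events = truth.event_times["eyeblink"]
print(f"blink cues at {events[:4]} ... ({events.size} total, every {cfg.blink_interval_s} s)")

blink = truth.sources_of("eyeblink")[0]
frontal = int(np.argmax(truth.mixing[:, blink]))
c = int(events[0] * cfg.fs)
peak = np.abs(rec.data[frontal, c - 30 : c + 30]).max()
quiet = np.abs(rec.data[frontal, c + 300 : c + 360]).max()
print(f"frontal channel {rec.montage.labels[frontal]}: "
      f"{peak:.0f} uV at the first cue vs {quiet:.0f} uV between cues")
print("-> the cued blink deflection dwarfs ongoing background activity,")
print("   as in a real artifact-training acquisition.")
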