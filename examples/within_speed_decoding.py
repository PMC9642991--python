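"""Decode edge orientation from one neuron's responses at a single speed.

An ideal observer classifies each held-out trial among the four edge
orientations (chance 25%) from either the response intensity (peak or mean
firing rate) or the firing-rate profile.  Profiles carry far more orientation
information than intensities, because orientation mostly restructures the
spike train rather than changing how much the neuron fires.
"""

from edgecode import SimConfig, generate_dataset, segment_trials
from edgecode.classify import (
    intensity_classify_within,
    intensity_signals,
    profile_classify_within,
    profile_signals,
)

records, _ = generate_dataset(SimConfig(n_fa=1, n_sa=0, seed=3))
trials = segment_trials(records[0])
speed = 30.0

peak = intensity_signals(trials, "peak")
mean = intensity_signals(trials, "mean")
prof = profile_signals(trials, "temporal")

print(f"neuron {records[0].neuron_id} at {speed:g} mm/s, 60 held-out decisions each:")
for name, result in [
    ("peak firing rate ", intensity_classify_within(peak, speed)),
    ("mean firing rate ", intensity_classify_within(mean, speed)),
    ("rate profile     ", profile_classify_within(prof, speed)),
]:
    print(f"  {name}: {result.accuracy:.2f} correct (chance {result.chance})")
print("the profile decoder, which sees the sequential structure of the spike")
print("train, outperforms both intensity decoders.")
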