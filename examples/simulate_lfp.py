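"""Simulate a cue-conditioned multi-trial LFP-like dataset.

Builds a stable neural-field ensemble on a 2 mm patch, simulates a small
delayed-response session with six cue angles, and prints basic summaries.
"""

import numpy as np

from engramfield.synthetic import GeneratorConfig, simulate_recording

cfg = GeneratorConfig(
    n_trials=12,
    n_channels=16,
    delay_ms=300.0,
    master_seed=7,
)
rec = simulate_recording(cfg)

print(f"data shape (trials x channels x time): {rec.data.shape}")
print(f"cue angles: {sorted(set(rec.cue_angles))}")
print(f"signal RMS: {np.sqrt(np.mean(rec.data**2)):.4f} (potential units)")
print(f"per-channel spacing: {np.diff(rec.channel_positions_mm)[0]*1000:.0f} um")
# The RMS is the size of noise-driven fluctuations around the zero
# baseline; the cue adds a small angle-dependent spatial bump on top.
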