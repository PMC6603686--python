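"""Extract the 14 per-beat features from a simulated record.

Assembles beats (R-peak + pulse landmarks + ABP references), computes the
feature vector per beat — transit times PTTb/PTTa/PTTc, the K value, heart
rate, and the nine waveform-shape quantities — and min-max normalizes the
table. The printed means sit in the middle of each feature's physiological
range; the definitional identities Tupr+Tdownr=1 and S1+S2=1 hold row by
row.
"""

import numpy as np

from pttbp import SimConfig, annotate_beats, extract_features, minmax_normalize, simulate_subject

# per-beat variation in rate, transit delay and pressure, as in real data
rng = np.random.default_rng(2)
nb = 80
record, _ = simulate_subject(
    SimConfig(duration_s=60.0,
              hr_bpm=72.0 + 6.0 * rng.standard_normal(nb),
              ptt_s=0.22 + 0.04 * rng.random(nb),
              sbp_mmhg=112.0 + 12.0 * rng.random(nb),
              dbp_mmhg=72.0 + 8.0 * rng.random(nb),
              seed=2)
)
beats = annotate_beats(record)
dataset = extract_features(beats, record.ppg, record.fs)

print(f"{len(dataset)} beats x {dataset.features.shape[1]} features")
print(dataset.features.mean().round(3).to_string())
print(f"labels: SBP {dataset.labels['SBP'].mean():.1f} mmHg, "
      f"DBP {dataset.labels['DBP'].mean():.1f} mmHg")
f = dataset.features
print(f"max |Tupr+Tdownr-1| = {np.max(np.abs(f['Tupr']+f['Tdownr']-1)):.2e}, "
      f"max |S1+S2-1| = {np.max(np.abs(f['S1']+f['S2']-1)):.2e}")

normalized, scaler = minmax_normalize(dataset)
print(f"after min-max scaling: per-feature min {normalized.features.min().min():.1f}, "
      f"max {normalized.features.max().max():.1f}")
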