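"""Neuronal stimulus encoding: fixed-window and sliding-window d'.

Builds a small population, sums the units into a population count
series, and measures how well post-stimulus spike counts separate from
pre-stimulus counts (AUROC -> d' = sqrt(2) Z(AUROC)).  The sliding trace
peaks near the evoked-kernel latency (~40 ms).
"""

import numpy as np

from whisksel import SynthConfig, fixed_window_dprime, sliding_dprime
from whisksel.spikes import BinnedCounts
from whisksel.synth import simulate_population_counts

cfg = SynthConfig(n_units=8, seed=5, excitatory_fraction=1.0)
target_counts, distractor_counts, gt = simulate_population_counts(
    cfg, n_trials_per_stim=200
)


def binned(counts):
    return BinnedCounts(counts=counts, window=(-0.1, 0.1), bin_s=0.005,
                        trial_index=np.arange(counts.shape[0]))


pop_target = binned(target_counts.sum(axis=0))
pop_distractor = binned(distractor_counts.sum(axis=0))

for name, pop in [("target", pop_target), ("distractor", pop_distractor)]:
    fixed = fixed_window_dprime(pop)
    print(f"population {name}-stimulus encoding: AUROC {fixed.auroc[0]:.3f}, "
          f"d' {fixed.dprime[0]:.2f}")

sliding = sliding_dprime(pop_target)
print(f"\nsliding-window d' peaks at {sliding.peak_time_s() * 1e3:.0f} ms "
      f"post-stimulus (d' = {sliding.dprime.max():.2f})")
print("window-start (ms) vs d':")
for s, d in zip(sliding.window_start_s[::4], sliding.dprime[::4]):
    print(f"  {s * 1e3:5.0f}  {d:6.2f}")

print("\nthe preferred (contralateral) stimulus drives a short-latency"
      "\ntransient; the 20 ms windows localize it to ~40 ms, matching the"
      "\ngenerator's evoked-kernel latency.")
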