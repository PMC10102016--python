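"""Population selectivity and the rotation-vs-shift contrast.

Each unit contributes a (preferred d', unpreferred d') pair.  With the
light off the generator couples the two weakly; with the light on the
coupling strengthens (suppressing the gating region lets distractor
responses through).  The linear-fit slope CIs of the two conditions are
disjoint: a selectivity "rotation", not a uniform shift.
"""

import numpy as np
import pandas as pd

from whisksel import SynthConfig, fit_selectivity, gating_model_contrast, unit_selectivity
from whisksel.spikes import BinnedCounts
from whisksel.synth import simulate_population_counts

cfg = SynthConfig(
    n_units=200, selectivity_slope=-0.05, selectivity_slope_on=0.45,
    excitatory_fraction=1.0, seed=77,
)


def binned(counts):
    return BinnedCounts(counts=counts, window=(-0.1, 0.1), bin_s=0.005,
                        trial_index=np.arange(counts.shape[0]))


fits = {}
for opto in ("off", "on"):
    tgt, dst, _ = simulate_population_counts(cfg, 150, opto=opto, seed=cfg.seed)
    rows = []
    for u in range(cfg.n_units):
        pref, unpref = unit_selectivity(binned(tgt[u]), binned(dst[u]), "target")
        rows.append({"unit_id": f"u{u:03d}", "dprime_preferred": pref,
                     "dprime_unpreferred": unpref})
    fits[opto] = fit_selectivity(pd.DataFrame(rows), opto)
    f = fits[opto].fit
    print(f"light-{opto}: slope {f.slope:+.3f} "
          f"(95% CI {f.slope_ci[0]:+.3f} to {f.slope_ci[1]:+.3f}), "
          f"n = {f.n} units")

contrast = gating_model_contrast(fits["off"], fits["on"])
print(f"\ngating-model verdict: {contrast.verdict}")
print("disjoint slope CIs with overlapping center heights mean the light"
      "\nre-couples distractor to target encoding across units (rotation)"
      "\nrather than displacing every unit equally (shift).")
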