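"""Validate both estimators on synthetic data with known ground truth."""

import numpy as np

from hetfix import (
    CultureSimConfig,
    LabelingSimConfig,
    fixation_rate,
    mfi_point,
    simulate_culture_pair,
    simulate_labeling,
)

# Flux index: truth b/a = 0.13, 10 % multiplicative noise, 100 samples.
cfg = LabelingSimConfig(b_over_a=0.13, noise_cv=0.10, n_replicates=100, seed=1)
vals = [mfi_point(m.x_unlabeled, m.y_labeled, cfg.alpha).mfi for m in simulate_labeling(cfg)]
print(f"flux index: truth 0.130, recovered {np.mean(vals):.3f} "
      f"(sd {np.std(vals, ddof=1):.3f}, n = {len(vals)})")

# Fixation rate: truth 20 mg/L/h, 5 % noise, 200 simulated culture pairs.
rates = []
for s in range(200):
    pair = simulate_culture_pair(
        CultureSimConfig(true_rate_mg_L_h=20.0, noise_cv=0.05, n_replicates=10, seed=s)
    )
    rates.append(fixation_rate(*pair).volumetric_rate_mg_per_L_h)
print(f"fixation rate: truth 20.0, recovered {np.mean(rates):.1f} "
      f"(sd {np.std(rates, ddof=1):.1f}, n = {len(rates)} pairs)")
print("Unbiased recovery shows the estimators invert their own models;")
print("the per-pair spread is the intrinsic noise of the paired balance.")
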