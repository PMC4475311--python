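"""Estimate the CO2-fixation flux index from labeled/unlabeled 3PGA pools.

Builds a handful of isotopologue measurements for a bypass-carrying strain
over an induction time course, estimates the basal labeling ratio from
isotope-free controls, and prints the flux index per timepoint.
"""

from hetfix import (
    IsotopologueMeasurement,
    estimate_basal_ratio,
    forward_pool_ratio,
    mfi_series,
)

# Isotope-free controls: label at the natural-abundance level only.
controls = [
    IsotopologueMeasurement(f"ctrl{i}", "empty-vector", 0.0, 100.0, y)
    for i, y in enumerate([3.41, 3.47, 3.47])
]
basal = estimate_basal_ratio(controls)
print(f"basal labeling ratio alpha = {basal.alpha:.4f} "
      f"(sd {basal.dispersion:.4f}, n = {basal.n_samples})")

# A fixing strain whose bypass/central flux ratio ramps 0.07 -> 0.13 -> 0.12
# with enzyme expression (pools constructed from the forward model).
samples = [
    IsotopologueMeasurement(f"fix_t{t}", "RBC-PRK", t, 100.0,
                            100.0 * forward_pool_ratio(1.0, b, basal.alpha))
    for t, b in [(3.0, 0.07), (6.0, 0.13), (13.0, 0.12)]
]
table = mfi_series(samples, basal)
print(table.to_string(index=False))
print("mfi_mean is the bypass-to-central flux ratio b/a: 0.13 at 6 h means")
print("the CO2-fixing bypass carries 13 % of the central-pathway flux.")
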