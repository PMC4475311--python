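# hetfix

Quantitative analysis of **heterotrophic CO2 fixation** — for metabolic
engineers who put a Calvin-cycle bypass (phosphoribulokinase + Rubisco)
into a sugar-eating microbe and want to know how much CO2 it actually
fixes.

Metabolites made by the bypass are chemically identical to those made by
central metabolism, so fixation cannot be read off a concentration. This
package implements the two estimators that solve that problem, plus the
supporting analyses:

* **Flux index from isotope labeling** (`hetfix.isotope_flux`). Feed
  `13C`-bicarbonate and quantify the unlabeled (*x*) and single-`13C`
  (*y*) pools of 3-phosphoglycerate, the metabolite where the bypass
  rejoins glycolysis. At steady state the bypass/central flux ratio is

  ```
  MFI = b/a = ((1-α)·y - α·x) / ((1+α)·x - (1-α)·y)
  ```

  where α is the basal (natural-abundance) labeling ratio measured in
  isotope-free medium (default 0.0345). MFI = 0.13 means the bypass
  carries 13 % of the central-pathway flux.

* **Fixation rate from a paired carbon balance**
  (`hetfix.carbon_balance`). Compare a fixing strain against a
  deactivated-enzyme control grown identically. With recovery fraction
  *f* = 0.96 of sugar carbon into biomass + CO2, consumed xylose carbon
  Cx and biomass B (primes: control),

  ```
  C_fixed = f·Cx'·(B/B') - f·Cx      [mmol C / L]
  ```

  The unknown specific CO2-secretion constant cancels between the paired
  strains. Volumetric rate = C_fixed · 44.01 / duration (mg CO2 L⁻¹ h⁻¹);
  specific rate divides by test biomass.

* **Carbonate speciation** (`hetfix.carbonate_speciation`):
  [HCO3⁻]/[CO2] = 10^(pH − pKa), pKa 6.35 — why a bicarbonate transporter
  alone barely raises Rubisco's substrate while carbonic anhydrase does.

* **Autotroph benchmark** (`hetfix.benchmark`): a packaged table of
  published fixation rates for 14 autotrophic microbes and 3 engineered
  heterotrophs, with recomputed specific rates and summary statistics.

* **Synthetic data** (`hetfix.synthetic_data`): generators that draw
  labeling measurements and matched culture pairs from the exact models
  the estimators invert, so everything is testable end to end with known
  ground truth.

## Worked example

```python
from hetfix import CultureObservation, fixation_rate

test = CultureObservation("RBC-PRK", consumed_xylose_mmol_per_L=13.7,
                          biomass_gDCW_per_L=0.82, duration_h=24.0)
control = CultureObservation("RBC197-PRK2021", consumed_xylose_mmol_per_L=29.8,
                             biomass_gDCW_per_L=1.59, duration_h=24.0)
res = fixation_rate(test, control)
print(f"{res.fixed_carbon_mmolC_per_L:.2f} mmol C/L, "
      f"{res.volumetric_rate_mg_per_L_h:.1f} mg CO2/L/h, "
      f"{res.specific_rate_mg_per_gDCW_h:.1f} mg CO2/g DCW/h")
```

prints

```
8.01 mmol C/L, 14.7 mg CO2/L/h, 17.9 mg CO2/g DCW/h
```

i.e. over 24 h this culture fixed 8 mmol of CO2 carbon per litre — a
volumetric rate of ~15 mg CO2 L⁻¹ h⁻¹, inside the published 13.3 ± 3.2
for this strain pair — and ~18 mg per gram of dry cells per hour. More
narrative scripts live in `examples/` (flux index from pools, speciation,
benchmark placement, synthetic-recovery validation).

A thin CLI wraps the same functions:

```
hetfix speciate --ph 7.5
hetfix mfi --input isotopologues.csv --controls controls.csv --out mfi.csv
hetfix rate --cultures cultures.csv --method per-replicate
hetfix benchmark --add-strain mine,19.6,0.87
hetfix simulate fixtures --seed 1 --out fixtures/
```

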