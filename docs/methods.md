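# Methods

## The labeling model behind the flux index

A strain carrying the phosphoribulokinase/Rubisco bypass makes
3-phosphoglycerate (3PGA) two ways: *a* mol per unit time from central
metabolism (unlabeled carbon, from sugar) and *b* mol from the bypass,
each of which incorporates one `13C` atom when the medium is fed with
`13C`-bicarbonate. Natural `13C` abundance couples the pools: a fraction
α of nominally unlabeled 3PGA appears in the single-`13C` form, so
production of the labeled species is `b + α(a+b)` and of the unlabeled
species `(1−α)(a+b)`. Downstream consumption removes both species in
proportion to their pool sizes, so at metabolic steady state the measured
pool ratio `y/x` equals the production ratio. Inverting gives the
estimator

    MFI = b/a = ((1−α)y − αx) / ((1+α)x − (1−α)y).

Assumptions worth keeping in mind: a true steady state over the sampling
window; a single `13C` species (multi-labeled isotopologues are not
modeled — correct for the single Rubisco carboxylation, would
under-count if label recycled through the pentose-phosphate pool);
and α measured at the **molecule** level in isotope-free medium rather
than derived from per-atom abundance (3 carbons × ~1.1 % per atom would
predict ~3.3 %, close to the measured 3.45 % used as default).

Properties the implementation guarantees (and the tests check): exact
inversion of the forward model; scale invariance in (x, y); zero crossing
exactly at `y/x = α/(1−α)`; saturation (`valid=False`) exactly at
`y/x ≥ (1+α)/(1−α)`. Below-basal samples yield a *negative* index flagged
`below_basal` rather than being clamped, so control strains scatter
around zero without bias.

### Coefficient rounding

The two-decimal coefficient form `(0.97y − 0.03x)/(1.03x − 0.97y)` is the
rounding of the exact coefficients at α = 3.45 %. It overstates the index
by roughly 5 % relative (0.137 vs 0.130 on the same pools), so the exact
form is the default and `mode="paper_rounded"` exists only for literal
reproduction of previously published values.

### Aggregation and comparison

`mfi_series` computes the index per sample and then averages within
(strain, timepoint) groups — not index-of-averaged-pools — which matches
replicate error propagation and keeps per-sample scale invariance.
Saturated samples are excluded from group means (logged), not allowed to
poison them. Published time courses do not state whether error bars are
sd or se nor the per-point n; we report sample sd and n explicitly.
Group comparison uses the equal-variance two-sample t-test (Student), with
Welch behind a flag.

## The paired carbon balance

For the control (non-fixing) strain, a measured fraction f = 0.96 of
consumed sugar carbon is recovered as biomass plus released CO2, and CO2
release is proportional to biomass with a strain-intrinsic specific
secretion constant. Because the bypass branches off upstream glycolysis,
the test strain shares that constant; writing both balances and
eliminating it leaves

    C_fixed = f·Cx′·(B/B′) − f·Cx   (mmol C per litre),

with Cx consumed xylose carbon (5 C per xylose) and B biomass. Biomass
enters only as the ratio B/B′, so the gC-per-gDCW conversion cancels and
the estimator runs on g DCW directly; supplying a carbon fraction must
not (and does not) change the result. CO2 mass uses 44.01 mg/mmol.
Durations must match between the pair; negative fixed carbon is returned
as "no detectable fixation" rather than clamped, preserving linearity.

Three uncertainty modes: `means` (summary fields), `per_replicate`
(rate per matched replicate pair, then mean ± sd — the faithful mode when
replicate data exist, since published per-replicate rates are generally
not recoverable from printed means), and `monte_carlo` (independent
normals truncated at zero on the four inputs, default seed 20150618,
reported mean ± sd). Note the estimator is intrinsically noisy: it is a
small difference of two large carbon terms, so percent-level measurement
error produces tens-of-percent rate error per pair — consistent with the
±25 % spreads published for triplicate flask cultures.

## Carbonate speciation

`[HCO3−]/[CO2] = 10^(pH − pKa)` with apparent pKa 6.35 (first
dissociation only; carbonate is negligible at pH ≤ 8; no temperature or
ionic-strength correction). The reciprocal, as a percentage, is the CO2
increment per unit bicarbonate increment — the quantitative reason a
bicarbonate transporter alone under-delivers CO2 to Rubisco at pH 7.5
(ratio ~14, increment ~7 %).

## Synthetic data: what it emulates and what it does not

`simulate_labeling` draws pools exactly on the steady-state production
ratio and multiplies x and y by independent lognormal factors with mean 1
and a configured CV (concentrations are positive; LC-MS error is
approximately proportional). It does **not** model pool-filling kinetics,
induction dynamics (the expression ramp is a fixture convenience mapping
time to a bypass-flux multiplier), correlated noise between channels, or
multi-labeled species. Default CV 5 % with triplicates; real LC-MS/MS
noise for these metabolites is not published, so recovery results
quantify estimator behavior under the stated noise, not instrument truth.

`simulate_culture_pair` parameterizes secretion as the dimensionless
ratio ρ = secreted CO2 carbon / biomass carbon (default 1.25, which
reproduces a control consuming 29.8 mmol/L xylose reaching 1.59 g DCW/L
at 0.48 gC/gDCW) instead of a specific rate in mmol g⁻¹ h⁻¹ — this
avoids the growth-integral ambiguity of substituting a specific rate into
a cumulative balance, and since the estimator eliminates the secretion
term either way, recovered rates are provably independent of ρ and of the
carbon fraction (tested to 1e-12 relative). Zero-noise pairs close the
balance exactly, so the simulator doubles as the estimator's oracle.

## Problem sizes and tolerances in the validation studies

* Flux-index recovery: truth 0.13, noise CV 10 %, n = 100 samples, mean
  within 5 % relative. The per-sample index sd under these conditions is
  ~0.027 (≈20 % relative), and multiplicative noise adds a small positive
  O(CV²) bias, so the 5 % band is ~2 se wide of comfortable.
* Control behavior: no bypass flux, α = 0.0345, CV 10 %, n = 100; the
  index distribution is centered at 0 with mean |MFI| ≈ 0.004, far below
  the 0.03 ceiling expected of a non-fixing strain.
* Rate recovery: truth 20 mg L⁻¹ h⁻¹, CV 5 %, 1000 simulated pairs with
  10 replicates per culture, mean within 2 %. Replication 10 was chosen
  so the mean's standard error (~0.7 %) makes the 2 % band a ≥2.5 se
  margin; at triplicate replication the per-pair sd (~43 % relative)
  would make a 2 % claim statistically unsupportable at this n.
* Exactness: zero-noise recovery and the forward/inverse round trip hold
  to 1e-9 absolute over the tested flux grids.

## Benchmark conventions

Median over even counts averages the two middle values. Min/max specific
rates use the printed column when present. Recomputing specific rates
(1-decimal rounding of rate/biomass) flags six rows that disagree with
their printed values — evidently computed upstream from unrounded data —
and the discrepancy is documented, not corrected. Two volumetric rates
whose printed strain designations abut the rate column are transcribed as
11.0 and 21.0 (noted in the packaged CSV's comments). One footnote's
OD-to-DCW conversion (17.63 × 0.35) matches no printed biomass value; the
conversion is provided as an operation but its original application is
unclear.

## Known limitations

* No raw LC-MS/MS processing: inputs are already-quantified amounts.
* No gas-phase CO2 accounting; fixation is inferred from the liquid-phase
  balance alone.
* The paired balance assumes equal cultivation conditions and equal
  secretion constants between test and control; violations bias the rate
  in ways the package cannot detect from the data it sees.
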