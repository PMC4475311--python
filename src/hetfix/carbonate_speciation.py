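"""Bicarbonate/CO2 partitioning at intracellular pH.

Rubisco uses dissolved CO2, not bicarbonate, as its substrate.  At a given
pH the first carbonate equilibrium (apparent pKa 6.35 for CO2(aq)/H2CO3 vs
HCO3-) sets the speciation by Henderson–Hasselbalch:

    [HCO3-]/[CO2] = 10^(pH - pKa)

At a typical intracellular pH of 7.5 the ratio is ~14, so importing extra
bicarbonate raises CO2 by only ~7 % of the bicarbonate increment — which is
why a bicarbonate transporter alone does little for CO2-limited fixation
while carbonic anhydrase (fast interconversion) helps.  Only the first
dissociation is modeled; carbonate (CO3^2-) is negligible at pH <= 8.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Apparent first pKa of carbonic acid (CO2(aq) + H2CO3 <-> HCO3- + H+).
DEFAULT_PKA = 6.35


def bicarbonate_co2_ratio(ph: float, pka: float = DEFAULT_PKA) -> float:
    """[HCO3-]/[CO2] ratio at the given pH (Henderson–Hasselbalch)."""
    return 10.0 ** (ph - pka)


def co2_increment_fraction(ratio: float) -> float:
    """CO2 increment as a percentage of the bicarbonate increment.

    With speciation ratio r, adding bicarbonate raises CO2 by 100/r
    percent of the bicarbonate rise once equilibrium is restored.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return 100.0 / ratio


@dataclass(frozen=True)
class SpeciationResult:
    """Speciation at one pH: ratio and the CO2-increment percentage."""

    ph: float
    pka: float
    bicarbonate_to_co2_ratio: float
    co2_fraction_of_increment: float


def speciate(ph: float, pka: float = DEFAULT_PKA) -> SpeciationResult:
    ratio = bicarbonate_co2_ratio(ph, pka)
    return SpeciationResult(
        ph=ph,
        pka=pka,
        bicarbonate_to_co2_ratio=ratio,
        co2_fraction_of_increment=co2_increment_fraction(ratio),
    )
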