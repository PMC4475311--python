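import pytest

from hetfix import CultureObservation

# Flask-culture summary observations (triplicate means +- sd) for the
# CO2-fixing strains and the deactivated-enzyme control, 24 h window.
TABLE1 = {
    "RBC-PRK": dict(xylose=13.7, sd_xylose=1.1, biomass=0.82, sd_biomass=0.33, rate=13.3, sd_rate=3.2),
    "RBC-PRK-CA": dict(xylose=14.8, sd_xylose=1.5, biomass=0.87, sd_biomass=0.29, rate=19.6, sd_rate=4.0),
    "control": dict(xylose=29.8, sd_xylose=4.7, biomass=1.59, sd_biomass=0.25),
}


def _obs(strain: str) -> CultureObservation:
    d = TABLE1[strain]
    return CultureObservation(
        strain=strain,
        consumed_xylose_mmol_per_L=d["xylose"],
        biomass_gDCW_per_L=d["biomass"],
        duration_h=24.0,
        sd_xylose=d["sd_xylose"],
        sd_biomass=d["sd_biomass"],
    )


@pytest.fixture
def rbc_prk_obs() -> CultureObservation:
    return _obs("RBC-PRK")


@pytest.fixture
def rbc_prk_ca_obs() -> CultureObservation:
    return _obs("RBC-PRK-CA")


@pytest.fixture
def control_obs() -> CultureObservation:
    return _obs("control")
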