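"""Synthetic isotopologue and culture data with the assumed structure.

Two generators mirror the two estimators:

* :func:`simulate_labeling` draws labeled/unlabeled 3PGA pool measurements
  from the steady-state two-pathway labeling model (central flux *a*,
  bypass flux *b*, basal ratio *alpha*), with multiplicative lognormal
  measurement noise — concentrations are positive and LC-MS errors are
  approximately proportional.

* :func:`simulate_culture_pair` builds a matched test/control culture pair
  that satisfies the paired carbon balance exactly before noise.  CO2
  secretion is parameterized as the dimensionless ratio ``rho`` (secreted
  CO2 carbon per biomass carbon) shared by both strains; because the
  estimator eliminates the secretion term, recovered rates must be
  independent of ``rho`` and of the biomass carbon fraction.

Noiseless outputs satisfy the defining balances to floating-point
precision, so each simulator doubles as the oracle for its estimator.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .carbon_balance import BalanceConstants, CultureObservation
from .isotope_flux import DEFAULT_ALPHA, IsotopologueMeasurement, forward_pool_ratio

#: Carbon molar mass, mg per mmol (for gDCW <-> mmol C conversion).
CARBON_MG_PER_MMOL = 12.011


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class LabelingSimConfig:
    """Conditions for simulated isotope-labeling measurements.

    ``expression_ramp`` maps time (h) to a multiplier on ``b_over_a``,
    emulating the rise of bypass flux with enzyme expression; it is a
    fixture convenience, not a kinetic model.
    """

    a_flux: float = 1.0
    b_over_a: float = 0.13
    alpha: float = DEFAULT_ALPHA
    timepoints_h: tuple[float, ...] = (6.0,)
    n_replicates: int = 3
    noise_cv: float = 0.05
    expression_ramp: Mapping[float, float] | None = None
    strain: str = "fixer"
    baseline_pool: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_flux <= 0:
            raise ValueError("a_flux must be > 0")
        if self.b_over_a < 0:
            raise ValueError("b_over_a must be >= 0")
        if not 0.0 <= self.alpha < 0.5:
            raise ValueError("alpha must be in [0, 0.5)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.timepoints_h:
            raise ValueError("timepoints_h must be non-empty")
        if self.baseline_pool <= 0:
            raise ValueError("baseline_pool must be > 0")


def simulate_labeling(config: LabelingSimConfig) -> list[IsotopologueMeasurement]:
    """Draw isotopologue measurements from the steady-state labeling model.

    For each timepoint and replicate the noiseless pool sizes are
    ``x0 = baseline_pool * a_flux`` and ``y0 = R * x0`` with R the
    steady-state pool ratio for bypass flux ``a * b_over_a * ramp(t)``;
    independent lognormal factors (mean 1, given CV) then perturb x and y.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    ramp = dict(config.expression_ramp or {})
    out: list[IsotopologueMeasurement] = []
    for t in config.timepoints_h:
        mult = ramp.get(t, 1.0)
        b = config.a_flux * config.b_over_a * mult
        ratio = forward_pool_ratio(config.a_flux, b, config.alpha)
        x0 = config.baseline_pool * config.a_flux
        y0 = ratio * x0
        fx = _lognormal_factors(rng, config.noise_cv, config.n_replicates)
        fy = _lognormal_factors(rng, config.noise_cv, config.n_replicates)
        for i in range(config.n_replicates):
            out.append(
                IsotopologueMeasurement(
                    sample_id=f"{config.strain}_t{t:g}_r{i + 1}",
                    strain=config.strain,
                    time_h=t,
                    x_unlabeled=float(x0 * fx[i]),
                    y_labeled=float(y0 * fy[i]),
                )
            )
    return out


@dataclass(frozen=True)
class CultureSimConfig:
    """Conditions for a simulated test/control culture pair.

    Defaults are tuned to the study's flask cultures: a control consuming
    ~30 mmol/L xylose over 24 h reaching ~1.6 g DCW/L (rho = 1.25,
    biomass carbon fraction 0.48), a test strain consuming about half the
    xylose, and 5 % multiplicative measurement noise over 3 replicates.
    """

    control_xylose_mmol_L: float = 29.8
    test_xylose_mmol_L: float | None = None  # default: half the control
    secretion_ratio_rho: float = 1.25
    recovery_fraction: float = 0.96
    true_rate_mg_L_h: float = 20.0
    duration_h: float = 24.0
    biomass_carbon_fraction: float = 0.48
    noise_cv: float = 0.05
    n_replicates: int = 3
    initial_pH: float = 7.0
    final_pH: float = 6.8
    seed: int = 0
    constants: BalanceConstants = field(default_factory=BalanceConstants)

    def __post_init__(self) -> None:
        if self.control_xylose_mmol_L <= 0:
            raise ValueError("control_xylose_mmol_L must be > 0")
        if self.test_xylose_mmol_L is not None and self.test_xylose_mmol_L <= 0:
            raise ValueError("test_xylose_mmol_L must be > 0")
        if self.secretion_ratio_rho <= 0:
            raise ValueError("secretion_ratio_rho must be > 0")
        if not 0.0 < self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must be in (0, 1]")
        if self.true_rate_mg_L_h < 0:
            raise ValueError("true_rate_mg_L_h must be >= 0")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if not 0.0 < self.biomass_carbon_fraction < 1.0:
            raise ValueError("biomass_carbon_fraction must be in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_culture_pair(
    config: CultureSimConfig,
) -> tuple[CultureObservation, CultureObservation]:
    """Simulate a matched (test, control) culture pair.

    Carbon bookkeeping (all per litre, mmol C): the control converts
    ``f * Cx'`` recovered xylose carbon into biomass plus secreted CO2 in
    proportion ``1 : rho``, so control biomass carbon is
    ``f * Cx' / (1 + rho)``.  The test strain additionally fixes
    ``true_rate * duration / m_CO2`` mmol C, which joins central
    metabolism and is partitioned by the same rho.  Biomass carbon is
    converted to g DCW via the biomass carbon fraction (simulator-internal;
    it cancels in the estimator).  Replicate noise is multiplicative
    lognormal; summary fields are replicate means.
    """
    c = config
    k = c.constants
    nC = k.carbons_per_xylose
    f = c.recovery_fraction

    cx_control = c.control_xylose_mmol_L * nC
    test_xylose = (
        c.test_xylose_mmol_L
        if c.test_xylose_mmol_L is not None
        else c.control_xylose_mmol_L / 2.0
    )
    cx_test = test_xylose * nC
    fixed_c = c.true_rate_mg_L_h * c.duration_h / k.co2_molar_mass_mg_per_mmol

    biomass_c_control = f * cx_control / (1.0 + c.secretion_ratio_rho)
    biomass_c_test = (f * cx_test + fixed_c) / (1.0 + c.secretion_ratio_rho)
    if biomass_c_test <= 0 or biomass_c_control <= 0:
        raise ValueError("configuration yields non-positive biomass")

    def to_gdcw(mmol_c: float) -> float:
        return mmol_c * CARBON_MG_PER_MMOL / 1000.0 / c.biomass_carbon_fraction

    rng = np.random.default_rng(c.seed)

    def observe(strain: str, xylose: float, biomass: float) -> CultureObservation:
        n = c.n_replicates
        reps = None
        sd_x = sd_b = None
        if n > 1:
            fx = _lognormal_factors(rng, c.noise_cv, n)
            fb = _lognormal_factors(rng, c.noise_cv, n)
            xs = xylose * fx
            bs = biomass * fb
            reps = tuple((float(a), float(b)) for a, b in zip(xs, bs))
            xylose_mean, biomass_mean = float(np.mean(xs)), float(np.mean(bs))
            sd_x = float(np.std(xs, ddof=1))
            sd_b = float(np.std(bs, ddof=1))
        else:
            fx = _lognormal_factors(rng, c.noise_cv, 1)
            fb = _lognormal_factors(rng, c.noise_cv, 1)
            xylose_mean, biomass_mean = float(xylose * fx[0]), float(biomass * fb[0])
        return CultureObservation(
            strain=strain,
            consumed_xylose_mmol_per_L=xylose_mean,
            biomass_gDCW_per_L=biomass_mean,
            duration_h=c.duration_h,
            initial_pH=c.initial_pH,
            final_pH=c.final_pH,
            replicates=reps,
            sd_xylose=sd_x,
            sd_biomass=sd_b,
        )

    test = observe("sim-fixer", test_xylose, to_gdcw(biomass_c_test))
    control = observe("sim-control", c.control_xylose_mmol_L, to_gdcw(biomass_c_control))
    return test, control


def write_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write CSV fixtures exercising the full pipeline; returns the paths.

    Emits ``isotopologues.csv`` (a fixing strain over 3/6/13 h with the
    bypass flux ramping 0.07 -> 0.13 -> 0.12; 50 replicates per timepoint
    so the group means are tight enough for recovery checks at 5 % noise),
    ``controls.csv`` (isotope-free controls at the basal ratio),
    ``cultures.csv`` and ``replicates.csv`` (a test/control pair with
    replicate detail).  Deterministic given the seed.
    """
    out = Path(out_dir)
    if not out.is_dir():
        raise ValueError(f"not a writable directory: {out}")

    ramp = {3.0: 0.07 / 0.13, 6.0: 1.0, 13.0: 0.12 / 0.13}
    labeled = simulate_labeling(
        LabelingSimConfig(
            b_over_a=0.13,
            timepoints_h=(3.0, 6.0, 13.0),
            expression_ramp=ramp,
            strain="RBC-PRK",
            n_replicates=50,
            noise_cv=0.05,
            seed=seed,
        )
    )
    controls = simulate_labeling(
        LabelingSimConfig(
            b_over_a=0.0,
            timepoints_h=(0.0,),
            n_replicates=3,
            strain="empty-vector",
            noise_cv=0.02,
            seed=seed + 1,
        )
    )

    def meas_frame(ms: Sequence[IsotopologueMeasurement]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "strain": m.strain,
                    "time_h": m.time_h,
                    "x_unlabeled": m.x_unlabeled,
                    "y_labeled": m.y_labeled,
                }
                for m in ms
            ]
        )

    test, control = simulate_culture_pair(CultureSimConfig(seed=seed + 2))
    cultures = pd.DataFrame(
        [
            {
                "strain": obs.strain,
                "role": role,
                "consumed_xylose_mmol_L": obs.consumed_xylose_mmol_per_L,
                "biomass_gDCW_L": obs.biomass_gDCW_per_L,
                "duration_h": obs.duration_h,
                "initial_pH": obs.initial_pH,
                "final_pH": obs.final_pH,
                "sd_xylose": obs.sd_xylose,
                "sd_biomass": obs.sd_biomass,
            }
            for role, obs in (("test", test), ("control", control))
        ]
    )
    replicates = pd.DataFrame(
        [
            {
                "strain": obs.strain,
                "replicate_id": f"r{i + 1}",
                "consumed_xylose_mmol_L": x,
                "biomass_gDCW_L": b,
            }
            for obs in (test, control)
            for i, (x, b) in enumerate(obs.replicates or ())
        ]
    )

    written = []
    for name, frame in (
        ("isotopologues.csv", meas_frame(labeled)),
        ("controls.csv", meas_frame(controls)),
        ("cultures.csv", cultures),
        ("replicates.csv", replicates),
    ):
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)
    return written


def manifest_digest(paths: Sequence[Path]) -> dict[str, str]:
    """SHA-256 of each written fixture, for determinism checks."""
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(paths)}
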