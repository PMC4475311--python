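"""Metabolic flux index (MFI) for heterotrophic CO2 fixation.

An engineered heterotroph carrying a Rubisco/PRK bypass produces the joint
metabolite 3-phosphoglycerate (3PGA) from two routes: the central carbon
pathway (flux *a*, unlabeled carbon from sugar) and the CO2-fixing bypass
(flux *b*, which incorporates one ``13C`` atom per molecule when the medium
is fed with ``13C``-bicarbonate).  At metabolic steady state the ratio of
labeled to unlabeled 3PGA pools identifies the flux ratio ``b/a`` — the
metabolic flux index of heterotrophic CO2 fixation, MFI_h-CO2 — once the
basal (natural-abundance) labeling ratio ``alpha`` of an isotope-free
culture is accounted for.

The forward model: of ``a + b`` moles of 3PGA produced, a fraction
``alpha`` of the nominally unlabeled pool appears in the single-13C form,
so labeled production is ``b + alpha*(a+b)`` and unlabeled production is
``(1-alpha)*(a+b)``.  Steady-state consumption removes both forms in
proportion to their pool sizes, so the measured pool ratio ``y/x`` equals
the production ratio, and inverting gives

    MFI = b/a = ((1-alpha)*y - alpha*x) / ((1+alpha)*x - (1-alpha)*y)

The estimator is scale invariant in ``(x, y)``, crosses zero exactly at the
basal ratio ``y/x = alpha/(1-alpha)``, and saturates (``b/a -> inf``) at
``y/x = (1+alpha)/(1-alpha)``.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

#: Basal labeled/unlabeled 3PGA ratio measured in isotope-free medium.
DEFAULT_ALPHA = 0.0345

FLAG_OK = "ok"
FLAG_BELOW_BASAL = "below_basal"
FLAG_SATURATED = "saturated"

_MODES = ("exact", "paper_rounded")


@dataclass(frozen=True)
class IsotopologueMeasurement:
    """One sample's quantified unlabeled (x) and single-13C (y) 3PGA pools.

    Units are arbitrary but must be consistent between ``x`` and ``y``
    (the flux index only depends on their ratio).
    """

    sample_id: str
    strain: str
    time_h: float
    x_unlabeled: float
    y_labeled: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"sample {self.sample_id!r}: time_h must be >= 0")
        if self.x_unlabeled <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: x_unlabeled must be > 0 "
                "(a zero unlabeled pool is a measurement failure)"
            )
        if self.y_labeled < 0:
            raise ValueError(f"sample {self.sample_id!r}: y_labeled must be >= 0")

    @property
    def pool_ratio(self) -> float:
        return self.y_labeled / self.x_unlabeled


@dataclass(frozen=True)
class BasalRatio:
    """Basal labeled-to-unlabeled 3PGA ratio from isotope-free controls."""

    alpha: float
    n_samples: int
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 0.5:
            raise ValueError(f"alpha must be in [0, 0.5), got {self.alpha}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class LabelingModel:
    """Latent two-pathway labeling system.

    ``a_flux`` mol 3PGA from the central pathway and ``b_flux`` mol fixed
    13CO2 per unit time; ``c_cons``/``d_cons`` are steady-state consumptions
    of the unlabeled/labeled pools; ``alpha`` couples natural 13C abundance.
    """

    a_flux: float
    b_flux: float
    alpha: float = DEFAULT_ALPHA
    c_cons: float = 0.0
    d_cons: float = 0.0

    def __post_init__(self) -> None:
        if self.a_flux <= 0:
            raise ValueError("a_flux must be > 0")
        if self.b_flux < 0:
            raise ValueError("b_flux must be >= 0")
        if not 0.0 <= self.alpha < 0.5:
            raise ValueError("alpha must be in [0, 0.5)")
        if self.c_cons < 0 or self.d_cons < 0:
            raise ValueError("consumptions must be >= 0")

    @property
    def labeled_production(self) -> float:
        return self.b_flux + self.alpha * (self.a_flux + self.b_flux)

    @property
    def unlabeled_production(self) -> float:
        return (1.0 - self.alpha) * (self.a_flux + self.b_flux)

    @property
    def mfi_true(self) -> float:
        return self.b_flux / self.a_flux


@dataclass(frozen=True)
class MFIResult:
    """Point estimate of the flux index b/a for one sample."""

    mfi: float
    labeled_fraction: float
    valid: bool = True
    flag: str = FLAG_OK

    def __post_init__(self) -> None:
        if self.flag not in (FLAG_OK, FLAG_BELOW_BASAL, FLAG_SATURATED):
            raise ValueError(f"unknown flag {self.flag!r}")
        if self.valid and not math.isfinite(self.mfi):
            raise ValueError("a valid result must carry a finite mfi")


def estimate_basal_ratio(
    controls: Sequence[IsotopologueMeasurement],
) -> BasalRatio:
    """Estimate the basal 13C/12C labeling ratio from isotope-free controls.

    ``alpha`` is the mean of per-sample ``y/x`` ratios; ``dispersion`` is
    their sample standard deviation (0 for a single control).
    """
    if len(controls) == 0:
        raise ValueError("no control samples")
    ratios = []
    for m in controls:
        if m.x_unlabeled <= 0:  # defensive; the dataclass already rejects this
            raise ValueError(f"sample {m.sample_id!r}: x_unlabeled must be > 0")
        ratios.append(m.pool_ratio)
    alpha = statistics.fmean(ratios)
    sd = statistics.stdev(ratios) if len(ratios) > 1 else 0.0
    return BasalRatio(alpha=alpha, n_samples=len(ratios), dispersion=sd)


def forward_pool_ratio(a_flux: float, b_flux: float, alpha: float) -> float:
    """Steady-state labeled/unlabeled pool ratio y/x implied by fluxes.

    R = (b + alpha*(a+b)) / ((1-alpha)*(a+b)); consumption preserves the
    pool ratio at steady state, so the measured ratio equals this
    production ratio.
    """
    if a_flux <= 0:
        raise ValueError("a_flux must be > 0")
    if b_flux < 0:
        raise ValueError("b_flux must be >= 0")
    if not 0.0 <= alpha < 0.5:
        raise ValueError("alpha must be in [0, 0.5)")
    total = a_flux + b_flux
    return (b_flux + alpha * total) / ((1.0 - alpha) * total)


def mfi_point(
    x: float,
    y: float,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "exact",
) -> MFIResult:
    """Estimate the flux index b/a from one (x, y) pool measurement.

    Parameters
    ----------
    x, y
        Unlabeled and single-13C 3PGA quantities (same units).
    alpha
        Basal labeling ratio.  Ignored in ``paper_rounded`` mode.
    mode
        ``"exact"`` uses coefficients derived from ``alpha``:
        ``((1-a)y - a x) / ((1+a)x - (1-a)y)``.  ``"paper_rounded"``
        uses the fixed rounded coefficients ``(0.97y - 0.03x) /
        (1.03x - 0.97y)`` (the printed two-decimal form at
        alpha = 3.45 %), which biases the index upward by roughly 5 %
        relative and is provided for literal reproduction only.

    A negative numerator (label below the basal level) is reported as a
    negative index with flag ``below_basal``; a non-positive denominator
    means the labeled pool exceeds what any finite b/a can produce and
    yields ``valid=False``, flag ``saturated`` and an infinite sentinel.
    """
    if x <= 0:
        raise ValueError("x must be > 0")
    if y < 0:
        raise ValueError("y must be >= 0")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode == "exact":
        if not 0.0 <= alpha < 0.5:
            raise ValueError("alpha must be in [0, 0.5)")
        num = (1.0 - alpha) * y - alpha * x
        den = (1.0 + alpha) * x - (1.0 - alpha) * y
    else:
        num = 0.97 * y - 0.03 * x
        den = 1.03 * x - 0.97 * y
    labeled_fraction = y / (x + y)
    if den <= 0:
        return MFIResult(
            mfi=math.inf,
            labeled_fraction=labeled_fraction,
            valid=False,
            flag=FLAG_SATURATED,
        )
    mfi = num / den
    flag = FLAG_BELOW_BASAL if num < 0 else FLAG_OK
    return MFIResult(mfi=mfi, labeled_fraction=labeled_fraction, flag=flag)


def mfi_series(
    measurements: Iterable[IsotopologueMeasurement],
    basal: BasalRatio | float = DEFAULT_ALPHA,
    mode: str = "exact",
) -> pd.DataFrame:
    """Per-(strain, timepoint) summary of per-sample flux indices.

    Each sample's MFI is computed individually (per-sample-then-mean, which
    preserves the estimator's scale invariance and matches replicate error
    propagation) and aggregated within (strain, time_h) groups.  Saturated
    samples are excluded from the group mean and counted in
    ``n_saturated``; the exclusion is logged as a warning.

    Returns a frame with columns strain, time_h, mfi_mean, mfi_sd, n,
    n_saturated, sorted by (strain, time_h).
    """
    alpha = basal.alpha if isinstance(basal, BasalRatio) else float(basal)
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements supplied")

    rows = []
    for m in measurements:
        try:
            res = mfi_point(m.x_unlabeled, m.y_labeled, alpha=alpha, mode=mode)
        except ValueError as exc:
            raise ValueError(f"sample {m.sample_id!r}: {exc}") from exc
        rows.append(
            {
                "strain": m.strain,
                "time_h": m.time_h,
                "sample_id": m.sample_id,
                "mfi": res.mfi,
                "valid": res.valid,
            }
        )
    frame = pd.DataFrame(rows)

    out = []
    for (strain, time_h), grp in frame.groupby(["strain", "time_h"], sort=True):
        sat = grp.loc[~grp["valid"]]
        if len(sat):
            logger.warning(
                "excluding %d saturated sample(s) from group (%s, %g h): %s",
                len(sat), strain, time_h, ", ".join(sat["sample_id"]),
            )
        ok = grp.loc[grp["valid"], "mfi"]
        out.append(
            {
                "strain": strain,
                "time_h": time_h,
                "mfi_mean": ok.mean() if len(ok) else math.nan,
                "mfi_sd": ok.std(ddof=1) if len(ok) > 1 else 0.0 if len(ok) else math.nan,
                "n": int(len(ok)),
                "n_saturated": int(len(sat)),
            }
        )
    return pd.DataFrame(out)


def compare_mfi_groups(
    group1: Sequence[float],
    group2: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on flux-index values from two strains/conditions.

    Equal-variance (Student) by default; set ``welch=True`` for unequal
    variances.  Returns ``(t, p)``; the p-value is symmetric in group
    order.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = _stats.ttest_ind(group1, group2, equal_var=not welch)
    return float(t), float(p)
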