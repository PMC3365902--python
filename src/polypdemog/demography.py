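"""Age structures, catch-curve mortality, survivorship, and demographic summaries.

Once a general (or per-site) growth curve is available, every surveyed
polyp is aged by inverting the curve at its length (completed years).  The
resulting integer age-frequency distribution is analysed with the classical
catch-curve semi-log regression

    ln(N_t) = -Z * t + ln(N_0)

whose negated slope Z is the instantaneous rate of mortality and whose r²
measures how close the population is to steady state (r² = 1 when
recruitment exactly balances mortality).  The survivorship curve
N_t = N_0 * exp(-Z * t) then gives the theoretical age structure, from
which theoretical analogues of the observed summary parameters (percentage
of immature individuals, mean age, age at maximum percentage biomass, mean
age of biomass) are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    CensoredLength,
    InsufficientDataError,
    MissingMassError,
    UndefinedSummaryError,
)
from .growth import CoralRecord, GrowthParams, vbgf_age_at_length, vbgf_length_at_age

__all__ = [
    "AgeStructure",
    "MortalityFit",
    "LengthMassModel",
    "DemographySummary",
    "assign_ages",
    "build_age_structure",
    "fit_mortality",
    "survivorship",
    "theoretical_structure",
    "summarize_demography",
]


@dataclass(frozen=True)
class AgeStructure:
    """Integer age-class frequencies for one site, observed and (optionally) theoretical."""

    site: str
    class_ages: np.ndarray          # 0-based completed years
    observed_counts: np.ndarray     # integers >= 0, interior zeros retained
    theoretical_counts: Optional[np.ndarray] = None

    @property
    def max_age(self) -> int:
        return int(self.class_ages[-1])

    @property
    def n(self) -> int:
        return int(self.observed_counts.sum())


@dataclass(frozen=True)
class MortalityFit:
    """Semi-log age-frequency regression: Z, N0 and the stability r²."""

    z: float          # instantaneous rate of mortality, 1/year
    ln_n0: float      # regression intercept
    r2: float         # population-structure stability
    n_classes: int    # nonzero classes used in the regression

    @property
    def n0(self) -> float:
        return math.exp(self.ln_n0)


@dataclass(frozen=True)
class LengthMassModel:
    """Allometric length-mass relation mass = a_m * L**b_m (g, mm)."""

    coeff: float      # a_m, g * mm^(-b_m)
    exponent: float   # b_m

    def __post_init__(self):
        if not (self.coeff > 0 and self.exponent > 0):
            raise ValueError("allometric coefficient and exponent must be positive")

    def mass_at_length(self, length_mm) -> float:
        return self.coeff * np.asarray(length_mm, dtype=float) ** self.exponent


@dataclass(frozen=True)
class DemographySummary:
    """The eight observed/theoretical demographic parameters for one site."""

    site: str
    observed_pct_immature: float
    theoretical_pct_immature: float
    observed_mean_age: float
    theoretical_mean_age: float
    observed_age_max_biomass: int
    theoretical_age_max_biomass: int
    observed_mean_age_biomass: float
    theoretical_mean_age_biomass: float
    z: float
    stability_r2: float
    n: int
    n_censored: int = 0


def assign_ages(records: Sequence[CoralRecord], params: GrowthParams) -> list[CoralRecord]:
    """Age every record by inverting the growth curve (completed years).

    Records whose length is at or beyond ``L_inf`` cannot be inverted; they
    are real old animals, so they are flagged censored and assigned the
    completed-years age of 0.99 * L_inf rather than dropped (dropping them
    would bias the fraction of immature individuals upward).
    """
    ceiling_age = int(
        vbgf_age_at_length(params, 0.99 * params.l_inf, mode="completed_years")
    )
    out = []
    for r in records:
        try:
            age = int(vbgf_age_at_length(params, r.length_mm, "completed_years"))
            out.append(replace(r, age_class=age, censored=False))
        except CensoredLength:
            out.append(replace(r, age_class=ceiling_age, censored=True))
    return out


def build_age_structure(aged_records: Sequence[CoralRecord], site: str) -> AgeStructure:
    """Count aged records per integer class from 0 to the maximum observed class.

    Interior empty classes are retained with count 0 (they matter for the
    support of the theoretical curve, though they are excluded from the
    semi-log regression).
    """
    ages = [r.age_class for r in aged_records if r.age_class is not None]
    if not ages:
        raise InsufficientDataError("no aged records to build an age structure from")
    max_age = max(ages)
    counts = np.bincount(ages, minlength=max_age + 1)
    return AgeStructure(
        site=site,
        class_ages=np.arange(max_age + 1),
        observed_counts=counts,
    )


def fit_mortality(structure: AgeStructure) -> MortalityFit:
    """Catch-curve fit: OLS of ln(N_t) on t over classes with N_t >= 1.

    Zero-count classes are excluded (ln 0 undefined).  A perfectly flat
    structure has slope 0 by symmetry but an undefined r²; by convention it
    is reported as Z = 0, r² = 0 (a flat structure is maximally far from
    the exponentially decaying steady state with Z > 0).
    """
    mask = structure.observed_counts >= 1
    t = structure.class_ages[mask].astype(float)
    n_t = structure.observed_counts[mask].astype(float)
    if len(t) < 3:
        raise InsufficientDataError(
            f"catch-curve regression needs >= 3 nonzero age classes, got {len(t)}"
        )
    y = np.log(n_t)
    if np.allclose(y, y[0]):
        return MortalityFit(z=0.0, ln_n0=float(y[0]), r2=0.0, n_classes=len(t))
    res = sps.linregress(t, y)
    return MortalityFit(
        z=float(-res.slope),
        ln_n0=float(res.intercept),
        r2=float(res.rvalue**2),
        n_classes=len(t),
    )


def survivorship(fit: MortalityFit, t) -> float:
    """Expected number surviving to age ``t``: N_0 * exp(-Z * t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    out = fit.n0 * np.exp(-fit.z * t)
    return float(out) if out.ndim == 0 else out


def theoretical_structure(fit: MortalityFit, max_age: int) -> np.ndarray:
    """Survivorship evaluated on integer classes 0..max_age (the observed support)."""
    if max_age < 0:
        raise ValueError("max_age must be >= 0")
    return survivorship(fit, np.arange(max_age + 1))


def _pct_immature(counts: np.ndarray, first_mature_class: int) -> float:
    total = counts.sum()
    return 100.0 * counts[:first_mature_class].sum() / total


def _mean_age(counts: np.ndarray) -> float:
    t = np.arange(len(counts))
    return float((t * counts).sum() / counts.sum())


def _biomass_summaries(biomass: np.ndarray) -> tuple[int, float]:
    """(age at max % biomass, mean age of biomass); ties break to the youngest class."""
    total = biomass.sum()
    if total <= 0:
        raise UndefinedSummaryError("total biomass is zero; biomass ages undefined")
    t = np.arange(len(biomass))
    return int(np.argmax(biomass)), float((t * biomass).sum() / total)


def summarize_demography(
    structure: AgeStructure,
    fit: MortalityFit,
    params: GrowthParams,
    massmodel: LengthMassModel,
    aged_records: Sequence[CoralRecord],
    maturity_length_mm: float = 3.0,
) -> DemographySummary:
    """Compute the eight observed/theoretical demographic parameters for one site.

    Maturity is length-triggered: the first mature class is the completed-years
    age at ``maturity_length_mm`` plus one, so individuals in classes strictly
    below it are immature.  Theoretical quantities use the survivorship curve
    evaluated on the observed class support (0..max observed class).  Observed
    biomass per class sums the measured corallite masses; theoretical biomass
    multiplies the theoretical count by the allometric mass at the VBGF length
    of the class index.
    """
    if maturity_length_mm >= params.l_inf:
        raise ValueError("maturity length must be below the asymptotic length")
    counts = structure.observed_counts.astype(float)
    theo = (
        structure.theoretical_counts
        if structure.theoretical_counts is not None
        else theoretical_structure(fit, structure.max_age)
    )

    first_mature = int(
        vbgf_age_at_length(params, maturity_length_mm, "completed_years")
    ) + 1

    # observed biomass per class from measured masses
    missing = [r for r in aged_records if r.mass_g is None]
    if missing:
        raise MissingMassError(
            f"{len(missing)} aged records lack mass; observed biomass undefined"
        )
    obs_biomass = np.zeros(structure.max_age + 1)
    for r in aged_records:
        obs_biomass[r.age_class] += r.mass_g

    class_lengths = vbgf_length_at_age(params, structure.class_ages.astype(float))
    theo_biomass = theo * massmodel.mass_at_length(class_lengths)

    obs_age_max_b, obs_mean_age_b = _biomass_summaries(obs_biomass)
    theo_age_max_b, theo_mean_age_b = _biomass_summaries(theo_biomass)

    return DemographySummary(
        site=structure.site,
        observed_pct_immature=_pct_immature(counts, first_mature),
        theoretical_pct_immature=_pct_immature(theo, first_mature),
        observed_mean_age=_mean_age(counts),
        theoretical_mean_age=_mean_age(theo),
        observed_age_max_biomass=obs_age_max_b,
        theoretical_age_max_biomass=theo_age_max_b,
        observed_mean_age_biomass=obs_mean_age_b,
        theoretical_mean_age_biomass=theo_mean_age_b,
        z=fit.z,
        stability_r2=fit.r2,
        n=structure.n,
        n_censored=sum(1 for r in aged_records if r.censored),
    )
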