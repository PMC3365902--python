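"""Von Bertalanffy growth estimation from band-dated coral skeletons.

The size of a solitary coral follows the von Bertalanffy growth function
(VBGF)

    L(t) = L_inf * (1 - exp(-K * t))

where ``L_inf`` is the asymptotic (maximum expected) corallite length and
``K`` the growth constant.  ``L_inf`` and ``K`` are estimated with the
classical Ford-Walford plot: the mean length of each integer age class is
regressed at age t+1 on age t; for an exact VBGF this plot is a straight
line with slope exp(-K) and intercept L_inf * (1 - exp(-K)).

The module also provides the model-premise check (mean growth rate L/t must
decay roughly exponentially with age) and the ANCOVA-gated pooling of
per-site Ford-Walford regressions into a single general growth curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    CensoredLength,
    InsufficientDataError,
    NonConvergentGrowthError,
)

__all__ = [
    "CoralRecord",
    "GrowthParams",
    "GrowthRateDecayFit",
    "PoolingRefusal",
    "vbgf_length_at_age",
    "vbgf_age_at_length",
    "fit_growth_rate_decay",
    "ford_walford_fit",
    "walford_pairs",
    "pool_growth_curves",
]


@dataclass(frozen=True)
class CoralRecord:
    """One measured polyp.

    ``length_mm`` is the maximum axis of the oral disc, the primary size
    measure.  ``band_age_years`` is the CT growth-band count (annual bands;
    a banded skeleton is at least 1 year old).  ``true_age`` is only set by
    the simulator and never used by estimators.
    """

    site: str
    patch: str
    length_mm: float
    mass_g: Optional[float] = None
    band_age_years: Optional[int] = None
    true_age: Optional[int] = field(default=None, compare=True)
    age_class: Optional[int] = None
    censored: bool = False

    def __post_init__(self):
        if not (self.length_mm > 0 and math.isfinite(self.length_mm)):
            raise ValueError(f"length must be positive and finite, got {self.length_mm}")
        if self.mass_g is not None and self.mass_g < 0:
            raise ValueError(f"mass must be non-negative, got {self.mass_g}")
        if self.band_age_years is not None and self.band_age_years < 1:
            raise ValueError(
                f"band age must be >= 1 year (got {self.band_age_years}); "
                "a banded skeleton has at least one annual band"
            )


@dataclass(frozen=True)
class GrowthParams:
    """VBGF parameters with Ford-Walford regression diagnostics.

    Invariants: ``0 < walford_slope < 1`` iff ``K > 0``;
    ``L_inf = walford_intercept / (1 - walford_slope)``;
    ``K = -ln(walford_slope)``.
    """

    l_inf: float
    k: float
    walford_slope: float = float("nan")
    walford_intercept: float = float("nan")
    n_age_classes: int = 0
    r2: float = float("nan")

    @classmethod
    def from_walford(cls, slope: float, intercept: float,
                     n_age_classes: int = 0, r2: float = float("nan")) -> "GrowthParams":
        if not (0.0 < slope < 1.0):
            raise NonConvergentGrowthError(
                f"Ford-Walford slope {slope:g} outside (0, 1): "
                "no asymptotic growth in this sample"
            )
        return cls(
            l_inf=intercept / (1.0 - slope),
            k=-math.log(slope),
            walford_slope=slope,
            walford_intercept=intercept,
            n_age_classes=n_age_classes,
            r2=r2,
        )


@dataclass(frozen=True)
class GrowthRateDecayFit:
    """Exponential decay of mean growth rate with age: rate(t) = A * exp(-B*t)."""

    amplitude: float  # A, mm/year
    decay: float      # B, 1/year
    r2: float
    n: int


@dataclass(frozen=True)
class PoolingRefusal:
    """Returned when the ANCOVA gate rejects merging sites into one growth curve."""

    reason: str        # "slopes_differ" or "intercepts_differ"
    p_slopes: float
    p_intercepts: Optional[float] = None

    def __bool__(self) -> bool:  # a refusal is falsy: `if result: use pooled`
        return False


def vbgf_length_at_age(params: GrowthParams, t) -> float:
    """Expected corallite length (mm) at age ``t`` years.

    Strictly increasing in ``t`` and bounded above by ``L_inf``.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    out = params.l_inf * (1.0 - np.exp(-params.k * t))
    return float(out) if out.ndim == 0 else out


def vbgf_age_at_length(params: GrowthParams, length: float,
                       mode: str = "continuous") -> float:
    """Invert the growth curve: age (years) at which the expected length is ``length``.

    ``mode="continuous"`` returns -ln(1 - L/L_inf)/K; ``mode="completed_years"``
    returns its floor (the ageing convention used to build integer age classes).
    Raises :class:`CensoredLength` when ``length >= L_inf`` — such an individual
    is older than the curve can resolve.
    """
    if mode not in ("continuous", "completed_years"):
        raise ValueError(f"unknown mode {mode!r}")
    if length < 0:
        raise ValueError("length must be non-negative")
    if length >= params.l_inf:
        raise CensoredLength(length, params.l_inf)
    t = -math.log(1.0 - length / params.l_inf) / params.k
    if mode == "completed_years":
        return float(math.floor(t))
    return t


def _dated(records: Sequence[CoralRecord]) -> list[CoralRecord]:
    return [r for r in records if r.band_age_years is not None]


def fit_growth_rate_decay(records: Sequence[CoralRecord]) -> GrowthRateDecayFit:
    """Check the model premise: mean growth rate L/age decays with age.

    Computes rate_i = L_i / age_i for each band-dated record and fits
    ln(rate) = ln(A) - B*age by ordinary least squares.  The reported r²
    is that of the log-linear fit, the conventional way an exponential
    fit's variance explained is quoted.
    """
    dated = _dated(records)
    ages = np.array([r.band_age_years for r in dated], dtype=float)
    if len(dated) < 4 or len(np.unique(ages)) < 3:
        raise InsufficientDataError(
            "growth-rate decay fit needs >= 4 dated records spanning >= 3 distinct ages"
        )
    rates = np.array([r.length_mm for r in dated]) / ages
    res = sps.linregress(ages, np.log(rates))
    return GrowthRateDecayFit(
        amplitude=float(np.exp(res.intercept)),
        decay=float(-res.slope),
        r2=float(res.rvalue**2),
        n=len(dated),
    )


def age_class_mean_lengths(records: Sequence[CoralRecord]) -> dict[int, float]:
    """Mean corallite length per integer band-age class."""
    dated = _dated(records)
    out: dict[int, list[float]] = {}
    for r in dated:
        out.setdefault(int(r.band_age_years), []).append(r.length_mm)
    return {t: float(np.mean(v)) for t, v in sorted(out.items())}


def walford_pairs(records: Sequence[CoralRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(mean length at t, mean length at t+1) for every consecutive class pair present."""
    means = age_class_mean_lengths(records)
    x, y = [], []
    for t in sorted(means):
        if t + 1 in means:
            x.append(means[t])
            y.append(means[t + 1])
    return np.array(x), np.array(y)


def ford_walford_fit(records: Sequence[CoralRecord]) -> GrowthParams:
    """Estimate VBGF parameters from band-dated records via the Ford-Walford plot.

    Mean length per integer age class is computed, then mean length at age
    t+1 is regressed on mean length at age t over all consecutive class
    pairs.  ``L_inf = intercept / (1 - slope)`` and ``K = -ln(slope)``.
    Missing intermediate age classes break the consecutive-pair chain; they
    are not interpolated.
    """
    x, y = walford_pairs(records)
    if len(x) < 3:
        raise InsufficientDataError(
            f"Ford-Walford fit needs >= 3 consecutive age-class pairs, got {len(x)}"
        )
    res = sps.linregress(x, y)
    return GrowthParams.from_walford(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_age_classes=len(x) + 1,
        r2=float(res.rvalue**2),
    )


def pool_growth_curves(
    per_site_fits: Sequence[GrowthParams],
    per_site_records: Sequence[Sequence[CoralRecord]],
    alpha: float = 0.05,
):
    """Merge per-site growth curves into one general curve if ANCOVA allows.

    The Ford-Walford regressions of all sites are compared with ANCOVA:
    first homogeneity of slopes, then (under a common slope) equality of
    intercepts, both at level ``alpha``.  If neither rejects, age-length
    data of all sites are merged, class means recomputed, and a single
    general Ford-Walford regression returned.  Otherwise a
    :class:`PoolingRefusal` states which test rejected.
    """
    if len(per_site_fits) != len(per_site_records):
        raise ValueError("need one record list per site fit")
    if len(per_site_fits) == 0:
        raise InsufficientDataError("no site fits to pool")
    if len(per_site_fits) == 1:
        return per_site_fits[0]

    from .stats import ancova_walford  # local import to avoid a cycle

    pairs = [walford_pairs(recs) for recs in per_site_records]
    res = ancova_walford(pairs, alpha=alpha)
    if res.decision != "homogeneous":
        return PoolingRefusal(
            reason=res.decision,
            p_slopes=res.p_slopes,
            p_intercepts=res.p_intercepts,
        )
    merged: list[CoralRecord] = [r for recs in per_site_records for r in recs]
    return ford_walford_fit(merged)


def with_band_age(record: CoralRecord, band_age: int) -> CoralRecord:
    """Copy of ``record`` with the CT band age set."""
    return replace(record, band_age_years=int(band_age))
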