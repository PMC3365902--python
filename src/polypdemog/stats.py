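"""Comparative and correlational statistics for the demographic pipeline.

Four tools: Pearson correlation with bootstrap resampling (site-level
parameters against mean SST, small n), the ANCOVA gate on Ford-Walford
regressions that decides whether sites share one growth curve,
Kruskal-Wallis on daily temperatures, and pairwise two-sample
Kolmogorov-Smirnov comparisons of age-frequency distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .demography import AgeStructure
from .errors import InsufficientDataError, UndefinedCorrelationError

__all__ = [
    "CorrelationResult",
    "AncovaResult",
    "pearson_with_bootstrap",
    "ancova_walford",
    "kruskal_wallis",
    "ks_compare_structures",
    "sst_depth_agreement",
]


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    r2: float
    r_bs: float                    # mean Pearson r over bootstrap resamples
    r2_bs: float                   # its square
    n_resamples: int
    n_degenerate_resamples: int    # resamples discarded for a constant coordinate
    ci_low: float                  # 2.5 % percentile of resample r
    ci_high: float                 # 97.5 % percentile


@dataclass(frozen=True)
class AncovaResult:
    p_slopes: float
    p_intercepts: Optional[float]
    decision: str   # homogeneous | slopes_differ | intercepts_differ


def pearson_with_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_resamples: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> CorrelationResult:
    """Pearson r with a case-resampling bootstrap.

    With only a handful of sites the normal-theory assumptions behind the
    Pearson test are shaky, so the coefficient is also estimated by drawing
    n index pairs with replacement ``n_resamples`` times and averaging the
    resample coefficients.  Resamples in which either coordinate is constant
    (correlation undefined) are discarded and counted, not redrawn.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("x and y must have equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("a constant variable has no defined correlation")

    r = float(sps.pearsonr(x, y).statistic)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    xs, ys = x[idx], y[idx]
    xs_c = xs - xs.mean(axis=1, keepdims=True)
    ys_c = ys - ys.mean(axis=1, keepdims=True)
    sx = np.sqrt((xs_c**2).sum(axis=1))
    sy = np.sqrt((ys_c**2).sum(axis=1))
    ok = (sx > 0) & (sy > 0)
    r_samples = (xs_c * ys_c).sum(axis=1)[ok] / (sx[ok] * sy[ok])
    n_degenerate = int(n_resamples - ok.sum())
    if n_degenerate >= n_resamples:
        raise UndefinedCorrelationError("every bootstrap resample was degenerate")
    r_bs = float(r_samples.mean())
    lo, hi = np.percentile(r_samples, [2.5, 97.5])
    return CorrelationResult(
        n=n, r=r, r2=r * r, r_bs=r_bs, r2_bs=r_bs * r_bs,
        n_resamples=n_resamples, n_degenerate_resamples=n_degenerate,
        ci_low=float(lo), ci_high=float(hi),
    )


def ancova_walford(
    site_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA comparing Ford-Walford regressions across sites.

    ``site_pairs`` holds, per site, the (mean length at t, mean length at
    t+1) points of its Walford plot.  A full-interaction linear model tests
    homogeneity of slopes first; if slopes are homogeneous at ``alpha``,
    a common-slope model tests equality of intercepts.  The decision is
    invariant to site ordering.
    """
    if len(site_pairs) < 2:
        raise ValueError("ANCOVA needs >= 2 sites")
    frames = []
    for i, (x, y) in enumerate(site_pairs):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 3:
            raise InsufficientDataError(
                f"site {i}: ANCOVA needs >= 3 Walford pairs per site, got {len(x)}"
            )
        if np.ptp(x) == 0:
            raise ValueError(f"site {i}: constant predictor, singular design")
        frames.append(pd.DataFrame({"x": x, "y": y, "site": str(i)}))
    data = pd.concat(frames, ignore_index=True)

    full = smf.ols("y ~ x * C(site)", data=data).fit()
    common = smf.ols("y ~ x + C(site)", data=data).fit()
    single = smf.ols("y ~ x", data=data).fit()

    # manual partial F-tests so that noise-free designs (zero residual, e.g.
    # identical sites or exactly parallel lines) degrade gracefully instead
    # of producing 0/0 statistics
    tss = float(((data["y"] - data["y"].mean()) ** 2).sum())
    tol = 1e-12 * max(tss, 1.0)

    def partial_f_p(restricted, full_model) -> float:
        delta = float(restricted.ssr - full_model.ssr)
        df_num = float(restricted.df_resid - full_model.df_resid)
        if df_num <= 0 or full_model.df_resid <= 0:
            return 1.0
        if full_model.ssr < tol:  # perfect fit under the full model
            return 1.0 if delta < tol else 0.0
        f = (delta / df_num) / (full_model.ssr / full_model.df_resid)
        return float(sps.f.sf(f, df_num, full_model.df_resid))

    p_slopes = partial_f_p(common, full)
    if p_slopes < alpha:
        return AncovaResult(p_slopes=p_slopes, p_intercepts=None, decision="slopes_differ")
    p_intercepts = partial_f_p(single, common)
    decision = "intercepts_differ" if p_intercepts < alpha else "homogeneous"
    return AncovaResult(p_slopes=p_slopes, p_intercepts=p_intercepts, decision=decision)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups.

    Identical groups have H = 0 and p = 1 by convention (scipy raises on a
    fully tied sample).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("empty group")
    if sum(len(g) for g in arrays) < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _expand_structure(structure: AgeStructure) -> np.ndarray:
    return np.repeat(structure.class_ages, structure.observed_counts)


def ks_compare_structures(
    structures: Sequence[AgeStructure],
    correction: str = "none",
) -> pd.DataFrame:
    """Pairwise two-sample Kolmogorov-Smirnov tests between site age structures.

    Each structure's counts are expanded into individual age samples.  With
    ``correction="bonferroni"`` the p-values are multiplied by the number of
    pairs (capped at 1).  Returns a tidy frame with one row per site pair.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    if len(structures) < 2:
        raise ValueError("need >= 2 structures")
    for s in structures:
        if s.n < 5:
            raise InsufficientDataError(f"site {s.site}: needs >= 5 individuals, has {s.n}")
    pairs = list(combinations(range(len(structures)), 2))
    rows = []
    for i, j in pairs:
        a, b = structures[i], structures[j]
        res = sps.ks_2samp(_expand_structure(a), _expand_structure(b))
        p = res.pvalue * len(pairs) if correction == "bonferroni" else res.pvalue
        rows.append({
            "site_a": a.site, "site_b": b.site,
            "D": float(res.statistic), "p": float(min(p, 1.0)),
        })
    return pd.DataFrame(rows)


def sst_depth_agreement(surface: pd.Series, depth: pd.Series) -> dict[str, float]:
    """Agreement between surface temperature and temperature at sampling depth.

    Both inputs are datetime-indexed °C series (any cadence).  They are
    averaged to daily means, aligned on common dates, and summarised by the
    Pearson r² of the daily means plus the paired-difference statistics
    (mean, SD, SE = SD/sqrt(days)).  Requires >= 30 common days.
    """
    s_daily = surface.groupby(surface.index.floor("D")).mean()
    d_daily = depth.groupby(depth.index.floor("D")).mean()
    common = s_daily.index.intersection(d_daily.index)
    if len(common) < 30:
        raise InsufficientDataError(
            f"need >= 30 common days after daily averaging, got {len(common)}"
        )
    s, d = s_daily.loc[common].to_numpy(), d_daily.loc[common].to_numpy()
    if np.ptp(s) == 0 and np.ptp(d) == 0:
        r2 = 1.0   # two constant, identical-cadence series agree trivially
    elif np.ptp(s) == 0 or np.ptp(d) == 0:
        r2 = 0.0
    else:
        r2 = float(sps.pearsonr(s, d).statistic ** 2)
    diff = s - d
    sd = float(diff.std(ddof=1))
    return {
        "r2": r2,
        "mean_difference": float(diff.mean()),
        "sd": sd,
        "se": sd / np.sqrt(len(common)),
        "n_days": int(len(common)),
    }
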