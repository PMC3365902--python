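# Methods

## Growth model

Corallite length (maximum oral-disc axis, mm) is modelled with the von
Bertalanffy growth function (VBGF)

    L_t = L∞ (1 − e^(−K t))

an asymptotic model whose premise — growth rate declining with age — is
checked before fitting: for each band-dated skeleton the mean lifetime
growth rate `L/t` is computed and `ln(rate)` is regressed on age by
ordinary least squares. A positive decay coefficient with a reasonable r²
supports the asymptotic model. The fit is log-linear OLS rather than
nonlinear least squares because the variance explained by an exponential
decay is conventionally quoted on the log scale.

`L∞` and `K` come from the Ford-Walford plot in its classical form: the
mean length of each integer age class is computed, and mean length at age
t+1 is regressed on mean length at age t over every *consecutive* class
pair. For an exact VBGF this plot is a straight line with slope `e^(−K)`
and intercept `L∞(1 − e^(−K))`, and the fit recovers the parameters to
machine precision (a property the test suite enforces for arbitrary
`0 < K < 1`). Missing intermediate age classes break the pair chain and
are not interpolated. At least three usable pairs are required — a
two-point regression is always degenerate. A Walford slope outside (0, 1)
means the sample shows no asymptotic growth and is reported as a distinct
error rather than a parameter set; with slow growth (`K ≈ 0.06`, slope
≈ 0.94) and only ~30 dated skeletons this happens with non-trivial
probability, which is why pooling decisions are taken on the Walford point
pairs rather than on per-site parameter estimates (below).

**Ageing convention.** Undated survey individuals are aged by the inverse
curve `t = −ln(1 − L/L∞)/K`, truncated to completed years (floor). The
floor, not rounding, is the convention that makes a 12.8 mm polyp on the
general curve (L∞ = 15.4 mm, K = 0.062/yr) exactly 28 years old, the
worked example the package reproduces. Individuals at or beyond `L∞`
cannot be inverted; they are flagged censored and assigned the
completed-years age at `0.99·L∞` instead of being dropped (dropping real
old animals would bias the immature fraction upward). The censored count
is carried through to the site summary. Numerically, the continuous
inverse round-trips the forward curve to |error| < 1e−9 provided the
length is not within ~1e−6 of the asymptote, where the inversion is
inherently ill-conditioned in double precision.

## Pooling gate

Whether all sites share one growth curve is decided by ANCOVA on the
per-site Ford-Walford regressions: first homogeneity of slopes (partial
F-test of the site × length interaction), then — only if slopes are
homogeneous — equality of intercepts under a common slope, both at
α = 0.05. If neither rejects, the age-length data of all sites are merged,
class means recomputed on the merged data, and a single general curve
fitted. The alternative (averaging per-site class means) was considered
and not used; recomputation weights classes by their actual sample sizes.
The F-tests are computed manually from residual sums of squares so that
noise-free designs (identical sites, exactly parallel lines) degrade to
p = 1 / p = 0 instead of 0/0. In the orchestrated pipeline the gate runs
on the Walford point pairs directly, so a site whose own slope estimate is
degenerate can still contribute to (and be aged by) the pooled curve;
per-site fits are required only when the gate refuses, because only then
are they used for ageing.

## Mortality, stability, survivorship

The catch-curve regression `ln N_t = −Z t + ln N₀` is fitted by OLS over
age classes with `N_t ≥ 1`; zero classes are excluded (ln 0 undefined)
rather than shifted by +1, which keeps the steady-state identity exact: a
perfectly exponential count vector returns the generating `Z` with
r² = 1. The r² is reported as population-structure stability (1 = steady
state, falling toward 0 as the structure departs from it; the suite checks
that increasing Poisson noise strictly decreases the median r²). A
perfectly flat structure is reported as `Z = 0`, r² = 0 by convention.
Survivorship is `N_t = N₀ e^(−Zt)`, and theoretical age structures
evaluate it on the *observed* class support (0..max observed class), not
an infinite horizon.

**Known bias.** With `Z ≈ 0.4` and ~200 individuals, classes beyond age
~8 have expected counts below 3; conditioning on `N_t ≥ 1` biases the
median `Z` estimate low by roughly 9% on a 0..12 support (measured by
simulation; still within the 15% recovery band the tests assert).
Length-based ageing adds a further ~7% downward bias at that scale: near
the asymptote small length noise maps to large, right-skewed age errors,
smearing old individuals into older classes and flattening the catch
curve. Both effects grow on long sparse supports (low `Z`, low `n`), where
median underestimation can reach 25–50%. This is a property of the method
itself, not of the implementation — the end-to-end test therefore checks
that the length-based chain stays within 15% of what the catch curve gives
on true ages, and this note records the intrinsic bias.

## Demographic summaries

For each site, observed and theoretical versions of four parameters are
computed. Maturity is length-triggered (default 3 mm) and converted to a
class with the same ageing curve used for the population; the first mature
class is `floor(t(3 mm)) + 1`, which places maturity at 2–3 years on the
coldest site's parameters. Observed mean age is the mean of individual
completed-year classes (class indices, not midpoints). Observed biomass
per class sums measured corallite masses; theoretical biomass is the
survivorship count times the allometric mass `a_m L(t)^{b_m}` at the VBGF
length of the class index. Ages at maximum % biomass break ties to the
youngest class. Requesting observed biomass with any missing masses is an
explicit error, not a silent drop.

## Statistics

* **Pearson + bootstrap** — with only six sites, the parametric Pearson
  test is fragile, so the coefficient is also estimated by case
  resampling: n index pairs drawn with replacement, r computed per
  resample (default 100,000), degenerate resamples (a constant coordinate)
  discarded and counted rather than redrawn. The reported `r_BS` is the
  mean of retained resample coefficients — attenuated toward zero relative
  to the point estimate, as expected at n = 6 — with 2.5/97.5 percentile
  bounds also returned.
* **Kruskal-Wallis** on daily mean temperatures (hourly data are first
  aggregated to days to temper serial correlation); fully tied samples
  return H = 0, p = 1 by convention.
* **Kolmogorov-Smirnov** comparisons of age structures are pairwise, each
  structure expanded to individual age samples, with optional Bonferroni
  over the pairs; the publication-style omnibus "distributions differ" call
  is the maximum corrected p.
* **Surface-vs-depth agreement** — both series are averaged to daily
  means, aligned on common dates (≥ 30 required), and summarised by r² and
  paired-difference statistics (mean, SD, SE = SD/√days).

## Synthetic-data generator

The generator emulates the six-site study design. Ages are drawn as
independent Poisson counts per class with mean `N₀ e^(−Zt)`, t = 0..30 by
default — open recruitment, so total site size is Poisson rather than
fixed, matching the error structure the semi-log regression assumes. `N₀`
defaults to the value that makes the expected site size equal the surveyed
sample sizes (76–210). Lengths sit on the VBGF at the class midpoint
t + 0.5 (so integer classes have interior mean lengths and class 0 is not
zero-length) times `1 + ε`, ε Gaussian with CV 0.05, truncated at ±5 SD
and floored at 0.1 mm. Masses follow `a_m L^{b_m}` with lognormal noise
(log-SD 0.1). The allometric coefficients (a_m = 0.0016 g·mm^(−2.7),
b_m = 2.7) are synthetic placeholders for a relation published elsewhere;
they are config-exposed and nothing is asserted about them.

The CT subsample is drawn uniformly without replacement from individuals
of age ≥ 1: a skeleton younger than one year has no complete annual band
to count, so it cannot be band-dated (the record type likewise rejects
band_age = 0). Band-age error defaults to 0 (CT counts treated as exact);
when enabled it is rounded Gaussian, clipped below at 1. Temperature
series are a sinusoidal annual cycle (default amplitude 4 °C, peak in
early August) plus white noise, with the depth series offset by a constant
(default 2.18 °C) and independently noised.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: individual growth heterogeneity beyond
measurement noise (real dated samples show age explaining only ~45–74% of
growth-rate variance, whereas the noise-only simulator yields ~95%; the
premise test asserts only the floor of that band), within-year banding,
spatial patch structure, size-selective mortality, and year-to-year
recruitment pulses (the r² stability metric on real data reflects those;
here it reflects only Poisson sampling).

## Problem sizes and determinism

The simulation-based checks use the study's own scales: 175 dated
skeletons for growth recovery (100 replicates), ~210-individual age
structures for mortality recovery (500 replicates), 200-replicate power
and calibration runs for the ANCOVA gate and KS comparisons. The whole
suite runs in well under a minute. Every stochastic component takes an
explicit seed or Generator; population streams are keyed on
(seed, site index) so sites are independent but jointly reproducible, and
`scripts/acceptance.py` derives all replicate seeds from its single
`--seed` via `SeedSequence.spawn`.

## Known limitations

* Per-site growth fits at ~30 dated skeletons are noisy and occasionally
  degenerate (Walford slope ≥ 1) when true growth is slow; the pipeline
  surfaces this as an explicit error on the refusal branch rather than
  guessing.
* The catch-curve and ageing biases quantified above mean site-level `Z`
  from length-aged structures should be read as having ~10–20% downward
  bias at survey scale even when the model is exactly right.
* Theoretical % immature and related summaries depend on the support
  convention (observed class range); other conventions (infinite horizon,
  alternative N₀ normalisation) give different values and are not
  implemented.
* The bootstrap correlation at n = 6 is descriptive; no multiple-testing
  correction is applied across the ten parameter correlations.
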