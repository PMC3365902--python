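# polypdemog

Growth and population-dynamics analysis for solitary corals sampled along an
environmental (sea-surface-temperature) gradient, built around the classical
age-based toolkit of coral sclerochronology and fisheries science:

* **Growth** — individual size follows the von Bertalanffy growth function
  (VBGF), `L_t = L∞ (1 − e^(−Kt))`, with asymptotic corallite length `L∞`
  (mm) and growth constant `K` (1/yr). The parameters are estimated from
  CT band-dated skeletons with the **Ford-Walford plot**: mean length per
  integer age class at age *t+1* regressed on age *t*; the slope is
  `e^(−K)` and the intercept `L∞(1 − e^(−K))`. An ANCOVA gate (slopes, then
  intercepts, α = 0.05) decides whether sites share one general curve.
* **Demography** — every surveyed polyp is aged by inverting the growth
  curve at its length (completed years). The age-frequency distribution is
  analysed with the catch-curve semi-log regression
  `ln N_t = −Z·t + ln N₀`; the negated slope `Z` is the instantaneous rate
  of mortality, and the regression `r²` measures population-structure
  stability (1 in a steady state). The survivorship curve
  `N_t = N₀ e^(−Zt)` yields theoretical analogues of the observed summary
  parameters: % of individuals below sexual maturity (length-triggered at
  3 mm), mean age, age at maximum % biomass, and mean age of biomass
  (biomass via an allometric length-mass relation `m = a_m L^{b_m}`).
* **Statistics** — Kruskal-Wallis on daily temperatures, pairwise
  two-sample Kolmogorov-Smirnov on age structures, and Pearson correlation
  of every site-level parameter against mean annual SST, with a
  case-resampling bootstrap (default 100,000 resamples) for the small
  number of sites.
* **Synthetic data** — an individual-based cohort simulator generating
  populations with truncated-geometric ages (`P(age = t) ∝ e^(−Zt)`,
  independent Poisson class counts), VBGF lengths with multiplicative
  noise, allometric masses, CT-dated subsamples and sinusoidal paired
  surface/depth temperature series. Its defaults reproduce the six-site
  study design (76–210 polyps per site, ~30 dated skeletons per site,
  site mortality rates 0.07–0.43/yr, ~2 °C SST span).

Intended users: marine ecologists and biostatisticians who want the whole
chain — banded-skeleton growth fit → population ageing → mortality and
stability → temperature correlations — as tested, scriptable functions
rather than a spreadsheet workflow.

## Worked example

```python
import numpy as np
from polypdemog import (GrowthParams, SimulationConfig, simulate_population,
    simulate_ct_subsample, ford_walford_fit, assign_ages, build_age_structure,
    fit_mortality, vbgf_age_at_length)

cfg = SimulationConfig(seed=42)                  # the six-site study design
pop = simulate_population(cfg, 1)                # Calafuria, the coldest site
dated = simulate_ct_subsample(pop, 30, seed=42)  # CT band-dated skeletons
fit = ford_walford_fit(dated)
print(f"Ford-Walford: L_inf = {fit.l_inf:.1f} mm, K = {fit.k:.3f} / yr "
      f"(truth 8.6 mm, 0.185 / yr; n = {len(dated)} dated)")

aged = assign_ages(pop.records, fit)
structure = build_age_structure(aged, pop.site_label)
mort = fit_mortality(structure)
print(f"Catch curve:  Z = {mort.z:.3f} / yr, stability r^2 = {mort.r2:.2f} "
      f"(truth Z = 0.427, n = {structure.n})")

general = GrowthParams(l_inf=15.4, k=0.062)
print(f"Oldest polyp (12.8 mm) on the general curve: "
      f"{vbgf_age_at_length(general, 12.8, 'completed_years'):.0f} completed years")
```

prints

```
Ford-Walford: L_inf = 12.2 mm, K = 0.110 / yr (truth 8.6 mm, 0.185 / yr; n = 30 dated)
Catch curve:  Z = 0.453 / yr, stability r^2 = 0.91 (truth Z = 0.427, n = 218)
Oldest polyp (12.8 mm) on the general curve: 28 completed years
```

The growth fit illustrates the well-known behaviour of the Walford plot at
30 dated individuals: `L∞` and `K` are strongly negatively correlated, so a
single small sample can overshoot `L∞` while undershooting `K` even though
the median across replicate samples is close to the truth (the test suite
checks the medians). The catch-curve `Z` uses all 218 polyps of the site
and lands much closer; the mortality estimate is the more robust of the
two at survey scale.

The same analysis runs end-to-end from the shell:

```bash
polypdemog run --seed 1 --out-dir out/          # simulate + full analysis
polypdemog simulate --seed 3 --out-dir data/    # just write survey/temperature CSVs
polypdemog growth data/survey.csv --out-dir out/
polypdemog demography data/survey.csv --out-dir out/
polypdemog correlate out/demography_summary.csv data/sst.csv --out-dir out/
```

`run` writes a per-site parameter table (`site_table.csv`), the
SST-correlation table (`correlations.csv`) and a JSON manifest recording
the seed, a config hash and every gate decision (e.g. whether the ANCOVA
allowed pooling the growth curves).

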