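# ginitrend

Trends in the geographic inequality of health-workforce distribution, and
whether those trends changed at a known policy year.

Many health systems struggle with the uneven distribution of physicians
between urban and rural areas. A standard way to quantify the unevenness is
the **population-weighted Gini coefficient**: within a region, rank its
spatial units (e.g. municipalities) by provider-to-population ratio, plot the
cumulative share of providers *L(p)* against the cumulative population share
*p* (the Lorenz curve), and take

&nbsp;&nbsp;&nbsp;&nbsp;*G* = 1 − Σₖ (xₖ − xₖ₋₁)(yₖ + yₖ₋₁),

twice the area between the Lorenz curve and the diagonal (*G* = 0: providers
exactly proportional to population; *G* → 1: all providers in one place).
For specialties serving a subpopulation — pediatricians — the denominator is
that subpopulation (residents under 15).

To ask whether a policy introduced in a known year changed the inequality
*trend*, the region × year Gini panel is fit with a fixed-knot segmented
(change-point) regression

&nbsp;&nbsp;&nbsp;&nbsp;E(Y) = β₀ + β₁·t + β₂·z + β₃·z·t,&nbsp;&nbsp; z = 1{year ≥ knot},

so the pre-period slope is β₁, the post-period slope is β₁ + β₃, and **β₃ —
the change in slope at the knot — is the policy-effect estimate** (two-sided
t test, α = 0.05; conventional or cluster-robust-by-region standard errors).
The motivating application is Japan's 2004 postgraduate medical training
reform: 47 prefectures, ~1,750 municipalities on harmonized 2010 boundaries,
eight biennial survey waves 1996–2010, knot at 2004.

The package provides:

- **data model** — long unit-year panel I/O (CSV), validation, boundary
  crosswalk aggregation (count-conserving many-to-one merges), per-capita
  rates;
- **inequality** — Lorenz curves, the trapezoid Gini, an independent
  population-weighted pairwise-mean-difference Gini used as a cross-check,
  the n/(n−1) small-sample correction, and region × year Gini panels;
- **trend** — `ChangePointRegression`, a scikit-learn-compatible estimator
  (`fit`/`predict`/`get_params`), plus mean-Gini series;
- **stratification** — built-in urban/rural prefecture schemes (OECD
  typology, metropolitan-area codes, population density) and stratified
  fits;
- **synthetic data** — a generator of registry-like panels whose
  within-region Gini follows a configurable segmented trajectory (log-normal
  unit ratios with a closed-form Gini ↔ shape link), and Monte-Carlo
  recovery/power experiments;
- a `ginitrend` CLI (`simulate`, `gini`, `fit`, `stratify`, `run-all`).

## Worked example

```python
from ginitrend import (SyntheticConfig, generate_panel, gini_panel,
                       fit_changepoint, slopes)

cfg = SyntheticConfig(seed=42)           # 47 regions x 37 units, 8 biennial waves
panel = generate_panel(cfg)              # long unit-year table
gp = gini_panel(panel)                   # Gini per region-year (physicians/population)
fit = fit_changepoint(gp, knot_year=2004)
pre, post = slopes(fit)
print(f"slope pre  = {pre:+.5f} per wave")
print(f"slope post = {post:+.5f} per wave")
print(f"slope change b3 = {fit.params_[3]:+.5f} (SE {fit.bse_[3]:.5f}, p = {fit.pvalues_[3]:.3g})")
```

prints

```
slope pre  = -0.00358 per wave
slope post = +0.00274 per wave
slope change b3 = +0.00632 (SE 0.00100, p = 6.79e-10)
```

The generator injected a pre-period slope of −0.003 Gini units per wave and a
slope change of +0.006 at the 2004 knot; the fit recovers both (a declining
pre-period trend reversing into a worsening post-period trend), and the tiny
p-value on β₃ correctly flags the break. The same analysis runs from the
shell:

```bash
ginitrend simulate --seed 42 --out panel.csv
ginitrend run-all --data panel.csv --provider physicians --knot 2004 \
    --scheme oecd --out results/
```

which writes the Gini panels (within-region, national by-unit, national
by-region), Lorenz exports, the fit report, OECD-stratified fits and
mean-Gini series, each artifact carrying the run's config hash.

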