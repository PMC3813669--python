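# Methods

## Inequality measure

For one region in one survey year, let unit *i* have denominator population
*pᵢ* (total residents for physicians, under-15 residents for pediatricians)
and provider count *cᵢ*. Units are sorted by ascending ratio *rᵢ = cᵢ/pᵢ*
(stable sort, so tied ratios cannot affect the result); the Lorenz curve is
the piecewise-linear interpolation of the cumulative population shares *xₖ*
against cumulative provider shares *yₖ*, prepended with the origin. The Gini
coefficient is computed by the trapezoid rule

    G = 1 − Σₖ (xₖ − xₖ₋₁)(yₖ + yₖ₋₁),

clamped to [0, 1) against floating-point drift. An algebraically identical
but independently coded form — the population-weighted relative mean
absolute difference

    G = Σᵢⱼ wᵢ wⱼ |rᵢ − rⱼ| / (2 μ),  wᵢ = pᵢ/Σp,  μ = Σc/Σp

— is kept in the package and exercised against the trapezoid route in the
test suite (agreement to 1e-12 on random instances); the two are equal for
any piecewise-linear Lorenz curve, so a discrepancy can only be a coding
error.

Conventions for degenerate input, chosen once and exposed where users may
reasonably want the opposite:

- **zero-provider units** are included with ratio 0 (they form the flat
  initial Lorenz segment); excluding them would understate inequality;
- **zero-population units** are excluded from the computation with a logged
  warning (their ratio is undefined); they remain in storage;
- **region-years with zero providers** of the selected specialty have an
  undefined Gini and are emitted as missing (never as 0) and logged; the
  trend fit drops them listwise with a logged count;
- the **small-sample correction** multiplies a region-year's Gini by
  n/(n−1), n the number of contributing units; it requires n ≥ 2 and is off
  by default.

Useful invariants, all property-tested: scale invariance in provider counts;
invariance under splitting a unit into identical halves; merging units never
increases G (aggregation hides within-group inequality, which is also why a
boundary crosswalk must be applied uniformly to all years before comparing
them); G ≤ 1 − w_min, with equality when the smallest unit holds everything.

## Boundary harmonization

Municipal mergers over a study period change the unit map; Gini values are
only comparable over time on a fixed set of boundaries. The crosswalk
operation maps old unit ids many-to-one onto the final-year boundaries and
sums populations and counts within each target unit and year. It refuses
mappings that are incomplete or that merge across region boundaries, and it
conserves region-year totals exactly (tested).

## Change-point model

The region × year Gini panel is pooled into one OLS fit of

    E(Y) = β₀ + β₁ t + β₂ z + β₃ z·t,   z = 1{year ≥ knot},

one row per region-year, regions equally weighted. The knot year itself
belongs to the post-period (a survey taken late in the policy's first year
already reflects it). β₁ is the pre-period slope, β₁ + β₃ the post-period
slope, and β₃ the slope change — the estimate of interest. p-values are
two-sided from the t distribution on the residual degrees of freedom;
α = 0.05. `se_type="cluster"` switches to cluster-robust-by-region
covariance as a sensitivity option for within-region serial correlation; the
default is conventional OLS, matching a single pooled-regression standard
error per coefficient.

Two time codings are supported because slope magnitudes depend on the time
unit, and the fit report always embeds the coding:

- `wave` (default): t = 0, 1, 2, … per survey wave — slopes are per
  biennial wave;
- `calendar`: t = year − first year — slopes are per calendar year (half
  the wave-coded slopes for biennial data; fitted values, R², and the β₃
  p-value are coding-invariant, which is tested).

On exactly piecewise-linear data the fit is exact (residual sum of squares
0, coefficients recovered to machine precision), which pins the design
matrix construction.

## Urban/rural stratification

Three embedded binary schemes classify Japan's 47 prefectures:
OECD-typology predominantly-urban (13 prefectures), metropolitan-area-code
urban (14), and population-density ≥ 1000/km² urban (7); custom schemes are
explicit id lists. Matching is case-insensitive on romanized names. A
stratified analysis fits the change-point model independently per stratum;
strata partition the panel, and a failing stratum (e.g. too few rows) is
reported alongside the other stratum's successful fit rather than aborting
it.

## Synthetic panel generator

The generator produces registry-like panels for validation and power
analysis. Defaults mirror the motivating study design: 47 regions × 37 units
(~1,750 units), biennial waves 1996–2010, knot 2004.

**Trajectory.** Each region-year has a target Gini

    G_rt = clip(G0_r + s₁·τ(t) + Δ·(τ(t) − τ_knot)·1{t ≥ knot} + ε_rt, 0, 0.95)

with τ the wave index, ε_rt iid N(0, noise_sd²) — a hinge (no level jump),
so in the fitted parameterization the true β₃ equals Δ and the true β₂ is
−Δ·τ_knot. Defaults G0 = 0.30, s₁ = −0.003/wave, Δ = +0.006/wave,
noise_sd = 0.01 put the panel on the empirical scale of within-prefecture
physician Ginis and their observed trend sizes.

**Populations.** Unit populations are log-normal(μ = 10.2, σ = 1.0) draws
(median ≈ 27,000, heavy right tail, like municipal populations), rounded,
drawn once per region and constant over years; a per-wave drift multiplier
exists but defaults off so that trajectory tests are sharp. Child
populations are a fixed fraction (0.15) of each unit's population.

**Inequality mechanism and calibration.** Unit provider ratios follow a
log-normal shape, whose Gini has the closed form 2Φ(σ/√2) − 1
(`expected_gini_lognormal`, inverted analytically by `sigma_for_gini`).
Units are *placed at fixed log-normal quantiles* rather than drawn iid:
unit *i* gets ratio `base_rate·exp(σ q_i − σ²/2)` with
q_i = Φ⁻¹((i−½)/n). The shape σ for each region-year is then calibrated
against the package's own population-weighted Gini — the weighted Gini is
monotone in σ for fixed weights, so a 256-point grid plus monotone
interpolation inverts it to ~1e-6 — separately for the physician/population
and pediatrician/child-population pairings. Consequences, all tested:

- in deterministic count mode the realized region-year Gini equals its
  target to interpolation accuracy at *any* number of units, so a noise-free
  flat configuration yields an exactly constant panel;
- the only stochastic error around the regression line is the wave-level
  ε_rt (plus Poisson noise if enabled), iid across region-years — exactly
  the error structure conventional OLS assumes, so 95% CI coverage for β₃
  sits in its nominal band in the recovery experiments. Literal iid
  per-unit ratio draws would instead contribute either per-wave realization
  noise (breaking exactness) or, if frozen per unit, a region-level random
  effect that conventional SEs misprice — the calibrated design removes
  that nuisance term by construction.

`count_mode="deterministic"` (default) emits the real-valued expected counts
ratio·population; `"poisson"` draws integer headcounts, adding realistic
count noise that shrinks as base_rate grows (tested qualitatively at two
rates). Default base rates: 0.00184 physicians/resident and 0.0008
pediatricians/child, the empirical national magnitudes. Urban-specific
overrides of (G0, s₁, Δ) on a named subset of regions support stratified
power experiments. A single integer seed determines the output
byte-for-byte; Monte-Carlo experiments spawn independent child streams per
replicate.

**What the generator does not emulate:** physician migration dynamics,
spatially or serially correlated noise, population decline (unless drift is
enabled), part-time/headcount discrepancies, and within-region correlation
of unit ratios. Passing recovery tests therefore validate the estimation
machinery under the model's own assumptions, not the behaviour of real
registry data.

## Monte-Carlo experiment sizes

The recovery experiment uses 200 replicates at full study scale (bias and
coverage of β̂₃), the null-calibration experiment 400 replicates (type-I
error at α = 0.05 judged against a ~99% binomial band), and the stratified
qualitative-pattern experiment 100 replicates (rural-only break: reject in
the other stratum, not in the urban stratum, in ≥90% of replicates). These
sizes give Monte-Carlo standard errors comfortably below the margins being
checked while keeping the full suite and the acceptance script in the
low minutes on one CPU.

## Numerical notes

- Cumulative sums in double precision; final Gini clamp to [0, 1).
- Reported per-capita rates round half-up at one decimal (the convention of
  published registry tables); unrounded values are available.
- Lorenz convexity validation uses a slope-relative tolerance, since tiny
  population shares produce huge segment slopes.
- The calibration grid spans σ ∈ [0, σ(G = 0.995)]; targets are clipped to
  0.95, safely inside it.

## Known limitations

- The change-point fit assumes a common trend break across regions within a
  stratum; region-specific breaks are averaged.
- No autocorrelation-robust (e.g. Newey–West) or mixed-effects inference;
  cluster-robust SEs are the only serial-correlation sensitivity.
- Unknown-knot (joinpoint) search is out of scope — the knot is an input.
- Bootstrap confidence intervals for Gini values are not provided.
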