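"""Synthetic municipality-panel generator with a controllable Gini trajectory.

The generator emulates a national provider registry: ``n_regions`` regions
(default 47, named after Japan's prefectures) each containing
``units_per_region`` municipalities observed over biennial survey waves.
Within a region-year, the target inequality follows a segmented-linear
trajectory with a slope break at the knot year

    G_rt = clip(G0_r + s1 * tau(t) + delta * (tau(t) - tau(knot)) * 1[t >= knot] + eps_rt)

with ``tau`` the survey-wave index and ``eps_rt`` iid Gaussian wave-level
noise on the Gini scale, so the error structure matches the OLS assumptions
of the downstream change-point regression.

Inequality mechanism
--------------------
Unit provider-to-population ratios follow a log-normal shape, whose Gini has
the closed form ``2*Phi(sigma/sqrt(2)) - 1`` (:func:`expected_gini_lognormal`,
inverted by :func:`sigma_for_gini`). Rather than drawing iid log-normal
ratios — whose finite-sample realization error would contaminate the
trajectory with either per-wave or per-region random effects — each unit is
placed at a fixed log-normal quantile and the shape parameter is calibrated
per region against the package's own population-weighted Gini, by monotone
grid inversion, so that in deterministic count mode the realized region-year
Gini equals its target to interpolation accuracy (~1e-6) at any number of
units. The only stochastic terms are then the wave-level noise and, in
Poisson count mode, count realization noise. Unit populations are heavy-tailed
log-normal, drawn once per region and constant over years unless a drift
multiplier is set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import PANEL_COLUMNS
from .inequality import gini_panel
from .trend import fit_changepoint

PREFECTURES = (
    "Hokkaido", "Aomori", "Iwate", "Miyagi", "Akita", "Yamagata", "Fukushima",
    "Ibaraki", "Tochigi", "Gunma", "Saitama", "Chiba", "Tokyo", "Kanagawa",
    "Niigata", "Toyama", "Ishikawa", "Fukui", "Yamanashi", "Nagano", "Gifu",
    "Shizuoka", "Aichi", "Mie", "Shiga", "Kyoto", "Osaka", "Hyogo", "Nara",
    "Wakayama", "Tottori", "Shimane", "Okayama", "Hiroshima", "Yamaguchi",
    "Tokushima", "Kagawa", "Ehime", "Kochi", "Fukuoka", "Saga", "Nagasaki",
    "Kumamoto", "Oita", "Miyazaki", "Kagoshima", "Okinawa",
)

GINI_CAP = 0.95  # targets are clipped to [0, GINI_CAP]


def expected_gini_lognormal(sigma: float) -> float:
    """Gini coefficient of a log-normal distribution with shape ``sigma``:
    ``2*Phi(sigma/sqrt(2)) - 1``. Monotone increasing, 0 at sigma=0, -> 1."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(2.0 * norm.cdf(sigma / np.sqrt(2.0)) - 1.0)


def sigma_for_gini(g: float) -> float:
    """Log-normal shape parameter whose Gini equals ``g``:
    ``sigma = sqrt(2) * Phi^{-1}((g+1)/2)``."""
    if not 0.0 <= g < 1.0:
        raise ValueError("target Gini must lie in [0, 1)")
    return float(np.sqrt(2.0) * norm.ppf((g + 1.0) / 2.0))


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator; the seed determines the output.

    Parameters
    ----------
    n_regions, units_per_region : int
        Panel dimensions. Defaults 47 regions x 37 units (~1,750 units),
        the scale of Japan's post-merger municipal map.
    years : sequence of int
        Survey waves; default biennial 1996-2010 (8 waves).
    knot_year : int
        First post-period year (the wave of that year is post).
    baseline_gini : float or sequence
        Region baseline Gini G0 (scalar applied to all regions, or one value
        per region). Default 0.30, a typical within-region physician Gini.
    slope_pre, slope_change : float
        Pre-period slope s1 and slope change delta, in Gini units per wave.
        Defaults -0.003 and +0.006 mirror observed physician trends.
    noise_sd : float
        SD of the iid wave-level Gaussian noise on the Gini scale.
    population_lognormal : (mu, sigma)
        Log-normal parameters of unit populations (heavy-tailed; default
        gives a median municipality of ~27,000 residents).
    population_drift : float
        Per-wave multiplicative population growth (default 0: constant).
    child_fraction : float
        Child (under-15) share of each unit's population.
    base_rate, child_base_rate : float
        Mean providers per person: physicians per resident and pediatricians
        per child.
    count_mode : {"deterministic", "poisson"}
        Deterministic mode emits real-valued expected counts; Poisson mode
        draws integer headcounts around them.
    urban_regions : sequence
        Region ids given the urban-specific trajectory overrides below.
    urban_baseline_gini, urban_slope_pre, urban_slope_change : float or None
        Overrides for urban regions (None = same as elsewhere).
    region_ids : sequence or None
        Explicit region names; default prefecture names when n_regions <= 47.
    seed : int
    """

    n_regions: int = 47
    units_per_region: int = 37
    years: Sequence[int] = tuple(range(1996, 2011, 2))
    knot_year: int = 2004
    baseline_gini: float | Sequence[float] = 0.30
    slope_pre: float = -0.003
    slope_change: float = 0.006
    noise_sd: float = 0.01
    population_lognormal: tuple[float, float] = (10.2, 1.0)
    population_drift: float = 0.0
    child_fraction: float = 0.15
    base_rate: float = 0.00184
    child_base_rate: float = 0.0008
    count_mode: str = "deterministic"
    urban_regions: Sequence[str] = field(default_factory=tuple)
    urban_baseline_gini: float | None = None
    urban_slope_pre: float | None = None
    urban_slope_change: float | None = None
    region_ids: Sequence[str] | None = None
    seed: int = 0

    def resolved_region_ids(self) -> list[str]:
        if self.region_ids is not None:
            ids = [str(r) for r in self.region_ids]
            if len(ids) != self.n_regions:
                raise ValueError("region_ids length must equal n_regions")
            return ids
        if self.n_regions <= len(PREFECTURES):
            return list(PREFECTURES[: self.n_regions])
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]

    def validate(self) -> None:
        if self.n_regions < 1 or self.units_per_region < 1:
            raise ValueError("n_regions and units_per_region must be positive")
        if len(self.years) < 1 or len(set(self.years)) != len(self.years):
            raise ValueError("years must be a non-empty sequence of distinct years")
        g0 = np.atleast_1d(np.asarray(self.baseline_gini, dtype=float))
        if g0.size not in (1, self.n_regions):
            raise ValueError("baseline_gini must be scalar or one value per region")
        if np.any(g0 < 0) or np.any(g0 >= 1):
            raise ValueError("baseline Gini must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.child_fraction <= 1:
            raise ValueError("child_fraction must lie in (0, 1]")
        if self.base_rate <= 0 or self.child_base_rate <= 0:
            raise ValueError("base rates must be positive")
        if self.count_mode not in ("deterministic", "poisson"):
            raise ValueError("count_mode must be 'deterministic' or 'poisson'")
        unknown = set(map(str, self.urban_regions)) - set(self.resolved_region_ids())
        if unknown:
            raise ValueError(f"urban_regions not among region ids: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["urban_regions"] = list(self.urban_regions)
        d["population_lognormal"] = list(self.population_lognormal)
        if not np.isscalar(d["baseline_gini"]):
            d["baseline_gini"] = list(np.atleast_1d(d["baseline_gini"]).astype(float))
        if d["region_ids"] is not None:
            d["region_ids"] = list(d["region_ids"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("population_lognormal", "years", "urban_regions", "region_ids"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _weighted_gini_grid(weights: np.ndarray, quantiles: np.ndarray, sigma_grid: np.ndarray):
    """Population-weighted Gini of quantile-placed log-normal ratios, for a
    whole grid of shape parameters at once.

    ``weights`` and ``quantiles`` are paired per unit; because the ratio is
    monotone in the quantile, the ascending-ratio order equals the ascending-
    quantile order for every sigma, so no per-sigma sort is needed.
    """
    order = np.argsort(quantiles, kind="stable")
    w = weights[order].astype(float)
    q = quantiles[order]
    x = np.cumsum(w)
    x /= x[-1]
    dx = np.diff(x, prepend=0.0)
    # ratios up to a constant factor (cancels in the Gini)
    ratios = np.exp(sigma_grid[:, None] * q[None, :])  # (n_sigma, n_units)
    wy = np.cumsum(w[None, :] * ratios, axis=1)
    y = wy / wy[:, -1:]
    y_prev = np.concatenate([np.zeros((len(sigma_grid), 1)), y[:, :-1]], axis=1)
    g = 1.0 - np.sum(dx[None, :] * (y + y_prev), axis=1)
    return np.maximum(g, 0.0)


class _SigmaCalibration:
    """Monotone map target-Gini -> sigma for one fixed weight vector."""

    GRID_SIZE = 256

    def __init__(self, weights: np.ndarray, quantiles: np.ndarray):
        sigma_hi = sigma_for_gini(0.995)
        self.sigma_grid = np.linspace(0.0, sigma_hi, self.GRID_SIZE)
        self.gini_grid = _weighted_gini_grid(weights, quantiles, self.sigma_grid)
        # enforce strict monotonicity for interpolation (flat spots only at 0)
        self.gini_grid = np.maximum.accumulate(self.gini_grid)

    def sigma_for(self, target: np.ndarray) -> np.ndarray:
        return np.interp(target, self.gini_grid, self.sigma_grid)


def expected_gini_targets(config: SyntheticConfig) -> pd.DataFrame:
    """Noise-free target Gini per region-year (the trajectory mean).

    Returns a DataFrame ``region_id, year, target_gini``.
    """
    config.validate()
    noiseless = dataclasses.replace(config, noise_sd=0.0)
    regions = config.resolved_region_ids()
    years = np.asarray(sorted(config.years), dtype=int)
    rows = []
    for region in regions:
        targets = _region_targets(noiseless, None, region, years)
        rows.extend((region, int(y), float(g)) for y, g in zip(years, targets))
    return pd.DataFrame(rows, columns=["region_id", "year", "target_gini"])


def generate_panel(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a long unit-year panel in the package's canonical schema.

    Per region: unit populations are log-normal draws (rounded, constant over
    years up to the optional drift); each unit sits at a fixed standard-normal
    quantile; per year the log-normal shape is calibrated so the realized
    population-weighted Gini hits the target trajectory, separately for the
    physician/population and pediatrician/child-population pairings.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    regions = config.resolved_region_ids()
    years = np.asarray(sorted(config.years), dtype=int)
    n_units = config.units_per_region
    mu, sd = config.population_lognormal
    quantiles = norm.ppf((np.arange(1, n_units + 1) - 0.5) / n_units)

    frames = []
    for region in regions:
        frames.append(_generate_region(config, rng, region, years, quantiles, mu, sd))
    panel = pd.concat(frames, ignore_index=True)
    return panel[PANEL_COLUMNS]


def _region_targets(config, rng, region, years):
    tau = np.arange(len(years), dtype=float)
    tau_knot = float(np.searchsorted(years, config.knot_year))
    post = (years >= config.knot_year).astype(float)
    regions = config.resolved_region_ids()
    g0 = np.broadcast_to(
        np.atleast_1d(np.asarray(config.baseline_gini, dtype=float)), (len(regions),)
    )
    ridx = regions.index(region)
    is_urban = region in set(map(str, config.urban_regions))
    base = config.urban_baseline_gini if (is_urban and config.urban_baseline_gini is not None) else g0[ridx]
    s1 = config.urban_slope_pre if (is_urban and config.urban_slope_pre is not None) else config.slope_pre
    delta = config.urban_slope_change if (is_urban and config.urban_slope_change is not None) else config.slope_change
    eps = rng.normal(0.0, config.noise_sd, size=len(years)) if config.noise_sd > 0 else np.zeros(len(years))
    return np.clip(base + s1 * tau + delta * (tau - tau_knot) * post + eps, 0.0, GINI_CAP)


def _generate_region(config, rng, region, years, quantiles, mu, sd):
    n_units = config.units_per_region
    targets = _region_targets(config, rng, region, years)
    base_pop = np.maximum(np.round(rng.lognormal(mu, sd, size=n_units)), 1.0)

    unit_ids = [f"{region}-{i + 1:04d}" for i in range(n_units)]
    records = {c: [] for c in PANEL_COLUMNS}
    drift = config.population_drift

    # populations constant over years (drift off): one calibration per pairing
    pop0 = base_pop
    child0 = np.maximum(np.round(config.child_fraction * pop0), 1.0)
    calib_adult = _SigmaCalibration(pop0, quantiles)
    calib_child = _SigmaCalibration(child0, quantiles)

    for tidx, year in enumerate(years):
        if drift:
            pop = np.maximum(np.round(base_pop * (1.0 + drift) ** tidx), 1.0)
            child = np.maximum(np.round(config.child_fraction * pop), 1.0)
            ca = _SigmaCalibration(pop, quantiles)
            cc = _SigmaCalibration(child, quantiles)
        else:
            pop, child, ca, cc = pop0, child0, calib_adult, calib_child
        g = targets[tidx]
        sig_a = float(ca.sigma_for(np.asarray([g]))[0])
        sig_c = float(cc.sigma_for(np.asarray([g]))[0])
        ratio_a = config.base_rate * np.exp(sig_a * quantiles - sig_a**2 / 2.0)
        ratio_c = config.child_base_rate * np.exp(sig_c * quantiles - sig_c**2 / 2.0)
        phys = ratio_a * pop
        peds = ratio_c * child
        if config.count_mode == "poisson":
            phys = rng.poisson(phys).astype(float)
            peds = rng.poisson(peds).astype(float)
        records["region_id"].extend([region] * n_units)
        records["unit_id"].extend(unit_ids)
        records["year"].extend([int(year)] * n_units)
        records["population"].extend(pop.astype(int))
        records["child_population"].extend(child.astype(int))
        records["physicians"].extend(phys)
        records["pediatricians"].extend(peds)
    df = pd.DataFrame(records)
    if config.count_mode == "poisson":
        df["physicians"] = df["physicians"].astype(int)
        df["pediatricians"] = df["pediatricians"].astype(int)
    return df


@dataclass
class RecoverySummary:
    """Monte-Carlo summary of slope-change estimation on synthetic panels."""

    replicates: int
    n_failed: int
    true_slope_change: float
    mean_estimate: float
    sd_estimate: float
    bias: float
    coverage_95: float
    rejection_rate: float
    estimates: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "n_failed": self.n_failed,
            "true_slope_change": self.true_slope_change,
            "mean_estimate": self.mean_estimate,
            "sd_estimate": self.sd_estimate,
            "bias": self.bias,
            "coverage_95": self.coverage_95,
            "rejection_rate": self.rejection_rate,
        }


def stratified_pattern_experiment(
    config: SyntheticConfig,
    replicates: int,
    provider_field: str = "pediatricians",
    knot_year: int | None = None,
    year_coding: str = "wave",
    se_type: str = "conventional",
    alpha: float = 0.05,
) -> dict:
    """Per-stratum slope-change tests on panels where only non-urban regions
    carry the break.

    The config's ``urban_regions`` define the urban stratum (typically with
    ``urban_slope_change=0``). Each replicate generates a panel, computes the
    Gini panel, fits the change-point model per stratum, and records whether
    the other-stratum test rejects while the urban-stratum test does not —
    the qualitative signature of a rural-only policy effect.

    Returns a dict with per-stratum rejection rates and ``pattern_rate``, the
    fraction of replicates showing the signature.
    """
    from .stratification import stratified_fits  # local import avoids a cycle

    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    config.validate()
    if not config.urban_regions:
        raise ValueError("config must declare urban_regions")
    knot = config.knot_year if knot_year is None else knot_year
    urban_reject, other_reject, pattern = [], [], []
    n_failed = 0
    for child in np.random.SeedSequence(config.seed).spawn(replicates):
        rng = np.random.default_rng(child)
        try:
            panel = generate_panel(config, rng=rng)
            gp = gini_panel(panel, provider_field=provider_field)
            fits = stratified_fits(
                gp, list(config.urban_regions), knot_year=knot,
                year_coding=year_coding, se_type=se_type,
            )
            ur = fits.fits["urban"].pvalues_[3] < alpha
            ot = fits.fits["other"].pvalues_[3] < alpha
        except (ValueError, KeyError):
            n_failed += 1
            continue
        urban_reject.append(ur)
        other_reject.append(ot)
        pattern.append(ot and not ur)
    if len(pattern) < 2:
        raise RuntimeError("too few successful replicates")
    return {
        "replicates": replicates,
        "n_failed": n_failed,
        "urban_rejection_rate": float(np.mean(urban_reject)),
        "other_rejection_rate": float(np.mean(other_reject)),
        "pattern_rate": float(np.mean(pattern)),
    }


def recovery_experiment(
    config: SyntheticConfig,
    replicates: int,
    provider_field: str = "physicians",
    knot_year: int | None = None,
    year_coding: str = "wave",
    se_type: str = "conventional",
    alpha: float = 0.05,
) -> RecoverySummary:
    """Generate -> Gini panel -> change-point fit, repeated; summarize b3.

    Each replicate uses an independent child stream of the config seed. The
    configured slope change is compared on the scale of the fit's time
    coding (per wave, or per calendar year for biennial data under calendar
    coding). Replicates whose fit fails are counted, not fatal.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    config.validate()
    knot = config.knot_year if knot_year is None else knot_year
    years = sorted(config.years)
    step = float(np.median(np.diff(years))) if len(years) > 1 else 1.0
    truth = config.slope_change if year_coding == "wave" else config.slope_change / step

    estimates, ses, covered, rejected = [], [], [], []
    n_failed = 0
    children = np.random.SeedSequence(config.seed).spawn(replicates)
    for child in children:
        rng = np.random.default_rng(child)
        try:
            panel = generate_panel(config, rng=rng)
            gp = gini_panel(panel, provider_field=provider_field)
            fit = fit_changepoint(gp, knot_year=knot, year_coding=year_coding, se_type=se_type)
        except (ValueError, KeyError):
            n_failed += 1
            continue
        b3 = fit.params_[3]
        lo, hi = fit.conf_int_[3]
        estimates.append(b3)
        ses.append(fit.bse_[3])
        covered.append(lo <= truth <= hi)
        rejected.append(fit.pvalues_[3] < alpha)

    est = np.asarray(estimates)
    if est.size < 2:
        raise RuntimeError(f"too few successful replicates ({est.size}) to summarize")
    return RecoverySummary(
        replicates=replicates,
        n_failed=n_failed,
        true_slope_change=truth,
        mean_estimate=float(est.mean()),
        sd_estimate=float(est.std(ddof=1)),
        bias=float(est.mean() - truth),
        coverage_95=float(np.mean(covered)),
        rejection_rate=float(np.mean(rejected)),
        estimates=est,
    )
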