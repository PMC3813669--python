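"""Lorenz curves and population-weighted Gini coefficients.

The inequality of a provider distribution over spatial units is summarized by
the Gini coefficient of the provider-to-population ratio, weighted by the
denominator population. Units are ranked by ascending ratio; the Lorenz curve
plots the cumulative denominator-population share (x) against the cumulative
provider share (y), and the Gini is twice the area between the curve and the
diagonal. Two algebraically equivalent routes are provided:

* :func:`gini_from_lorenz` — trapezoidal area under the piecewise-linear
  Lorenz curve (the primary implementation), and
* :func:`gini_pairwise` — the population-weighted relative mean absolute
  difference of ratios, kept as an independent cross-check.

For small groups of units the sample Gini is biased downward; the
:func:`adjust_small_sample` correction multiplies by ``n/(n-1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import DENOMINATOR_FOR
from .errors import UndefinedGiniError

logger = logging.getLogger(__name__)

GINI_PANEL_COLUMNS = ["region_id", "year", "gini", "n_units", "adjusted"]


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative (population share, provider share) points for one group.

    ``x`` and ``y`` include the origin, so they have ``n_units + 1`` entries;
    the first point is (0, 0) and the last (1, 1). Ordering units by ascending
    ratio makes the curve convex and keeps it on or below the diagonal.
    """

    x: np.ndarray
    y: np.ndarray
    n_units: int

    def validate(self, atol: float = 1e-9) -> None:
        """Assert the defining invariants; raises AssertionError on violation."""
        assert self.x[0] == 0.0 and self.y[0] == 0.0
        assert abs(self.x[-1] - 1.0) <= atol and abs(self.y[-1] - 1.0) <= atol
        assert np.all(np.diff(self.x) > 0), "x must be strictly increasing"
        assert np.all(np.diff(self.y) >= -atol), "y must be non-decreasing"
        assert np.all(self.y <= self.x + atol), "curve must lie on/below diagonal"
        slopes = np.diff(self.y) / np.diff(self.x)
        # tolerance relative to slope magnitude: tiny x-steps give huge slopes
        tol = 1e-9 * np.maximum(np.abs(slopes[1:]), 1.0)
        assert np.all(np.diff(slopes) >= -tol), "curve must be convex"


@dataclass(frozen=True)
class GiniValue:
    """A Gini coefficient together with its provenance."""

    value: float
    n_units: int
    adjusted: bool = False
    region_id: str | None = None
    year: int | None = None

    def __float__(self) -> float:
        return float(self.value)


def _as_arrays(populations, providers):
    pop = np.asarray(populations, dtype=float)
    prov = np.asarray(providers, dtype=float)
    if pop.shape != prov.shape or pop.ndim != 1:
        raise ValueError("populations and providers must be 1-d arrays of equal length")
    if pop.size == 0 or not np.any(pop > 0):
        raise ValueError("need at least one unit with positive population")
    if np.any(pop < 0) or np.any(prov < 0):
        raise ValueError("populations and providers must be non-negative")
    if np.any(pop == 0):
        raise ValueError("zero-population units must be excluded before Gini computation")
    return pop, prov


def build_lorenz(populations, providers) -> LorenzCurve:
    """Build the Lorenz curve of providers over denominator populations.

    Units are sorted by ascending provider-to-population ratio (stable for
    ties, so tie order cannot affect downstream results); cumulative shares
    are taken against the supplied denominator population.
    """
    pop, prov = _as_arrays(populations, providers)
    if prov.sum() == 0:
        raise UndefinedGiniError("total providers is zero; Lorenz curve undefined")
    order = np.argsort(prov / pop, kind="stable")
    pop, prov = pop[order], prov[order]
    x = np.concatenate([[0.0], np.cumsum(pop) / pop.sum()])
    y = np.concatenate([[0.0], np.cumsum(prov) / prov.sum()])
    return LorenzCurve(x=x, y=y, n_units=int(pop.size))


def gini_from_lorenz(curve: LorenzCurve) -> GiniValue:
    """Gini by the trapezoid rule: ``1 - sum dx * (y_k + y_{k-1})``.

    The result is clamped to [0, 1) against floating-point drift.
    """
    g = 1.0 - float(np.sum(np.diff(curve.x) * (curve.y[1:] + curve.y[:-1])))
    g = min(max(g, 0.0), np.nextafter(1.0, 0.0))
    return GiniValue(value=g, n_units=curve.n_units)


def gini_pairwise(populations, providers) -> GiniValue:
    """Population-weighted relative mean absolute difference of ratios.

    ``G = sum_ij w_i w_j |r_i - r_j| / (2 mu)`` with ``w`` the denominator
    population shares, ``r_i`` the unit ratios and ``mu`` the overall ratio.
    Independent of the Lorenz route; identical for piecewise-linear curves.
    """
    pop, prov = _as_arrays(populations, providers)
    if prov.sum() == 0:
        raise UndefinedGiniError("total providers is zero; Gini undefined")
    w = pop / pop.sum()
    r = prov / pop
    mu = prov.sum() / pop.sum()
    g = float(np.abs(r[:, None] - r[None, :]).dot(w).dot(w) / (2.0 * mu))
    g = min(max(g, 0.0), np.nextafter(1.0, 0.0))
    return GiniValue(value=g, n_units=int(pop.size))


def adjust_small_sample(g: GiniValue | float, n: int | None = None) -> GiniValue:
    """Small-sample correction: multiply by ``n/(n-1)``.

    ``n`` defaults to the value's own unit count. Requires ``n >= 2``.
    """
    if isinstance(g, GiniValue):
        n = g.n_units if n is None else n
        base = g
    else:
        if n is None:
            raise ValueError("n is required when adjusting a bare float")
        base = GiniValue(value=float(g), n_units=int(n))
    if n < 2:
        raise ValueError("small-sample adjustment requires n >= 2")
    return replace(base, value=base.value * n / (n - 1), adjusted=True)


def _group_gini(pop: np.ndarray, prov: np.ndarray) -> float:
    """Fast trapezoid Gini on pre-filtered positive populations."""
    order = np.argsort(prov / pop, kind="stable")
    pop, prov = pop[order], prov[order]
    x = np.cumsum(pop)
    y = np.cumsum(prov)
    x /= x[-1]
    y /= y[-1]
    g = 1.0 - float(np.sum(np.diff(x, prepend=0.0) * (y + np.concatenate([[0.0], y[:-1]]))))
    return min(max(g, 0.0), np.nextafter(1.0, 0.0))


def gini_panel(
    df: pd.DataFrame,
    provider_field: str = "physicians",
    denominator_field: str | None = None,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Gini coefficient per region-year over that region's units.

    Parameters
    ----------
    df : DataFrame
        Long unit-year panel (see :mod:`ginitrend.data_model`).
    provider_field : str
        Numerator column; ``"pediatricians"`` is automatically paired with
        the child population unless ``denominator_field`` overrides it.
    denominator_field : str, optional
        Denominator population column.
    adjusted : bool
        Apply the ``n/(n-1)`` small-sample correction per region-year.

    Returns
    -------
    DataFrame
        Columns ``region_id, year, gini, n_units, adjusted``; one row per
        region-year. Zero-population units are excluded with a logged
        warning; region-years whose total providers are zero get ``NaN``
        (the Gini is undefined there, never 0) and are logged.
    """
    denom = denominator_field or DENOMINATOR_FOR.get(provider_field, "population")
    if provider_field not in df.columns or denom not in df.columns:
        raise KeyError(f"panel lacks {provider_field!r} or {denom!r}")
    n_zero_pop = int((df[denom] <= 0).sum())
    if n_zero_pop:
        logger.warning(
            "excluding %d unit-year rows with non-positive %s from Gini computation",
            n_zero_pop,
            denom,
        )
    work = df.loc[df[denom] > 0, ["region_id", "year", denom, provider_field]]
    if work.empty:
        raise ValueError("no units with positive denominator population")

    rows = []
    for (region, year), grp in work.groupby(["region_id", "year"], sort=True):
        pop = grp[denom].to_numpy(dtype=float)
        prov = grp[provider_field].to_numpy(dtype=float)
        n = pop.size
        if prov.sum() == 0:
            logger.warning("region %s year %s has zero %s; Gini missing", region, year, provider_field)
            rows.append((region, year, np.nan, n, adjusted))
            continue
        g = _group_gini(pop, prov)
        if adjusted:
            if n < 2:
                logger.warning("region %s year %s has a single unit; adjustment skipped", region, year)
            else:
                g = g * n / (n - 1)
        rows.append((region, year, g, n, adjusted))
    return pd.DataFrame(rows, columns=GINI_PANEL_COLUMNS)


def lorenz_table(
    df: pd.DataFrame,
    provider_field: str = "physicians",
    denominator_field: str | None = None,
) -> pd.DataFrame:
    """Lorenz-curve points per region-year as a plottable long table
    (``region_id, year, x, y``)."""
    denom = denominator_field or DENOMINATOR_FOR.get(provider_field, "population")
    work = df.loc[df[denom] > 0]
    frames = []
    for (region, year), grp in work.groupby(["region_id", "year"], sort=True):
        if grp[provider_field].sum() == 0:
            continue
        curve = build_lorenz(grp[denom], grp[provider_field])
        frames.append(
            pd.DataFrame({"region_id": region, "year": year, "x": curve.x, "y": curve.y})
        )
    if not frames:
        raise UndefinedGiniError("no region-year with positive providers")
    return pd.concat(frames, ignore_index=True)
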