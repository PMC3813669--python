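"""Fixed-knot linear change-point regression on a Gini panel.

The regression pools all region-year Gini values and fits

    E(Y) = b0 + b1*t + b2*z + b3*(z*t)

where ``t`` is the time covariate, ``z`` indicates the post-period
(``year >= knot_year``), and ``b3`` — the change in slope at the knot — is
the quantity of interest: the pre-period slope is ``b1`` and the post-period
slope is ``b1 + b3``. Inference uses OLS with t-distributed p-values on the
residual degrees of freedom; cluster-robust (by region) covariance is
available as a sensitivity option.

Two time codings are supported and always reported alongside estimates,
because slope magnitudes depend on the unit of time:

* ``"wave"`` (default): t is the 0-based rank of the survey wave, so slopes
  are per survey interval (two years for a biennial survey);
* ``"calendar"``: t = year - first year, so slopes are per calendar year.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

PARAM_NAMES = ["intercept", "t", "z", "zt"]
YEAR_CODINGS = ("wave", "calendar")


def build_design(
    years,
    knot_year: int,
    year_coding: str = "wave",
    all_years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Design columns ``t``, ``z`` and ``zt`` for a vector of years.

    ``z = 1`` where ``year >= knot_year`` (the knot year belongs to the
    post-period). Under wave coding ``t`` is the rank of the year among
    ``all_years`` (defaults to the sorted distinct years present); under
    calendar coding ``t = year - min(year)``.
    """
    years = np.asarray(years, dtype=int)
    if year_coding not in YEAR_CODINGS:
        raise ValueError(f"unknown year_coding {year_coding!r}; expected one of {YEAR_CODINGS}")
    grid = np.asarray(sorted(set(all_years if all_years is not None else years)), dtype=int)
    if year_coding == "wave":
        t = np.searchsorted(grid, years).astype(float)
    else:
        t = (years - grid[0]).astype(float)
    z = (years >= knot_year).astype(float)
    return pd.DataFrame({"t": t, "z": z, "zt": z * t})


class ChangePointRegression(BaseEstimator, RegressorMixin):
    """Segmented linear regression with a fixed knot, sklearn-style.

    Parameters
    ----------
    knot_year : int, default 2004
        First year of the post-period (the knot year itself is post).
    year_coding : {"wave", "calendar"}, default "wave"
        Time covariate coding; see module docstring.
    se_type : {"conventional", "cluster"}, default "conventional"
        Covariance estimator. ``"cluster"`` requires ``groups`` at fit time
        (one cluster per region).

    Attributes
    ----------
    params_ : ndarray of shape (4,)
        ``(b0, b1, b2, b3)``.
    bse_, pvalues_ : ndarray of shape (4,)
        Standard errors and two-sided p-values (t distribution).
    conf_int_ : ndarray of shape (4, 2)
        95% confidence intervals.
    slope_pre_, slope_post_ : float
        ``b1`` and ``b1 + b3``.
    intercept_ : float
    coef_ : ndarray of shape (3,)
        ``(b1, b2, b3)``, sklearn convention.
    results_ : statsmodels RegressionResults
        Full inferential machinery (summary, contrasts, ...).

    Examples
    --------
    >>> import numpy as np
    >>> years = np.repeat(np.arange(1996, 2012, 2), 3)
    >>> t = (years - 1996) / 2; z = years >= 2004
    >>> y = 0.30 - 0.003 * t + z * 0.006 * (t - 4)
    >>> fit = ChangePointRegression(knot_year=2004).fit(years, y)
    >>> np.round(fit.slope_post_ - fit.slope_pre_, 6)
    0.006
    """

    def __init__(
        self,
        knot_year: int = 2004,
        year_coding: str = "wave",
        se_type: str = "conventional",
    ):
        self.knot_year = knot_year
        self.year_coding = year_coding
        self.se_type = se_type

    def _design(self, years, all_years=None) -> np.ndarray:
        d = build_design(years, self.knot_year, self.year_coding, all_years=all_years)
        return sm.add_constant(d[["t", "z", "zt"]].to_numpy(), has_constant="add")

    def fit(self, X, y, groups=None):
        """Fit the change-point model.

        Parameters
        ----------
        X : array-like
            Survey years, shape (n,) or (n, 1).
        y : array-like
            Gini values (or any outcome), shape (n,).
        groups : array-like, optional
            Region labels; required for ``se_type="cluster"``.
        """
        years = np.asarray(X)
        if years.ndim == 2:
            if years.shape[1] != 1:
                raise ValueError("X must be a single column of years")
            years = years[:, 0]
        y = np.asarray(y, dtype=float)
        if years.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values; drop missing Gini cells first")
        uniq = np.unique(years)
        if uniq.size < 4:
            raise ValueError("need at least 4 distinct years to fit 4 parameters")
        if uniq.min() >= self.knot_year or uniq.max() < self.knot_year:
            raise ValueError("observations must span both sides of the knot")
        if self.se_type not in ("conventional", "cluster"):
            raise ValueError(f"unknown se_type {self.se_type!r}")

        self.years_seen_ = np.sort(uniq).astype(int)
        design = self._design(years, all_years=self.years_seen_)
        model = sm.OLS(y, design)
        if self.se_type == "cluster":
            if groups is None:
                raise ValueError("se_type='cluster' requires groups")
            res = model.fit(
                cov_type="cluster",
                cov_kwds={"groups": pd.factorize(np.asarray(groups))[0]},
                use_t=True,
            )
        else:
            res = model.fit(use_t=True)
        self.results_ = res
        self.params_ = np.asarray(res.params, dtype=float)
        self.bse_ = np.asarray(res.bse, dtype=float)
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        self.conf_int_ = np.asarray(res.conf_int(alpha=0.05), dtype=float)
        self.intercept_ = float(self.params_[0])
        self.coef_ = self.params_[1:].copy()
        self.slope_pre_ = float(self.params_[1])
        self.slope_post_ = float(self.params_[1] + self.params_[3])
        self.nobs_ = int(res.nobs)
        self.df_resid_ = float(res.df_resid)
        self.n_groups_ = int(len(np.unique(groups))) if groups is not None else None
        return self

    def predict(self, X):
        """Fitted mean Gini for the given years (same coding as at fit)."""
        check_is_fitted(self, "params_")
        years = np.asarray(X)
        if years.ndim == 2:
            years = years[:, 0]
        return self._design(years, all_years=self.years_seen_) @ self.params_

    def report(self) -> pd.DataFrame:
        """One row per coefficient: estimate, SE, p-value, 95% CI."""
        check_is_fitted(self, "params_")
        return pd.DataFrame(
            {
                "effect": PARAM_NAMES,
                "estimate": self.params_,
                "se": self.bse_,
                "p_value": self.pvalues_,
                "ci_low": self.conf_int_[:, 0],
                "ci_high": self.conf_int_[:, 1],
            }
        )

    def to_dict(self) -> dict:
        """JSON-friendly fit summary."""
        check_is_fitted(self, "params_")
        return {
            "knot_year": self.knot_year,
            "year_coding": self.year_coding,
            "se_type": self.se_type,
            "n_obs": self.nobs_,
            "n_regions": self.n_groups_,
            "coefficients": {
                name: {
                    "estimate": float(b),
                    "se": float(s),
                    "p_value": float(p),
                    "ci_95": [float(lo), float(hi)],
                }
                for name, b, s, p, (lo, hi) in zip(
                    PARAM_NAMES, self.params_, self.bse_, self.pvalues_, self.conf_int_
                )
            },
            "slope_pre": self.slope_pre_,
            "slope_post": self.slope_post_,
        }


def fit_changepoint(
    panel: pd.DataFrame,
    knot_year: int = 2004,
    year_coding: str = "wave",
    se_type: str = "conventional",
) -> ChangePointRegression:
    """Fit :class:`ChangePointRegression` on a Gini panel.

    Rows with missing Gini (region-years where the coefficient is undefined)
    are dropped listwise with a logged count.
    """
    n_missing = int(panel["gini"].isna().sum())
    if n_missing:
        logger.warning("dropping %d region-year rows with missing Gini", n_missing)
    work = panel.dropna(subset=["gini"])
    est = ChangePointRegression(knot_year=knot_year, year_coding=year_coding, se_type=se_type)
    groups = work["region_id"].to_numpy() if "region_id" in work.columns else None
    return est.fit(work["year"].to_numpy(), work["gini"].to_numpy(), groups=groups)


def slopes(fit: ChangePointRegression) -> tuple[float, float]:
    """(pre-period slope, post-period slope) = (b1, b1 + b3)."""
    return fit.slope_pre_, fit.slope_post_


def mean_series(panel: pd.DataFrame, region_subset: Sequence[str] | None = None) -> pd.Series:
    """Unweighted per-year mean of region Gini values.

    ``region_subset`` restricts to a group of regions (e.g. one urbanicity
    stratum); by default all regions contribute.
    """
    work = panel
    if region_subset is not None:
        subset = list(region_subset)
        if not subset:
            raise ValueError("region subset is empty")
        work = panel[panel["region_id"].isin(subset)]
        if work.empty:
            raise ValueError("region subset has no rows in the panel")
    return work.groupby("year")["gini"].mean().rename("mean_gini")
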