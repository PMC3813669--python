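"""Urban/rural stratification of regions and stratified change-point fits.

Three built-in binary urbanicity schemes for Japan's 47 prefectures are
embedded, reflecting classifications in common use:

* ``"oecd"`` — the 13 prefectures classified predominantly urban under the
  OECD regional typology;
* ``"metro"`` — the 14 prefectures containing central cities of major
  metropolitan areas (metropolitan area codes);
* ``"density"`` — the 7 prefectures with population density >= 1000/km^2.

Custom schemes are any explicit list of urban region ids (or a one-id-per-line
text file). Matching is case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .trend import ChangePointRegression, fit_changepoint

OECD_URBAN = (
    "Miyagi", "Saitama", "Chiba", "Tokyo", "Kanagawa", "Shizuoka", "Aichi",
    "Kyoto", "Osaka", "Hyogo", "Nara", "Hiroshima", "Fukuoka",
)
METRO_URBAN = (
    "Hokkaido", "Miyagi", "Saitama", "Chiba", "Tokyo", "Kanagawa", "Niigata",
    "Shizuoka", "Aichi", "Kyoto", "Osaka", "Hyogo", "Hiroshima", "Fukuoka",
)
DENSITY_URBAN = ("Saitama", "Chiba", "Tokyo", "Kanagawa", "Aichi", "Osaka", "Fukuoka")

BUILTIN_SCHEMES: Mapping[str, tuple[tuple[str, ...], str]] = {
    "oecd": (OECD_URBAN, "OECD regional typology: predominantly urban prefectures"),
    "metro": (METRO_URBAN, "prefectures with central cities of major metropolitan areas"),
    "density": (DENSITY_URBAN, "prefectures with population density >= 1000/km^2"),
}

STRATA = ("urban", "other")


@dataclass(frozen=True)
class StratificationScheme:
    """A named binary partition of regions into urban vs. other."""

    name: str
    urban_regions: frozenset  # lower-cased ids
    description: str = ""

    @classmethod
    def from_regions(cls, regions: Iterable[str], name: str = "custom", description: str = "") -> "StratificationScheme":
        urban = frozenset(str(r).strip().lower() for r in regions if str(r).strip())
        if not urban:
            raise ValueError("urban region list is empty")
        return cls(name=name, urban_regions=urban, description=description)


def get_scheme(spec) -> StratificationScheme:
    """Resolve a scheme: built-in name, path to a one-id-per-line file,
    an iterable of region ids, or an existing scheme."""
    if isinstance(spec, StratificationScheme):
        return spec
    if isinstance(spec, str):
        key = spec.lower()
        if key in BUILTIN_SCHEMES:
            regions, desc = BUILTIN_SCHEMES[key]
            return StratificationScheme.from_regions(regions, name=key, description=desc)
        path = Path(spec)
        if path.exists():
            lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
            return StratificationScheme.from_regions(lines, name=path.stem)
        raise ValueError(
            f"unknown scheme {spec!r}: not a built-in ({', '.join(BUILTIN_SCHEMES)}) "
            "and not an existing file"
        )
    return StratificationScheme.from_regions(spec)


def classify(region_id: str, scheme) -> str:
    """``"urban"`` iff the region is in the scheme's list, else ``"other"``."""
    scheme = get_scheme(scheme)
    return "urban" if str(region_id).strip().lower() in scheme.urban_regions else "other"


def stratify_panel(panel: pd.DataFrame, scheme) -> pd.Series:
    """Stratum label per panel row."""
    scheme = get_scheme(scheme)
    lowered = panel["region_id"].astype(str).str.strip().str.lower()
    return lowered.isin(scheme.urban_regions).map({True: "urban", False: "other"})


@dataclass
class StratifiedFits:
    """Per-stratum change-point fits with sizes and captured failures."""

    fits: dict  # stratum -> ChangePointRegression
    n_regions: dict  # stratum -> int
    errors: dict  # stratum -> str, for strata whose fit failed

    def to_dict(self) -> dict:
        return {
            stratum: {
                "n_regions": self.n_regions.get(stratum, 0),
                **(
                    {"fit": self.fits[stratum].to_dict()}
                    if stratum in self.fits
                    else {"error": self.errors.get(stratum, "no data")}
                ),
            }
            for stratum in STRATA
        }


def stratified_fits(
    panel: pd.DataFrame,
    scheme,
    knot_year: int = 2004,
    year_coding: str = "wave",
    se_type: str = "conventional",
) -> StratifiedFits:
    """Independent change-point fits for the urban and other strata.

    Strata partition the panel (every region lands in exactly one stratum).
    A stratum whose fit fails (e.g. too few rows for four parameters) is
    reported with its error while the other stratum's fit is still returned.
    """
    scheme = get_scheme(scheme)
    labels = stratify_panel(panel, scheme)
    all_regions = set(panel["region_id"].astype(str).str.strip().str.lower())
    if not (all_regions & scheme.urban_regions):
        raise ValueError("scheme matches no region in the panel")
    if all_regions <= scheme.urban_regions:
        raise ValueError("scheme classifies every region as urban; nothing to stratify")

    fits: dict = {}
    sizes: dict = {}
    errors: dict = {}
    for stratum in STRATA:
        sub = panel[labels == stratum]
        sizes[stratum] = int(sub["region_id"].nunique())
        try:
            fits[stratum] = fit_changepoint(
                sub, knot_year=knot_year, year_coding=year_coding, se_type=se_type
            )
        except (ValueError, KeyError) as exc:
            errors[stratum] = str(exc)
    return StratifiedFits(fits=fits, n_regions=sizes, errors=errors)
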