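"""Tabular panel model: I/O, validation, boundary crosswalks, per-capita rates.

A provider panel is held as a long-format :class:`pandas.DataFrame` with one
row per spatial unit (municipality) per survey year:

======================  =======================================================
column                  meaning
======================  =======================================================
``region_id``           region (prefecture) the unit belongs to
``unit_id``             spatial unit identifier, unique within a year
``year``                integer calendar year of the survey wave
``population``          resident population of the unit
``child_population``    residents under 15 years (pediatric denominator)
``physicians``          physician headcount registered in the unit
``pediatricians``       pediatrician headcount registered in the unit
======================  =======================================================

Counts may be non-negative reals (synthetic deterministic panels) or integers
(registry data, Poisson-mode panels).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrosswalkError, ParseError, SchemaError

ID_COLUMNS = ["region_id", "unit_id", "year"]
COUNT_COLUMNS = ["population", "child_population", "physicians", "pediatricians"]
PANEL_COLUMNS = ID_COLUMNS + COUNT_COLUMNS

#: numerator -> natural denominator pairing for Gini computation
DENOMINATOR_FOR = {"physicians": "population", "pediatricians": "child_population"}


def read_unit_year_table(
    source,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a unit-year panel from delimited text.

    Parameters
    ----------
    source : path or file-like
        CSV with a header row. Lines starting with ``#`` are ignored
        (writers may prepend a provenance comment).
    column_map : mapping, optional
        Maps canonical column names (see :data:`PANEL_COLUMNS`) to the names
        used in the file, e.g. ``{"physicians": "md_count"}``. Unmapped
        columns are expected under their canonical names.

    Returns
    -------
    pandas.DataFrame
        Columns in canonical order, count columns numeric, row order
        preserved.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ParseError
        If a count cell is non-numeric (the message carries the offending
        row number, 1-based over data rows).
    """
    df = pd.read_csv(source, comment="#", dtype={"unit_id": str, "region_id": str})
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ["year"] + COUNT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    df["year"] = df["year"].astype(int)
    return df[PANEL_COLUMNS + [c for c in df.columns if c not in PANEL_COLUMNS]]


def write_unit_year_table(df: pd.DataFrame, target, provenance: str | None = None) -> None:
    """Write a panel as CSV (stable column order, LF endings).

    ``provenance``, if given, is emitted as a leading ``#`` comment line and
    is ignored by :func:`read_unit_year_table`.
    """
    out = df[PANEL_COLUMNS + [c for c in df.columns if c not in PANEL_COLUMNS]]
    text = out.to_csv(index=False, lineterminator="\n")
    if provenance:
        text = f"# {provenance}\n{text}"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", newline="") as fh:
            fh.write(text)


def read_crosswalk(source) -> dict[str, str]:
    """Read an ``old_unit_id,new_unit_id`` CSV into a mapping."""
    df = pd.read_csv(source, comment="#", dtype=str)
    for col in ("old_unit_id", "new_unit_id"):
        if col not in df.columns:
            raise SchemaError(f"crosswalk is missing column {col!r}")
    dup = df["old_unit_id"].duplicated()
    if dup.any():
        ids = sorted(df.loc[dup, "old_unit_id"].unique())
        raise CrosswalkError(f"old unit(s) mapped more than once: {ids}")
    return dict(zip(df["old_unit_id"], df["new_unit_id"]))


def apply_crosswalk(df: pd.DataFrame, crosswalk: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate units onto harmonized boundaries.

    Every ``unit_id`` must appear in ``crosswalk`` (many-to-one, applied
    identically to all years). Rows mapping to the same target unit within a
    year are summed; populations and provider counts are conserved per
    region-year. Merges may never cross a region boundary.
    """
    unmapped = sorted(set(df["unit_id"]) - set(crosswalk))
    if unmapped:
        raise CrosswalkError(f"unit id(s) missing from crosswalk: {unmapped}")
    out = df.copy()
    out["unit_id"] = out["unit_id"].map(crosswalk)
    regions_per_target = out.groupby("unit_id")["region_id"].nunique()
    crossing = sorted(regions_per_target[regions_per_target > 1].index)
    if crossing:
        raise CrosswalkError(f"merge crosses region boundary for target unit(s): {crossing}")
    merged = (
        out.groupby(["region_id", "unit_id", "year"], as_index=False, sort=False)[COUNT_COLUMNS]
        .sum()
    )
    return merged[PANEL_COLUMNS]


def per_capita_rate(count, population, scale: float = 100_000, report: bool = False):
    """Providers per ``scale`` persons.

    With ``report=True`` the value is rounded half-up to one decimal, the
    precision at which such rates are conventionally published.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rate = scale * count / population
    if report:
        return float(Decimal(repr(rate)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return rate


@dataclass
class PanelValidationReport:
    """Enumerates balance and cleanliness violations of a panel."""

    missing_cells: list = field(default_factory=list)  # (region_id, year)
    duplicate_keys: list = field(default_factory=list)  # (unit_id, year)
    negative_rows: list = field(default_factory=list)  # row indices
    zero_population_units: list = field(default_factory=list)  # unit ids

    @property
    def is_clean(self) -> bool:
        return not (
            self.missing_cells
            or self.duplicate_keys
            or self.negative_rows
            or self.zero_population_units
        )

    def to_dict(self) -> dict:
        return {
            "missing_cells": [list(c) for c in self.missing_cells],
            "duplicate_keys": [list(k) for k in self.duplicate_keys],
            "negative_rows": list(self.negative_rows),
            "zero_population_units": list(self.zero_population_units),
            "is_clean": self.is_clean,
        }


def validate_panel(df: pd.DataFrame, expected_years: Sequence[int]) -> PanelValidationReport:
    """Report missing region-years, duplicate keys, negative values and
    zero-population units. A clean balanced panel yields an empty report."""
    report = PanelValidationReport()
    expected = sorted(int(y) for y in expected_years)
    present = df.groupby("region_id")["year"].agg(lambda s: set(s))
    for region, years in present.items():
        for y in expected:
            if y not in years:
                report.missing_cells.append((region, y))
    dup_mask = df.duplicated(subset=["unit_id", "year"], keep=False)
    if dup_mask.any():
        keys = df.loc[dup_mask, ["unit_id", "year"]].drop_duplicates()
        report.duplicate_keys = [tuple(k) for k in keys.itertuples(index=False)]
    neg = (df[COUNT_COLUMNS] < 0).any(axis=1)
    report.negative_rows = [int(i) for i in df.index[neg]]
    zero = df.loc[df["population"] == 0, "unit_id"].unique()
    report.zero_population_units = sorted(map(str, zero))
    return report
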