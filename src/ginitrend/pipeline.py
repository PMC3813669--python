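"""End-to-end analysis pipeline: validate -> harmonize -> Gini -> trend fits.

The pipeline mirrors the standard four-step workflow for a national provider
registry: (1) national inequality with regions as units, (2) national
inequality with municipalities as units, (3) within-region Gini panel and a
fixed-knot change-point fit, (4) the same fit stratified by urban/rural
status. Every artifact carries the run's config hash and seed for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import data_model, inequality, stratification, trend

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    data: str
    out_dir: str
    crosswalk: str | None = None
    scheme: str | None = "oecd"
    provider: str = "physicians"
    denominator: str | None = None  # default pairing per provider
    adjusted: bool = False
    knot_year: int = 2004
    year_coding: str = "wave"
    se_type: str = "conventional"
    expected_years: list[int] | None = None
    log_level: str = "INFO"
    seed: int | None = None  # recorded for provenance of simulated inputs

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (output location and
        logging verbosity excluded, so re-runs elsewhere hash identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Paths and in-memory artifacts produced by :func:`run_pipeline`."""

    out_dir: Path
    gini_panel: pd.DataFrame
    fit: trend.ChangePointRegression
    stratified: stratification.StratifiedFits | None
    artifacts: dict = field(default_factory=dict)


def _national_by_unit(records: pd.DataFrame) -> pd.DataFrame:
    nat = records.copy()
    nat["region_id"] = "NATION"
    return nat


def _national_by_region(records: pd.DataFrame) -> pd.DataFrame:
    agg = (
        records.groupby(["region_id", "year"], as_index=False)[data_model.COUNT_COLUMNS].sum()
    )
    agg = agg.rename(columns={"region_id": "unit_id"})
    agg["region_id"] = "NATION"
    return agg[data_model.PANEL_COLUMNS]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; write the artifact bundle to ``out_dir``.

    Stages: validate -> crosswalk -> Gini panels (within-region, national
    by-unit, national by-region) -> change-point fit -> stratified fits ->
    mean series -> Lorenz export. Any stage error propagates as
    :class:`PipelineStageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("ginitrend").addHandler(handler)
    provenance = f"config_hash={config.config_hash()} seed={config.seed}"
    artifacts: dict = {}
    try:
        records = _stage("read", data_model.read_unit_year_table, config.data)

        expected_years = config.expected_years or sorted(records["year"].unique())
        report = _stage("validate", data_model.validate_panel, records, expected_years)
        _write_json(out / "validation_report.json", report.to_dict(), provenance)
        artifacts["validation_report"] = report

        if config.crosswalk:
            cw = _stage("crosswalk", data_model.read_crosswalk, config.crosswalk)
            records = _stage("crosswalk", data_model.apply_crosswalk, records, cw)

        def _panel(df):
            return inequality.gini_panel(
                df,
                provider_field=config.provider,
                denominator_field=config.denominator,
                adjusted=config.adjusted,
            )

        panel = _stage("gini", _panel, records)
        nat_unit = _stage("gini", _panel, _national_by_unit(records))
        nat_region = _stage("gini", _panel, _national_by_region(records))
        _write_csv(out / "gini_panel.csv", panel, provenance)
        _write_csv(out / "gini_national_by_unit.csv", nat_unit, provenance)
        _write_csv(out / "gini_national_by_region.csv", nat_region, provenance)

        fit = _stage(
            "fit",
            trend.fit_changepoint,
            panel,
            knot_year=config.knot_year,
            year_coding=config.year_coding,
            se_type=config.se_type,
        )
        _write_json(out / "fit.json", fit.to_dict(), provenance)
        fit.report().to_csv(out / "fit.csv", index=False, lineterminator="\n")

        strat = None
        if config.scheme:
            strat = _stage(
                "stratify",
                stratification.stratified_fits,
                panel,
                config.scheme,
                knot_year=config.knot_year,
                year_coding=config.year_coding,
                se_type=config.se_type,
            )
            _write_json(out / "stratified_fits.json", strat.to_dict(), provenance)
            series = {
                stratum: trend.mean_series(
                    panel[stratification.stratify_panel(panel, config.scheme) == stratum]
                )
                for stratum in stratification.STRATA
            }
            strat_series = pd.DataFrame(series)
            strat_series.to_csv(out / "mean_series_by_stratum.csv", lineterminator="\n")

        mean = _stage("mean-series", trend.mean_series, panel)
        mean.to_csv(out / "mean_series.csv", lineterminator="\n")

        lorenz = _stage(
            "lorenz",
            inequality.lorenz_table,
            records,
            provider_field=config.provider,
            denominator_field=config.denominator,
        )
        _write_csv(out / "lorenz.csv", lorenz, provenance)

        _write_json(
            out / "manifest.json",
            {
                "config": dataclasses.asdict(config),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "artifacts": sorted(p.name for p in out.iterdir()),
            },
            provenance,
        )
    finally:
        logging.getLogger("ginitrend").removeHandler(handler)
        handler.close()
    return PipelineResult(
        out_dir=out, gini_panel=panel, fit=fit, stratified=strat, artifacts=artifacts
    )


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name for actionable CLI errors."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise PipelineStageError(name, exc) from exc


def _write_csv(path: Path, df: pd.DataFrame, provenance: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {provenance}\n")
        fh.write(df.to_csv(index=False, lineterminator="\n"))


def _write_json(path: Path, payload: dict, provenance: str) -> None:
    payload = {"_provenance": provenance, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
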