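"""End-to-end orchestration: simulate -> exposure -> collate -> fits -> thresholds.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage.  For
each analysis cell (region x life stage x season) the pipeline

1. compares model level structures on the full covariate set (posterior
   predictive loss, since hierarchy levels differ),
2. fits single-covariate final models at the winning structure and compares
   them by DIC (co-best = within 2),
3. sweeps day thresholds against each basin's critical abundance for
   co-best models with negative covariate effects, and
4. runs the random-forest branch (retention by OOB r-squared, importance
   ranking, interpretation-variable selection, partial dependence,
   changepoint, interpretation rule).

Every comparison and threshold decision is logged at info level; results are
written as plain CSV with a JSON metadata sidecar.  One top-level seed fans
out deterministically to per-stage seeds (CRC32 of stage name + seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bayes, collate, forest, synthetic, thresholds
from .exposure import (
    DEFAULT_BINS,
    SalinitySeries,
    build_exposure_table,
    covariate_name,
    exposure_wide,
    parse_covariate_name,
)

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the pipeline seed."""
    return zlib.crc32(f"{stage}:{seed}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Table I/O (CSV round-trip with schema validation)
# ---------------------------------------------------------------------------

SALINITY_COLUMNS = ("station_id", "basin_id", "date", "salinity")
DREDGE_COLUMNS = ("station_id", "basin_id", "date", "shell_height_class_mm", "count")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def _parse_iso_dates(col: pd.Series, what: str) -> pd.Series:
    try:
        return pd.to_datetime(col, format="%Y-%m-%d")
    except ValueError as exc:
        raise ValueError(f"{what}: dates must be ISO-8601 (YYYY-MM-DD): {exc}") from None


def write_salinity_csv(series: list[SalinitySeries], path: str | Path) -> None:
    df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_salinity_csv(path: str | Path) -> list[SalinitySeries]:
    df = pd.read_csv(path)
    _require_columns(df, SALINITY_COLUMNS, f"salinity csv {path}")
    df["date"] = _parse_iso_dates(df["date"], f"salinity csv {path}")
    return SalinitySeries.from_frame(df)


def write_dredge_csv(records: pd.DataFrame, path: str | Path) -> None:
    _require_columns(records, DREDGE_COLUMNS, "dredge records")
    records.to_csv(path, index=False)


def read_dredge_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DREDGE_COLUMNS, f"dredge csv {path}")
    df["date"] = _parse_iso_dates(df["date"], f"dredge csv {path}")
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValueError(f"dredge csv {path}: negative count at row(s) {list(bad[:5])}")
    return df


def write_draws_csv(fit: bayes.FitResult, path: str | Path) -> None:
    """Draws as CSV (one column per parameter) plus a JSON metadata sidecar."""
    bayes.draws_to_frame(fit.draws).to_csv(path, index=False)
    meta = {
        "levels": fit.spec.levels,
        "covariates": list(fit.spec.covariates),
        "quadratic": fit.spec.quadratic,
        "chains": fit.draws.settings.chains,
        "iterations": fit.draws.settings.iterations,
        "burn_in": fit.draws.settings.burn_in,
        "thin": fit.draws.settings.thin,
        "seed": fit.draws.settings.seed,
        "dic": fit.dic,
        "ppl": fit.ppl,
        "converged": fit.converged,
        "rhat": fit.rhat,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    scenario: str | None = "negative-slope-east"  # or None with explicit paths
    salinity_csv: str | None = None
    dredge_csv: str | None = None
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020)
    seasons: tuple[str, ...] = ("fall",)
    stages: tuple[str, ...] = ("spat",)
    regions: tuple[str, ...] = ("east",)
    window_kinds: tuple[str, ...] = ("summer",)
    level_structures: tuple[str, ...] = bayes.LEVEL_STRUCTURES
    covariates: tuple[str, ...] | None = None  # None -> all summer covariates
    mcmc: bayes.McmcSettings = field(default_factory=bayes.McmcSettings)
    rf: forest.RFSettings = field(default_factory=forest.RFSettings)
    priors: bayes.PriorSpec = field(default_factory=bayes.PriorSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("year range must be non-empty")
        if self.scenario is None and (self.salinity_csv is None or self.dredge_csv is None):
            raise ValueError("either a scenario or salinity+dredge paths must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("mcmc", bayes.McmcSettings), ("rf", forest.RFSettings), ("priors", bayes.PriorSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("years", "seasons", "stages", "regions", "window_kinds", "level_structures", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def summer_covariates(self) -> tuple[str, ...]:
        if self.covariates is not None:
            return self.covariates
        cols = []
        for b in DEFAULT_BINS:
            for stat in ("total", "consecutive"):
                cols.append(covariate_name("summer", b, stat))
        return tuple(cols)


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _load_inputs(config: PipelineConfig, out: Path) -> tuple[list[SalinitySeries], pd.DataFrame]:
    if config.scenario is not None:
        bundle = synthetic.make_fixture(config.scenario, seed=stage_seed(config.seed, "simulate"))
        records = synthetic.abundance_to_dredge_records(bundle.abundance)
        write_salinity_csv(bundle.salinity, out / "salinity.csv")
        write_dredge_csv(records, out / "dredge.csv")
        (out / "truth.txt").write_text(synthetic.truth_to_text(bundle.truth))
        return bundle.salinity, records
    return read_salinity_csv(config.salinity_csv), read_dredge_csv(config.dredge_csv)


def _bayes_cell(
    config: PipelineConfig,
    abundance: pd.DataFrame,
    exposure: pd.DataFrame,
    region: str,
    season: str,
    stage: str,
) -> tuple[list[dict], list[thresholds.ThresholdResult]]:
    """Model-scale comparison, single-covariate finals, and threshold sweeps."""
    mcmc = dataclasses.replace(config.mcmc, seed=stage_seed(config.seed, f"bayes:{region}:{season}:{stage}"))
    covs = config.summer_covariates()
    cell = dict(region=region, season=season, stage=stage)
    summary_rows: list[dict] = []

    scale_fits = []
    for levels in config.level_structures:
        spec = bayes.ModelSpec(levels=levels, covariates=covs, season=season, stage=stage, region=region)
        try:
            fit = bayes.gibbs_fit(abundance, exposure, spec, config.priors, mcmc)
        except ValueError as exc:
            logger.info("scale %s skipped for %s: %s", levels, cell, exc)
            continue
        scale_fits.append(fit)
        summary_rows.append({**cell, "role": "scale", **bayes.summarize_fit(fit, covariate=None)})
    ranking = bayes.compare_models(scale_fits, criterion="ppl")
    best_levels = scale_fits[ranking.order[0]].spec.levels
    logger.info(
        "%s: best level structure by PPL is %s (PPL %.1f)",
        cell, best_levels, ranking.values[ranking.order[0]],
    )

    final_fits = []
    for cov in covs:
        spec = bayes.ModelSpec(levels=best_levels, covariates=(cov,), season=season, stage=stage, region=region)
        fit = bayes.gibbs_fit(abundance, exposure, spec, config.priors, mcmc)
        final_fits.append(fit)
        summary_rows.append({**cell, "role": "final", **bayes.summarize_fit(fit)})
    final_ranking = bayes.compare_models(final_fits, criterion="dic")
    co_best = [final_fits[i] for i in final_ranking.co_best]
    logger.info(
        "%s: co-best single-covariate models (within 2 DIC): %s",
        cell, [f.spec.covariates[0] for f in co_best],
    )

    results: list[thresholds.ThresholdResult] = []
    for fit in co_best:
        cov = fit.spec.covariates[0]
        cls = bayes.classify_effect(fit, cov)
        if cls not in ("negative-50", "negative-95"):
            logger.info("%s: %s classified %s; no sweep (quadratic check candidate)", cell, cov, cls)
            continue
        stat, _, b = parse_covariate_name(cov)
        kind = "continuous" if stat == "consecutive" else "total"
        if not fit.spec.has_basin:
            logger.info("%s: %s has no basin intercepts; skipping per-basin sweeps", cell, cov)
            continue
        for basin in fit.basin_ids:
            crit = collate.critical_abundance(abundance, basin, season, stage)
            res = thresholds.sweep_threshold(
                fit, basin, crit, exposure_kind=kind, salinity=f"< {b.upper:g}", region=region
            )
            logger.info("%s: bayes threshold %s %s -> %s days", cell, basin, cov, res.days)
            results.append(res)
    return summary_rows, results


def _rf_cell(
    config: PipelineConfig,
    abundance: pd.DataFrame,
    exposure: pd.DataFrame,
    region: str,
    season: str,
    stage: str,
) -> tuple[dict, list[thresholds.ThresholdResult]]:
    covs = list(config.summer_covariates())
    sel = abundance[
        (abundance["season"] == season)
        & (abundance["stage"] == stage)
        & (abundance["basin_id"].map(collate.region_split) == region)
    ]
    merged = sel.merge(exposure[["station_id", "year", *covs]], on=["station_id", "year"], how="inner")
    settings = dataclasses.replace(config.rf, seed=stage_seed(config.seed, f"rf:{region}:{season}:{stage}"))
    fit = forest.fit_rf(merged[covs], merged["abundance"].to_numpy(), settings)
    cell = dict(region=region, season=season, stage=stage)
    row = {**cell, "oob_r2": fit.oob_r2, "retained": fit.retained}
    if not fit.retained:
        logger.info("%s: RF model not retained (OOB r^2 %.3f)", cell, fit.oob_r2)
        return row, []
    imp = forest.variable_importance(fit)
    var = forest.select_interpretation_variable(imp, settings.cluster_tolerance)
    curve = forest.partial_dependence(fit, var)
    cp = forest.detect_changepoint(curve)
    row.update({"selected": var, "changepoint": cp})
    if cp is None:
        logger.info("%s: flat partial dependence for %s; no changepoint", cell, var)
        return row, []
    stat, wkind, b = parse_covariate_name(var)
    kind = "continuous" if stat == "consecutive" else "total"
    # Rising dependence in a safe bin -> subtract rule; decline within the
    # bin itself -> the changepoint is the threshold directly.
    direction = float(curve.values[-1] - curve.values[0])
    mode = "subtract" if direction >= 0 else "direct"
    res = thresholds.rf_interpretation_rule(
        wkind, int(cp), b, kind, mode=mode, region=region, season=season, stage=stage
    )
    logger.info("%s: RF threshold via %s rule: %s for %s days", cell, mode, res.salinity, res.days)
    return row, [res]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns a dict with the collated tables and threshold results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage_name = "input"
    try:
        series, records = _load_inputs(config, out)

        stage_name = "exposure"
        tidy = build_exposure_table(series, config.years, config.window_kinds)
        wide = exposure_wide(tidy)
        tidy.to_csv(out / "exposure.csv", index=False)
        wide.to_csv(out / "exposure_wide.csv", index=False)

        stage_name = "collate"
        abundance = pd.concat(
            [collate.collate_season(records, s) for s in config.seasons], ignore_index=True
        )
        abundance.to_csv(out / "abundance.csv", index=False)
        crit_rows = []
        for season in config.seasons:
            for stage in config.stages:
                for basin in sorted(abundance["basin_id"].unique()):
                    try:
                        c = collate.critical_abundance(abundance, basin, season, stage)
                    except ValueError:
                        continue
                    crit_rows.append(dataclasses.asdict(c))
        pd.DataFrame(crit_rows).to_csv(out / "critical_abundance.csv", index=False)

        all_thresholds: list[thresholds.ThresholdResult] = []
        model_rows: list[dict] = []
        rf_rows: list[dict] = []
        for region in config.regions:
            for season in config.seasons:
                for stage in config.stages:
                    stage_name = f"bayes:{region}:{season}:{stage}"
                    rows, found = _bayes_cell(config, abundance, wide, region, season, stage)
                    model_rows.extend(rows)
                    all_thresholds.extend(found)
                    stage_name = f"rf:{region}:{season}:{stage}"
                    rf_row, found = _rf_cell(config, abundance, wide, region, season, stage)
                    rf_rows.append(rf_row)
                    all_thresholds.extend(found)

        stage_name = "report"
        thr = pd.DataFrame([dataclasses.asdict(t) for t in all_thresholds])
        thr.to_csv(out / "thresholds.csv", index=False)
        pd.DataFrame(model_rows).to_csv(out / "model_summary.csv", index=False)
        pd.DataFrame(rf_rows).to_csv(out / "rf_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    return {
        "abundance": abundance,
        "exposure": wide,
        "thresholds": all_thresholds,
        "model_summary": pd.DataFrame(model_rows),
        "rf_summary": pd.DataFrame(rf_rows),
    }
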