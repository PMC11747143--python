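"""Collation of dredge monitoring records into model-ready abundance tables.

Raw records are per-dredge counts by 5-mm shell-height size class.  They are
classified into life stages (spat: shell height < 25 mm; adult: >= 25 mm),
summed per dredge sample, and averaged per station-year within a season
(fall = September-October, winter = November-December) to give one abundance
value A_ijk per station j in basin i in year k.

The critical abundance for a basin/season/stage is 50% of the five-year mean
abundance over its station-year rows; the Bayesian threshold sweep asks when
predicted abundance drops below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

SPAT_MAX_SH_MM = 25.0  # shell height below which an oyster counts as spat

SEASON_MONTHS: dict[str, tuple[int, ...]] = {
    "fall": (9, 10),
    "winter": (11, 12),
}

#: Louisiana estuarine basins by region.  Sabine and Outside Waters are not
#: part of the study design and are rejected.
REGION_OF_BASIN: dict[str, str] = {
    "pontchartrain": "east",
    "barataria": "east",
    "terrebonne": "east",
    "atchafalaya": "west",
    "vermilion-teche": "west",
    "vermilion": "west",
    "calcasieu": "west",
}


def classify_stage(shell_height_mm: float) -> str:
    """Life stage from shell height: < 25 mm -> 'spat', >= 25 mm -> 'adult'."""
    if shell_height_mm < 0:
        raise ValueError(f"shell height must be non-negative, got {shell_height_mm}")
    return "spat" if shell_height_mm < SPAT_MAX_SH_MM else "adult"


def region_split(basin_id: str) -> str:
    """Region ('east' | 'west') of a basin; unknown basins are an error."""
    key = str(basin_id).strip().lower()
    try:
        return REGION_OF_BASIN[key]
    except KeyError:
        raise ValueError(
            f"basin {basin_id!r} is not in the study registry "
            f"(known: {sorted(set(REGION_OF_BASIN))})"
        ) from None


def collate_season(records: pd.DataFrame, season: str) -> pd.DataFrame:
    """Per station-year-stage mean dredge abundance for one season.

    ``records`` columns: station_id, basin_id, date, shell_height_class_mm,
    count.  Counts are summed by stage within each dredge sample (one date),
    then averaged across the season's sample dates.  Station-years with no
    samples in the season get no row (not a zero).

    Returns columns: station_id, basin_id, year, season, stage, abundance.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be one of {sorted(SEASON_MONTHS)}, got {season!r}")
    cols = ["station_id", "basin_id", "year", "season", "stage", "abundance"]
    if records.empty:
        return pd.DataFrame(columns=cols)

    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    in_season = df["date"].dt.month.isin(SEASON_MONTHS[season])
    n_out = int((~in_season).sum())
    if n_out:
        logger.debug("collate_season(%s): ignoring %d out-of-season records", season, n_out)
    df = df[in_season]
    if df.empty:
        return pd.DataFrame(columns=cols)

    df["stage"] = df["shell_height_class_mm"].map(classify_stage)
    # Sum counts by stage within each dredge sample; a sample with no rows for
    # a stage contributes a zero for that stage (the dredge happened).
    per_sample = (
        df.pivot_table(
            index=["station_id", "basin_id", "date"],
            columns="stage",
            values="count",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=["spat", "adult"], fill_value=0.0)
        .reset_index()
    )
    per_sample["year"] = per_sample["date"].dt.year
    long = per_sample.melt(
        id_vars=["station_id", "basin_id", "year"],
        value_vars=["spat", "adult"],
        var_name="stage",
        value_name="count",
    )
    out = (
        long.groupby(["station_id", "basin_id", "year", "stage"], as_index=False)["count"]
        .mean()
        .rename(columns={"count": "abundance"})
    )
    out["season"] = season
    return out[cols].sort_values(["station_id", "year", "stage"]).reset_index(drop=True)


@dataclass(frozen=True)
class CriticalAbundance:
    """50% of the multi-year mean abundance for one basin/season/stage."""

    basin_id: str
    season: str
    stage: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("critical abundance must be non-negative")


def critical_abundance(
    table: pd.DataFrame, basin_id: str, season: str, stage: str
) -> CriticalAbundance:
    """Half the mean abundance over all station-year rows of a basin/season/stage."""
    sel = table[
        (table["basin_id"] == basin_id)
        & (table["season"] == season)
        & (table["stage"] == stage)
    ]
    if sel.empty:
        raise ValueError(
            f"no abundance rows for basin={basin_id!r}, season={season!r}, stage={stage!r}"
        )
    return CriticalAbundance(basin_id, season, stage, 0.5 * float(sel["abundance"].mean()))
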