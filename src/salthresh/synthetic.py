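"""Synthetic salinity and abundance data with the structure the analysis assumes.

The generator emulates the study's data layout — stations nested in basins
across two regions, five years of daily salinity, and per station-year-season
abundance — without attempting to mimic real Louisiana hydrology.

Daily salinity is a seasonal sinusoid (minimum in early summer, when high
river flow depresses salinity) plus stationary AR(1) Gaussian noise, clamped
at zero.  Controlled low-salinity events can be injected: an event overwrites
the baseline process on its dates with the target level plus a little noise,
which gives exposure-metric tests runs of exactly known length.

Abundance is drawn from the same multilevel normal model the Bayesian branch
fits: station intercepts around basin means, year effects, linear exposure
slopes, and unbounded normal residuals (negative draws are retained, matching
the model's likelihood).  All randomness flows from explicit seeds; there is
no global RNG state.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exposure import SalinitySeries, build_exposure_table, exposure_wide

#: Day-of-year at which the seasonal cycle reaches its salinity minimum
#: (June 1, the start of the high-river-flow summer).
SEASONAL_MINIMUM_DOY = 152

#: Standard deviation of the noise added on event days around the target level.
EVENT_NOISE_SD = 0.05

#: Shell-height class (mm) used when emitting dredge-format records.
STAGE_SHELL_HEIGHT_MM = {"spat": 10.0, "adult": 50.0}

#: Mid-month sample dates used to emit replicate dredge records per season.
SEASON_SAMPLE_DATES = {"fall": ((9, 15), (10, 15)), "winter": ((11, 15), (12, 15))}


@dataclass(frozen=True)
class LowSalinityEvent:
    """A contiguous run of days at a fixed low salinity level.

    ``station_ids=None`` applies the event to every station in the basin.
    """

    basin_id: str
    start_date: dt.date
    duration_days: int
    target_level: float
    station_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.target_level < 0:
            raise ValueError("target_level must be >= 0")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.duration_days, freq="D")


@dataclass(frozen=True)
class SalinityGenConfig:
    n_basins: int = 3
    stations_per_basin: int = 2
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020)
    baseline_mean: tuple[float, ...] | float = 10.0  # psu, per basin or shared
    seasonal_amplitude: float = 3.0  # psu
    ar1_coefficient: float = 0.8
    noise_sd: float = 1.5  # stationary sd of the AR(1) noise, psu
    events: tuple[LowSalinityEvent, ...] = ()
    seed: int = 0
    basin_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.n_basins < 1 or self.stations_per_basin < 1 or not self.years:
            raise ValueError("need at least one basin, station and year")
        if self.basin_ids is not None and len(self.basin_ids) != self.n_basins:
            raise ValueError("basin_ids length must equal n_basins")

    @property
    def basins(self) -> tuple[str, ...]:
        if self.basin_ids is not None:
            return tuple(self.basin_ids)
        return tuple(f"basin{i + 1}" for i in range(self.n_basins))

    def baseline_for(self, basin_index: int) -> float:
        if np.isscalar(self.baseline_mean):
            return float(self.baseline_mean)
        return float(self.baseline_mean[basin_index])

    @property
    def stations(self) -> tuple[tuple[str, str], ...]:
        """(station_id, basin_id) pairs, stations named <basin>-s<j>."""
        out = []
        for b in self.basins:
            for j in range(self.stations_per_basin):
                out.append((f"{b}-s{j + 1}", b))
        return tuple(out)


def generate_salinity(config: SalinityGenConfig) -> list[SalinitySeries]:
    """One daily series per station spanning Jan 1 of the first year to
    Dec 31 of the last, with events overwriting the baseline process.

    Overlapping events on the same station-dates are rejected.
    """
    start = dt.date(min(config.years), 1, 1)
    end = dt.date(max(config.years), 12, 31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal_shape = -np.cos(2 * np.pi * (doy - SEASONAL_MINIMUM_DOY) / 365.25)

    basin_index = {b: i for i, b in enumerate(config.basins)}
    innovation_sd = config.noise_sd * np.sqrt(1 - config.ar1_coefficient**2)

    out: list[SalinitySeries] = []
    for st_i, (station_id, basin_id) in enumerate(config.stations):
        rng = np.random.default_rng([config.seed, st_i])
        base = config.baseline_for(basin_index[basin_id]) + config.seasonal_amplitude * seasonal_shape
        noise = np.zeros(len(dates))
        if config.noise_sd > 0:
            e = rng.normal(0.0, innovation_sd, len(dates))
            e[0] = rng.normal(0.0, config.noise_sd)
            for t in range(1, len(dates)):
                e[t] += config.ar1_coefficient * e[t - 1]
            noise = e
        values = base + noise

        covered: set[pd.Timestamp] = set()
        for ev in config.events:
            if ev.basin_id != basin_id:
                continue
            if ev.station_ids is not None and station_id not in ev.station_ids:
                continue
            ev_dates = ev.dates
            clash = covered.intersection(ev_dates)
            if clash:
                raise ValueError(
                    f"overlapping low-salinity events on station {station_id} "
                    f"at {min(clash).date()}"
                )
            covered.update(ev_dates)
            mask = dates.isin(ev_dates)
            values[mask] = ev.target_level + rng.normal(0.0, EVENT_NOISE_SD, int(mask.sum()))

        values = np.clip(values, 0.0, None)
        out.append(SalinitySeries(station_id, basin_id, pd.Series(values, index=dates)))
    return out


# ---------------------------------------------------------------------------
# Abundance generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelTruth:
    """Known parameters behind a synthetic abundance table.

    ``gammas`` maps exposure covariate column names (e.g. ``c.d_su0.1``) to
    their slopes, selecting which exposure columns feed the linear predictor.
    ``step`` optionally records a non-linear step truth (covariate, day,
    drop, base) for changepoint fixtures.
    """

    basin_intercepts: dict[str, float]
    station_sd: float  # sd of station intercepts around their basin mean
    year_effects: dict[int, float]
    gammas: dict[str, float]
    sigma: float  # residual sd
    season: str = "fall"
    stage: str = "spat"
    step: dict | None = None

    def __post_init__(self) -> None:
        if self.station_sd < 0 or self.sigma < 0:
            raise ValueError("station_sd and sigma must be >= 0")


def generate_abundance(
    truth: ModelTruth, exposure: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Draw one abundance value per station-year from the multilevel model.

    ``exposure`` is the wide exposure table (station_id, basin_id, year +
    covariate columns) and must cover every station-year emitted.  Station
    intercepts are drawn once per station around the basin intercept;
    residuals are unbounded normal, so negative abundances can occur and
    are retained.
    """
    if "bin" in exposure.columns:
        exposure = exposure_wide(exposure)
    missing = [c for c in truth.gammas if c not in exposure.columns]
    if missing:
        raise KeyError(f"exposure table is missing covariate column(s): {missing}")
    unknown_years = set(exposure["year"].astype(int)) - set(truth.year_effects)
    if unknown_years:
        raise ValueError(f"truth has no year effect for years {sorted(unknown_years)}")

    rng = np.random.default_rng(seed)
    stations = sorted(exposure["station_id"].astype(str).unique())
    basin_of = (
        exposure.drop_duplicates("station_id").set_index("station_id")["basin_id"].to_dict()
    )
    station_intercepts = {}
    for s in stations:
        alpha = truth.basin_intercepts[str(basin_of[s])]
        station_intercepts[s] = rng.normal(alpha, truth.station_sd)

    rows = []
    for _, r in exposure.sort_values(["station_id", "year"]).iterrows():
        mu = station_intercepts[str(r["station_id"])]
        mu += truth.year_effects[int(r["year"])]
        for c, g in truth.gammas.items():
            mu += g * float(r[c])
        if truth.step is not None:
            x = float(r[truth.step["covariate"]])
            if x > truth.step["day"]:
                mu -= truth.step["drop"]
        rows.append(
            {
                "station_id": r["station_id"],
                "basin_id": r["basin_id"],
                "year": int(r["year"]),
                "season": truth.season,
                "stage": truth.stage,
                "abundance": mu + rng.normal(0.0, truth.sigma),
            }
        )
    return pd.DataFrame(rows)


def abundance_to_dredge_records(abundance: pd.DataFrame) -> pd.DataFrame:
    """Emit dredge-format records (two replicate monthly samples per season)
    whose seasonal mean equals each abundance value exactly (A-1 and A+1).

    Dredge counts cannot be negative, so replicates are clipped at zero; for
    abundance values below 1 the seasonal mean is therefore slightly biased,
    exactly as real near-zero counts would be.
    """
    rows = []
    for _, r in abundance.iterrows():
        sh = STAGE_SHELL_HEIGHT_MM[r["stage"]]
        for (month, day), delta in zip(SEASON_SAMPLE_DATES[r["season"]], (-1.0, 1.0)):
            rows.append(
                {
                    "station_id": r["station_id"],
                    "basin_id": r["basin_id"],
                    "date": dt.date(int(r["year"]), month, day).isoformat(),
                    "shell_height_class_mm": sh,
                    "count": max(0.0, float(r["abundance"]) + delta),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

EAST_BASINS = ("pontchartrain", "barataria", "terrebonne")

FIXTURE_SCENARIOS = ("null", "negative-slope-east", "rf-step")


@dataclass
class FixtureBundle:
    salinity: list[SalinitySeries]
    abundance: pd.DataFrame
    truth: ModelTruth
    exposure: pd.DataFrame  # wide, summer windows


def _varied_duration_events(
    config: SalinityGenConfig,
    rng: np.random.Generator,
    level: float,
    max_days: int = 80,
    start: dt.date | None = None,
) -> list[LowSalinityEvent]:
    """One summer event per station-year with duration ~ U{0..max_days}."""
    events = []
    for station_id, basin_id in config.stations:
        for year in config.years:
            d = int(rng.integers(0, max_days + 1))
            if d == 0:
                continue
            s = start or dt.date(year, 5, 5)
            events.append(
                LowSalinityEvent(
                    basin_id=basin_id,
                    station_ids=(station_id,),
                    start_date=dt.date(year, s.month, s.day),
                    duration_days=d,
                    target_level=level,
                )
            )
    return events


def _east_config(seed: int) -> SalinityGenConfig:
    return SalinityGenConfig(
        n_basins=3,
        stations_per_basin=2,
        years=(2016, 2017, 2018, 2019, 2020),
        baseline_mean=(13.0, 12.5, 13.5),
        seasonal_amplitude=1.5,
        ar1_coefficient=0.7,
        noise_sd=0.6,
        seed=seed,
        basin_ids=EAST_BASINS,
    )


def _linear_fixture(seed: int, gamma: float) -> FixtureBundle:
    rng = np.random.default_rng([seed, 1])
    config = _east_config(seed)
    # Durations capped at 60 days keep the basin-mean abundance positive at
    # the planted slope, as a real monitoring series would be.
    config = replace(
        config, events=tuple(_varied_duration_events(config, rng, level=0.5, max_days=60))
    )
    salinity = generate_salinity(config)
    exposure = exposure_wide(build_exposure_table(salinity, config.years))
    truth = ModelTruth(
        basin_intercepts={"pontchartrain": 28.0, "barataria": 32.0, "terrebonne": 30.0},
        station_sd=1.5,
        year_effects={y: e for y, e in zip(config.years, (1.0, -1.0, 0.5, -0.5, 0.0))},
        gammas={"c.d_su0.1": gamma},
        sigma=3.5,
    )
    abundance = generate_abundance(truth, exposure, seed=seed + 101)
    return FixtureBundle(salinity, abundance, truth, exposure)


def _rf_step_fixture(seed: int) -> FixtureBundle:
    # Baseline well above 9 psu keeps the non-event bins empty: the 1-3 bin
    # column pair carries all the signal and the other covariates are
    # constant zeros the forest never splits on.
    config = _east_config(seed)
    # One event per station-year; a deterministic spread of durations with
    # neighbours straddling the planted changepoint at 40 days so tree splits
    # land between 38 and 42.  With a single run the total-days and
    # maximum-consecutive-days statistics of the 1-3 bin coincide, so the
    # planted signal lives in that column pair and every other covariate is
    # (near-)constant.
    durations = [5, 10, 15, 20, 25, 30, 34, 38, 42, 46, 50, 55, 60, 65, 70, 75, 77, 36, 44, 28,
                 12, 22, 32, 48, 58, 68, 76, 18, 40, 62]
    events = []
    i = 0
    for station_id, basin_id in config.stations:
        for year in config.years:
            main = durations[i % len(durations)]
            i += 1
            events.append(
                LowSalinityEvent(
                    basin_id=basin_id,
                    station_ids=(station_id,),
                    start_date=dt.date(year, 6, 15),
                    duration_days=main,
                    target_level=2.0,
                )
            )
    config = replace(config, events=tuple(events))
    salinity = generate_salinity(config)
    exposure = exposure_wide(build_exposure_table(salinity, config.years))
    truth = ModelTruth(
        basin_intercepts={b: 30.0 for b in EAST_BASINS},
        station_sd=0.0,
        year_effects={y: 0.0 for y in config.years},
        gammas={},
        sigma=0.5,
        step={"covariate": "c.d_su1.3", "day": 40, "drop": 25.0},
    )
    abundance = generate_abundance(truth, exposure, seed=seed + 202)
    return FixtureBundle(salinity, abundance, truth, exposure)


def make_fixture(scenario: str, seed: int = 0) -> FixtureBundle:
    """Small canned datasets with stored truth.

    Scenarios: ``"null"`` (all slopes zero), ``"negative-slope-east"``
    (slope -0.6 on continuous days of salinity < 1), ``"rf-step"``
    (abundance drops by 15 once continuous days in the 1-3 bin exceed 40).
    """
    if scenario == "null":
        return _linear_fixture(seed, gamma=0.0)
    if scenario == "negative-slope-east":
        return _linear_fixture(seed, gamma=-0.6)
    if scenario == "rf-step":
        return _rf_step_fixture(seed)
    raise KeyError(f"unknown scenario {scenario!r}; known: {FIXTURE_SCENARIOS}")


def make_recovery_dataset(
    seed: int,
    gamma: float = -0.6,
    sigma: float = 5.0,
    n_basins: int = 3,
    stations_per_basin: int = 6,
) -> FixtureBundle:
    """A parameter-recovery dataset: n_basins x stations_per_basin stations
    x 5 years with a known slope on continuous days of salinity < 1.
    """
    config = SalinityGenConfig(
        n_basins=n_basins,
        stations_per_basin=stations_per_basin,
        years=(2016, 2017, 2018, 2019, 2020),
        baseline_mean=12.0,
        seasonal_amplitude=2.0,
        ar1_coefficient=0.7,
        noise_sd=0.8,
        seed=seed,
    )
    rng = np.random.default_rng([seed, 3])
    config = replace(
        config, events=tuple(_varied_duration_events(config, rng, level=0.5, max_days=100))
    )
    salinity = generate_salinity(config)
    exposure = exposure_wide(build_exposure_table(salinity, config.years))
    basins = config.basins
    truth = ModelTruth(
        basin_intercepts={b: 45.0 + 3.0 * i for i, b in enumerate(basins)},
        station_sd=2.0,
        year_effects={y: e for y, e in zip(config.years, (1.0, -1.0, 0.5, -0.5, 0.0))},
        gammas={"c.d_su0.1": gamma},
        sigma=sigma,
    )
    abundance = generate_abundance(truth, exposure, seed=seed + 404)
    return FixtureBundle(salinity, abundance, truth, exposure)


# ---------------------------------------------------------------------------
# Truth persistence (plain-text key-value sidecar)
# ---------------------------------------------------------------------------


def truth_to_text(truth: ModelTruth) -> str:
    lines = []
    for b, v in sorted(truth.basin_intercepts.items()):
        lines.append(f"basin_intercept.{b} = {v!r}")
    for y, v in sorted(truth.year_effects.items()):
        lines.append(f"year_effect.{y} = {v!r}")
    for c, g in sorted(truth.gammas.items()):
        lines.append(f"gamma.{c} = {g!r}")
    lines.append(f"station_sd = {truth.station_sd!r}")
    lines.append(f"sigma = {truth.sigma!r}")
    lines.append(f"season = {truth.season}")
    lines.append(f"stage = {truth.stage}")
    if truth.step is not None:
        for k, v in sorted(truth.step.items()):
            lines.append(f"step.{k} = {v!r}")
    return "\n".join(lines) + "\n"
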