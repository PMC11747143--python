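"""Low-salinity exposure covariates.

Daily mean salinity is discretised into five bins (0-1, >1-3, >3-5, >5-7,
>7-9 psu) and, for each station, window (summer = May 1 - Aug 31, or the
calendar year) and bin, two exposure statistics are computed:

* ``total_days``   -- number of window days whose salinity falls in the bin;
* ``max_consecutive_days`` -- the longest run of consecutive calendar days in
  the window all falling in the bin.

These are the covariates S<1, S1-3, S3-5, S5-7, S7-9 of the downstream
abundance models (one column per bin x statistic).  Cumulative "days below a
level" counts (< 1, < 3, < 5, < 7, < 9) are also provided.

Conventions (documented choices; the bin notation leaves edge behaviour
open):

* bins are lower-open / upper-closed, except "0-1" which is closed on both
  sides -- a day at exactly 5.0 psu counts in "3-5";
* "below level x" means strictly ``value < x``;
* a missing day is never counted and breaks a consecutive run;
* the summer window has a fixed length of 123 days in every year; the
  calendar window uses the true day count (366 in leap years).
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Bins and windows
# ---------------------------------------------------------------------------

BIN_LABELS: tuple[str, ...] = ("0-1", "1-3", "3-5", "5-7", "7-9")
BELOW_LEVELS: tuple[int, ...] = (1, 3, 5, 7, 9)

#: Fixed number of days from May 1 to Aug 31 inclusive (May 31 + Jun 30 +
#: Jul 31 + Aug 31).
SUMMER_DAYS: int = 123

#: Day count used by the random-forest interpretation rule for calendar-year
#: covariates (a constant, ignoring leap years).
CALENDAR_DAYS_NOMINAL: int = 365


@dataclass(frozen=True)
class SalinityBin:
    """One salinity interval; ``lower`` is open unless it is 0, ``upper`` closed."""

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"bin {self.label!r}: lower must be < upper")

    def contains(self, value: float) -> bool:
        if self.lower == 0.0:
            return 0.0 <= value <= self.upper
        return self.lower < value <= self.upper


DEFAULT_BINS: tuple[SalinityBin, ...] = (
    SalinityBin("0-1", 0.0, 1.0),
    SalinityBin("1-3", 1.0, 3.0),
    SalinityBin("3-5", 3.0, 5.0),
    SalinityBin("5-7", 5.0, 7.0),
    SalinityBin("7-9", 7.0, 9.0),
)

_BIN_BY_LABEL = {b.label: b for b in DEFAULT_BINS}


def bin_by_label(label: str) -> SalinityBin:
    """Look up one of the five standard bins by its label."""
    try:
        return _BIN_BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown salinity bin {label!r}; known: {BIN_LABELS}") from None


def assign_bin(value: float) -> str | None:
    """Return the bin label for a daily salinity value, or None above 9 psu.

    Raises ValueError for negative salinity.
    """
    if value < 0:
        raise ValueError(f"salinity must be non-negative, got {value}")
    for b in DEFAULT_BINS:
        if b.contains(value):
            return b.label
    return None


@dataclass(frozen=True)
class Window:
    """An exposure window: the summer (May 1 - Aug 31) or a calendar year."""

    kind: str  # "summer" | "calendar"
    year: int

    def __post_init__(self) -> None:
        if self.kind not in ("summer", "calendar"):
            raise ValueError(f"window kind must be 'summer' or 'calendar', got {self.kind!r}")

    @property
    def start(self) -> dt.date:
        return dt.date(self.year, 5, 1) if self.kind == "summer" else dt.date(self.year, 1, 1)

    @property
    def end(self) -> dt.date:
        return dt.date(self.year, 8, 31) if self.kind == "summer" else dt.date(self.year, 12, 31)

    @property
    def code(self) -> str:
        return "su" if self.kind == "summer" else "an"


def window_days(window: Window) -> int:
    """Length of the window in days: 123 for every summer, 365/366 for calendar years."""
    if window.kind == "summer":
        return SUMMER_DAYS
    return 366 if calendar.isleap(window.year) else 365


# ---------------------------------------------------------------------------
# Salinity series
# ---------------------------------------------------------------------------


@dataclass
class SalinitySeries:
    """One station's dated daily mean salinity.

    ``values`` is a pandas Series indexed by a DatetimeIndex of strictly
    increasing dates; NaN marks a missing day.
    """

    station_id: str
    basin_id: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.values.index)
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError(
                f"station {self.station_id}: dates must be strictly increasing"
            )
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError(f"station {self.station_id}: negative salinity values")
        idx = idx.rename(None)
        self.values = pd.Series(vals, index=idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "basin_id": self.basin_id,
                "date": self.values.index,
                "salinity": self.values.to_numpy(),
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> list["SalinitySeries"]:
        """Split a tidy (station_id, basin_id, date, salinity) frame into series."""
        out = []
        for (st, ba), grp in df.groupby(["station_id", "basin_id"], sort=True):
            s = pd.Series(
                grp["salinity"].to_numpy(dtype=float),
                index=pd.DatetimeIndex(pd.to_datetime(grp["date"])),
            ).sort_index()
            out.append(SalinitySeries(str(st), str(ba), s))
        return out


def _window_values(series: SalinitySeries, window: Window) -> np.ndarray:
    """Daily values over the full window date range, NaN where missing."""
    start, end = pd.Timestamp(window.start), pd.Timestamp(window.end)
    idx = series.values.index
    if idx[-1] < start or idx[0] > end:
        raise ValueError(
            f"station {series.station_id}: window {window.kind} {window.year} "
            f"entirely outside series range {idx[0].date()}..{idx[-1].date()}"
        )
    full = pd.date_range(start, end, freq="D")
    return series.values.reindex(full).to_numpy(dtype=float)


def _in_bin_mask(values: np.ndarray, b: SalinityBin) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if b.lower == 0.0:
            mask = (values >= 0.0) & (values <= b.upper)
        else:
            mask = (values > b.lower) & (values <= b.upper)
    return mask & ~np.isnan(values)


def _max_run(mask: np.ndarray) -> int:
    """Longest run of consecutive True values."""
    if not mask.any():
        return 0
    padded = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[::2]).max())


def total_days_in_bin(series: SalinitySeries, window: Window, b: SalinityBin) -> int:
    """Number of window days whose salinity falls in the bin; missing days excluded."""
    return int(_in_bin_mask(_window_values(series, window), b).sum())


def max_consecutive_days_in_bin(
    series: SalinitySeries, window: Window, b: SalinityBin
) -> int:
    """Longest run of consecutive window days in the bin; a missing day breaks a run."""
    return _max_run(_in_bin_mask(_window_values(series, window), b))


def total_days_below(series: SalinitySeries, window: Window, level: float) -> int:
    """Window days with salinity strictly below ``level`` (one of 1, 3, 5, 7, 9)."""
    if level not in BELOW_LEVELS:
        raise ValueError(f"level must be one of {BELOW_LEVELS}, got {level}")
    vals = _window_values(series, window)
    with np.errstate(invalid="ignore"):
        return int(((vals < level) & ~np.isnan(vals)).sum())


def max_consecutive_days_below(
    series: SalinitySeries, window: Window, level: float
) -> int:
    """Longest run of consecutive window days strictly below ``level``."""
    if level not in BELOW_LEVELS:
        raise ValueError(f"level must be one of {BELOW_LEVELS}, got {level}")
    vals = _window_values(series, window)
    with np.errstate(invalid="ignore"):
        mask = (vals < level) & ~np.isnan(vals)
    return _max_run(mask)


# ---------------------------------------------------------------------------
# Exposure table
# ---------------------------------------------------------------------------


def covariate_name(window_kind: str, b: SalinityBin, statistic: str) -> str:
    """Column name for one exposure covariate.

    Total-days columns are ``s_d_<win><lo>.<hi>`` and maximum-consecutive
    columns ``c.d_<win><lo>.<hi>`` with ``<win>`` 'su' (summer) or 'an'
    (calendar year), e.g. ``s_d_su7.9`` / ``c.d_su7.9``.
    """
    code = "su" if window_kind == "summer" else "an"
    prefix = {"total": "s_d", "consecutive": "c.d"}[statistic]
    return f"{prefix}_{code}{b.lower:g}.{b.upper:g}"


def parse_covariate_name(name: str) -> tuple[str, str, SalinityBin]:
    """Invert :func:`covariate_name` -> (statistic, window_kind, bin)."""
    import re

    m = re.fullmatch(r"(s_d|c\.d)_(su|an)(\d+(?:\.\d+)?)\.(\d+(?:\.\d+)?)", name)
    if m is None:
        raise ValueError(f"not an exposure covariate name: {name!r}")
    statistic = "total" if m.group(1) == "s_d" else "consecutive"
    window_kind = "summer" if m.group(2) == "su" else "calendar"
    lower, upper = float(m.group(3)), float(m.group(4))
    for b in DEFAULT_BINS:
        if b.lower == lower and b.upper == upper:
            return statistic, window_kind, b
    return statistic, window_kind, SalinityBin(f"{lower:g}-{upper:g}", lower, upper)


def build_exposure_table(
    series: Iterable[SalinitySeries],
    years: Sequence[int],
    window_kinds: Sequence[str] = ("summer",),
    bins: Sequence[SalinityBin] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Tidy per station-year-window-bin exposure counts.

    Columns: station_id, basin_id, year, window, bin, total_days,
    max_consecutive_days.  One station-year with summer windows yields
    5 bins x 2 statistics = 10 covariates in the wide layout
    (:func:`exposure_wide`); adding calendar windows doubles that to 20.
    """
    series = list(series)
    rows = []
    seen: set[tuple[str, int]] = set()
    for s in series:
        n_missing = int(s.values.isna().sum())
        if n_missing:
            logger.warning(
                "station %s: %d missing daily salinity values", s.station_id, n_missing
            )
        for year in years:
            key = (s.station_id, year)
            if key in seen:
                raise ValueError(f"duplicate station-year rows: {key}")
            for kind in window_kinds:
                w = Window(kind, year)
                vals = _window_values(s, w)
                for b in bins:
                    mask = _in_bin_mask(vals, b)
                    rows.append(
                        {
                            "station_id": s.station_id,
                            "basin_id": s.basin_id,
                            "year": year,
                            "window": kind,
                            "bin": b.label,
                            "total_days": int(mask.sum()),
                            "max_consecutive_days": _max_run(mask),
                        }
                    )
        seen.update((s.station_id, y) for y in years)
    cols = [
        "station_id",
        "basin_id",
        "year",
        "window",
        "bin",
        "total_days",
        "max_consecutive_days",
    ]
    return pd.DataFrame(rows, columns=cols)


def exposure_wide(table: pd.DataFrame, bins: Sequence[SalinityBin] = DEFAULT_BINS) -> pd.DataFrame:
    """Pivot the tidy exposure table to one row per station-year with named covariate columns."""
    by_label = {b.label: b for b in bins}
    if table.empty:
        return pd.DataFrame(columns=["station_id", "basin_id", "year"])
    pieces = []
    for (kind,), grp in table.groupby(["window"]):
        for stat, col in (("total", "total_days"), ("consecutive", "max_consecutive_days")):
            wide = grp.pivot_table(
                index=["station_id", "basin_id", "year"],
                columns="bin",
                values=col,
                aggfunc="first",
            )
            wide.columns = [covariate_name(kind, by_label[lbl], stat) for lbl in wide.columns]
            pieces.append(wide)
    out = pd.concat(pieces, axis=1).reset_index()
    return out
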