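"""Exposure covariates: binning, windows, day counts vs brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from salthresh.exposure import (
    DEFAULT_BINS,
    SUMMER_DAYS,
    Window,
    assign_bin,
    bin_by_label,
    build_exposure_table,
    covariate_name,
    exposure_wide,
    max_consecutive_days_below,
    max_consecutive_days_in_bin,
    parse_covariate_name,
    total_days_below,
    total_days_in_bin,
    window_days,
)

from conftest import make_series


# -- independent oracles -----------------------------------------------------


def in_bin(value, b):
    if math.isnan(value):
        return False
    if b.lower == 0.0:
        return 0.0 <= value <= b.upper
    return b.lower < value <= b.upper


def brute_total(values, b):
    return sum(1 for v in values if in_bin(v, b))


def brute_max_run(values, b):
    best = run = 0
    for v in values:
        run = run + 1 if in_bin(v, b) else 0
        best = max(best, run)
    return best


# -- binning and windows -----------------------------------------------------


@pytest.mark.parametrize(
    "value,label",
    [
        (0.0, "0-1"),
        (0.5, "0-1"),
        (1.0, "0-1"),  # upper edge closed
        (1.0001, "1-3"),
        (3.0, "1-3"),
        (5.0, "3-5"),
        (7.0, "5-7"),
        (9.0, "7-9"),
        (9.5, None),
        (34.3, None),
    ],
)
def test_assign_bin(value, label):
    assert assign_bin(value) == label


def test_assign_bin_rejects_negative():
    with pytest.raises(ValueError):
        assign_bin(-0.1)


def test_bins_partition_zero_to_nine():
    """The five bins tile [0, 9] with no gaps or overlaps."""
    for v in np.linspace(0, 9, 1001):
        hits = [b.label for b in DEFAULT_BINS if b.contains(v)]
        assert len(hits) == 1


@pytest.mark.parametrize("year", range(2016, 2021))
def test_summer_window_always_123_days(year):
    w = Window("summer", year)
    assert window_days(w) == 123
    assert (w.end - w.start).days + 1 == 123


@pytest.mark.parametrize("year,n", [(2016, 366), (2017, 365), (2020, 366)])
def test_calendar_window_days(year, n):
    assert window_days(Window("calendar", year)) == n


def test_window_rejects_bad_kind():
    with pytest.raises(ValueError):
        Window("spring", 2018)


# -- day counts --------------------------------------------------------------


def test_constant_high_salinity_counts_nothing():
    s = make_series([10.0] * 200, start="2018-01-01")
    w = Window("summer", 2018)
    for b in DEFAULT_BINS:
        assert total_days_in_bin(s, w, b) == 0
    for level in (1, 3, 5, 7, 9):
        assert total_days_below(s, w, level) == 0


def test_hand_countable_max_run():
    # days [4,4,6,4,4,4] in bin 3-5 -> longest run 3
    s = make_series([4, 4, 6, 4, 4, 4] + [10] * 120, start="2018-05-01")
    assert max_consecutive_days_in_bin(s, Window("summer", 2018), bin_by_label("3-5")) == 3
    assert total_days_in_bin(s, Window("summer", 2018), bin_by_label("3-5")) == 5


def test_forty_day_event_counts():
    """A 40-day run at 2 psu amid 10 psu gives 40 in bin 1-3, both statistics."""
    vals = [10.0] * 123
    vals[20:60] = [2.0] * 40
    s = make_series(vals, start="2018-05-01")
    w = Window("summer", 2018)
    b = bin_by_label("1-3")
    assert total_days_in_bin(s, w, b) == brute_total(vals, b) == 40
    assert max_consecutive_days_in_bin(s, w, b) == brute_max_run(vals, b) == 40
    assert total_days_below(s, w, 9) == 40
    assert total_days_below(s, w, 1) == 0
    assert max_consecutive_days_below(s, w, 3) == 40


def test_missing_day_breaks_run_and_is_never_counted():
    vals = [2.0] * 10 + [np.nan] + [2.0] * 5 + [10.0] * 107
    s = make_series(vals, start="2018-05-01")
    w = Window("summer", 2018)
    b = bin_by_label("1-3")
    assert total_days_in_bin(s, w, b) == 15
    assert max_consecutive_days_in_bin(s, w, b) == 10


def test_window_outside_series_errors():
    s = make_series([5.0] * 30, start="2018-05-01")
    with pytest.raises(ValueError, match="outside series"):
        total_days_in_bin(s, Window("summer", 2025), bin_by_label("3-5"))


def test_below_level_monotone_and_strict():
    vals = [0.5, 1.0, 2.0, 5.0, 7.0, 8.9] + [10.0] * 117
    s = make_series(vals, start="2018-05-01")
    w = Window("summer", 2018)
    counts = [total_days_below(s, w, lev) for lev in (1, 3, 5, 7, 9)]
    assert counts == sorted(counts)
    # strict inequality: the day at exactly 1.0 is not "< 1"
    assert counts[0] == 1
    with pytest.raises(ValueError):
        total_days_below(s, w, 4)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    values=hst.lists(
        hst.one_of(
            hst.floats(min_value=0, max_value=12, allow_nan=False),
            hst.just(float("nan")),
        ),
        min_size=123,
        max_size=200,
    )
)
def test_counts_match_brute_force(values):
    """Totals and max-consecutive runs agree with a day-by-day scan oracle."""
    s = make_series(values, start="2018-05-01")
    w = Window("summer", 2018)
    window_vals = [
        float(s.values.get(d, np.nan)) for d in pd.date_range(w.start, w.end, freq="D")
    ]
    for b in DEFAULT_BINS:
        assert total_days_in_bin(s, w, b) == brute_total(window_vals, b)
        assert max_consecutive_days_in_bin(s, w, b) == brute_max_run(window_vals, b)
        assert max_consecutive_days_in_bin(s, w, b) <= total_days_in_bin(s, w, b)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    values=hst.lists(
        hst.one_of(
            hst.floats(min_value=0, max_value=12, allow_nan=False),
            hst.just(float("nan")),
        ),
        min_size=123,
        max_size=123,
    )
)
def test_partition_of_window_days(values):
    """Bin totals + days above 9 + missing days tile the window exactly."""
    s = make_series(values, start="2018-05-01")
    w = Window("summer", 2018)
    total = sum(total_days_in_bin(s, w, b) for b in DEFAULT_BINS)
    above = sum(1 for v in values if not math.isnan(v) and v > 9)
    missing = sum(1 for v in values if math.isnan(v))
    assert total + above + missing == SUMMER_DAYS


# -- table building ----------------------------------------------------------


def test_exposure_table_ten_summer_covariates():
    s = make_series([8.0] * 365, start="2018-01-01")
    tidy = build_exposure_table([s], years=[2018], window_kinds=("summer",))
    assert len(tidy) == 5
    wide = exposure_wide(tidy)
    covs = [c for c in wide.columns if c not in ("station_id", "basin_id", "year")]
    assert len(covs) == 10
    assert "s_d_su7.9" in covs and "c.d_su7.9" in covs
    assert wide.loc[0, "s_d_su7.9"] == 123


def test_exposure_table_twenty_covariates_with_calendar():
    s = make_series([8.0] * 365, start="2018-01-01")
    tidy = build_exposure_table([s], years=[2018], window_kinds=("summer", "calendar"))
    wide = exposure_wide(tidy)
    covs = [c for c in wide.columns if c not in ("station_id", "basin_id", "year")]
    assert len(covs) == 20
    assert "s_d_an7.9" in covs


def test_empty_series_set_gives_empty_table():
    tidy = build_exposure_table([], years=[2018])
    assert tidy.empty
    assert exposure_wide(tidy).empty


def test_duplicate_station_year_rejected():
    s1 = make_series([8.0] * 365, start="2018-01-01", station="s1")
    s2 = make_series([8.0] * 365, start="2018-01-01", station="s1", basin="terrebonne")
    with pytest.raises(ValueError, match="duplicate"):
        build_exposure_table([s1, s2], years=[2018])


def test_exposure_table_invariants_on_fixture():
    from salthresh.synthetic import make_fixture

    bundle = make_fixture("negative-slope-east", seed=0)
    covs = [c for c in bundle.exposure.columns if c.startswith(("s_d", "c.d"))]
    totals = bundle.exposure[[c for c in covs if c.startswith("s_d")]]
    consec = bundle.exposure[[c for c in covs if c.startswith("c.d")]]
    assert (totals.to_numpy() <= SUMMER_DAYS).all()
    assert (totals.sum(axis=1) <= SUMMER_DAYS).all()
    assert (consec.to_numpy() <= totals.to_numpy()).all()


@pytest.mark.parametrize("name", ["s_d_su0.1", "c.d_su7.9", "s_d_an3.5"])
def test_covariate_name_round_trip(name):
    stat, kind, b = parse_covariate_name(name)
    assert covariate_name(kind, b, stat) == name


def test_parse_rejects_garbage():
    with pytest.raises(ValueError):
        parse_covariate_name("salinity_mean")
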