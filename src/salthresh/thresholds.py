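"""Turning fitted models into day-count exposure thresholds.

Two operational definitions are supported:

* **Bayesian critical-abundance crossing** — run a final single-covariate
  model across exposure day counts d = 0..123 and report the smallest d at
  which the posterior median of predicted abundance drops below the critical
  abundance (50% of the 5-year mean).  "More than 50% probability of being
  below the critical level" is operationalised as the posterior median of
  the predicted mean lying below it, which is equivalent for a continuous
  posterior.  Thresholds are derived only for negative covariate effects
  (negative-50 classification or stronger); positive effects mean a
  low-salinity day threshold cannot be detected this way.

* **Random-forest interpretation rule** — a partial-dependence changepoint
  of d days in a "safe" salinity bin (abundance rising with days in that
  bin) converts to a low-salinity threshold of (window length - d) days
  below the bin's lower bound, using the constants 123 (summer) and 365
  (calendar year).  When the partial dependence instead declines within a
  low bin itself, the changepoint is the threshold directly (no
  subtraction) and the level is the bin's upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import FitResult, classify_effect
from .collate import CriticalAbundance
from .exposure import CALENDAR_DAYS_NOMINAL, SUMMER_DAYS, SalinityBin


class PositiveEffectError(ValueError):
    """Raised when a threshold sweep is requested for a non-negative effect."""


@dataclass(frozen=True)
class ThresholdResult:
    """A detected low-salinity exposure threshold."""

    method: str  # "bayes" | "rf"
    salinity: str  # e.g. "< 5"
    exposure_kind: str  # "total" | "continuous"
    days: int | None  # None when the criterion is never met in the window
    window_kind: str = "summer"
    region: str | None = None
    basin: str | None = None
    season: str | None = None
    stage: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.days is not None:
            limit = SUMMER_DAYS if self.window_kind == "summer" else CALENDAR_DAYS_NOMINAL
            if not 0 <= self.days <= limit:
                raise ValueError(f"day count {self.days} outside [0, {limit}]")


def predict_abundance(fit: FitResult, basin: str, d: float) -> np.ndarray:
    """Posterior draws of mean abundance in ``basin`` at d days of exposure.

    Uses the basin-level intercept draws (alpha), the year effects averaged
    over posterior year intercepts, and the single exposure slope (plus its
    squared term for quadratic fits).
    """
    if len(fit.spec.covariates) != 1:
        raise ValueError("prediction requires a single-covariate final model")
    draws = fit.draws
    if fit.spec.has_basin:
        key = f"alpha[{basin}]"
        if key not in draws.params:
            raise KeyError(f"basin {basin!r} absent from fit (has {fit.basin_ids})")
        pred = draws[key].copy()
    else:
        pred = draws["mu0"].copy()
    if fit.spec.has_year:
        lam = np.column_stack([draws[f"lam[{k}]"] for k in fit.year_ids])
        pred = pred + lam.mean(axis=1)
    cov = fit.spec.covariates[0]
    pred = pred + draws[f"gamma[{cov}]"] * d
    if fit.spec.quadratic:
        pred = pred + draws[f"gamma[{cov}^2]"] * d**2
    return pred


def sweep_threshold(
    fit: FitResult,
    basin: str,
    critical: CriticalAbundance,
    window_length: int = SUMMER_DAYS,
    exposure_kind: str = "continuous",
    salinity: str | None = None,
    region: str | None = None,
) -> ThresholdResult:
    """Smallest integer day count at which predicted median abundance drops
    below the critical abundance; ``days=None`` if the median never crosses
    within the window.

    Only valid for fits whose covariate effect is classified negative
    (negative-50 or stronger); anything else raises
    :class:`PositiveEffectError`.
    """
    cov = fit.spec.covariates[0]
    cls = classify_effect(fit, cov)
    if cls not in ("negative-50", "negative-95"):
        raise PositiveEffectError(
            f"threshold sweep requires a negative covariate effect, got {cls!r} "
            f"for {cov!r}: day thresholds cannot be detected for non-negative relations"
        )
    days = np.arange(window_length + 1)
    base = predict_abundance(fit, basin, 0.0)
    gamma = fit.draws[f"gamma[{cov}]"]
    # medians of base + gamma*d (+ gamma2*d^2) per day, vectorised over the grid
    curves = base[:, None] + gamma[:, None] * days[None, :]
    if fit.spec.quadratic:
        curves = curves + fit.draws[f"gamma[{cov}^2]"][:, None] * (days**2)[None, :]
    medians = np.median(curves, axis=0)
    below = np.flatnonzero(medians < critical.value)
    hit = int(below[0]) if below.size else None
    note = (
        ">50% probability below critical abundance"
        if hit is not None
        else "predicted median abundance never fell below the critical abundance"
    )
    return ThresholdResult(
        method="bayes",
        salinity=salinity or cov,
        exposure_kind=exposure_kind,
        days=hit,
        window_kind="summer" if window_length == SUMMER_DAYS else "calendar",
        region=region,
        basin=basin,
        season=critical.season,
        stage=critical.stage,
        note=f"{note} ({cls})",
    )


def rf_interpretation_rule(
    window_kind: str,
    changepoint_days: int,
    b: SalinityBin,
    exposure_kind: str,
    mode: str = "subtract",
    region: str | None = None,
    season: str | None = None,
    stage: str | None = None,
) -> ThresholdResult:
    """Convert a partial-dependence changepoint into a low-salinity threshold.

    ``mode='subtract'`` (the default, for a rising dependence in a safe
    bin): threshold = (window constant - changepoint) days below the bin's
    lower bound — e.g. a changepoint at 30 days in the 7-9 summer bin gives
    "< 7 for 93 days".  ``mode='direct'`` (dependence declining within a low
    bin itself): the changepoint is the threshold and the level is the
    bin's upper bound — e.g. decline after 60 total days below 1 gives
    "< 1 for 60 days".
    """
    if window_kind not in ("summer", "calendar"):
        raise ValueError(f"window_kind must be 'summer' or 'calendar', got {window_kind!r}")
    if mode not in ("subtract", "direct"):
        raise ValueError(f"mode must be 'subtract' or 'direct', got {mode!r}")
    limit = SUMMER_DAYS if window_kind == "summer" else CALENDAR_DAYS_NOMINAL
    if not 0 <= changepoint_days <= limit:
        raise ValueError(f"changepoint {changepoint_days} outside [0, {limit}]")
    if mode == "subtract":
        days = limit - int(changepoint_days)
        level = b.lower
    else:
        days = int(changepoint_days)
        level = b.upper
    return ThresholdResult(
        method="rf",
        salinity=f"< {level:g}",
        exposure_kind=exposure_kind,
        days=days,
        window_kind=window_kind,
        region=region,
        season=season,
        stage=stage,
        note=f"{mode} rule from changepoint at {int(changepoint_days)} days in bin {b.label}",
    )
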