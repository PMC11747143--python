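"""Random-forest branch: fit, screen, select, partial dependence, changepoint.

A regression forest is fit to the exposure covariates with conventional
regression-forest defaults (500 trees, p/3 candidate variables per split,
minimum node size 5).  Models are screened by out-of-bag r-squared
(1 - OOB-MSE / Var(y)); only models above the retention threshold (0.75 by
default) are interpreted.  Variable importance is the impurity-based
(node-purity) measure; when the top three importances are tightly grouped
(within a configurable relative tolerance of the leader, 20% by default)
the variable with the lowest salinity bin among them is selected for
interpretation, otherwise the most important one.

The partial dependence of predicted abundance on the selected covariate is
computed by brute-force averaging (substitute each grid day value into every
training row and average the predictions), and the changepoint is the grid
day with the largest absolute first difference of a lightly smoothed curve
(centred moving average of width 3), ties broken toward the smaller day.
A manual override channel lets externally determined changepoints (e.g.
read off a published plot) feed the interpretation rule directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error

from .exposure import parse_covariate_name

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFSettings:
    n_trees: int = 500
    max_features: float = 1 / 3  # fraction of covariates tried per split
    min_node_size: int = 5
    seed: int = 0
    r2_retention: float = 0.75
    cluster_tolerance: float = 0.20  # "tightly grouped" = within 20% of the leader

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.r2_retention < 1:
            raise ValueError("r2_retention must be in (0, 1)")


@dataclass
class RFFit:
    model: RandomForestRegressor = field(repr=False)
    feature_names: tuple[str, ...]
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    oob_r2: float = float("nan")
    retained: bool = False
    settings: RFSettings = field(default_factory=RFSettings)


@dataclass
class PDPCurve:
    """Partial-dependence estimates of predicted abundance over a day grid."""

    variable: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be sorted strictly ascending")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("partial-dependence values must be finite")


def fit_rf(X: pd.DataFrame, y: np.ndarray, settings: RFSettings | None = None) -> RFFit:
    """Fit a regression forest and screen it by out-of-bag r-squared."""
    settings = settings or RFSettings()
    y = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise ValueError(f"need at least 10 observations, got {len(X)}")
    if X.isna().any().any():
        raise ValueError("covariate columns must be complete (no NaN)")
    if np.var(y) == 0:
        raise ValueError("constant response: r-squared is undefined")
    model = RandomForestRegressor(
        n_estimators=settings.n_trees,
        max_features=settings.max_features,
        min_samples_leaf=settings.min_node_size,
        oob_score=True,
        bootstrap=True,
        random_state=settings.seed,
        n_jobs=1,
    )
    model.fit(X.to_numpy(dtype=float), y)
    oob_pred = model.oob_prediction_
    oob_r2 = 1.0 - mean_squared_error(y, oob_pred) / float(np.var(y))
    retained = bool(oob_r2 > settings.r2_retention)
    if not retained:
        logger.info("model not retained: OOB r^2 %.3f <= %.2f", oob_r2, settings.r2_retention)
    return RFFit(
        model=model,
        feature_names=tuple(X.columns),
        X=X.copy(),
        y=y,
        oob_r2=oob_r2,
        retained=retained,
        settings=settings,
    )


def variable_importance(fit: RFFit) -> pd.Series:
    """Impurity-based (node-purity) importances, sorted descending."""
    imp = pd.Series(fit.model.feature_importances_, index=list(fit.feature_names))
    return imp.sort_values(ascending=False, kind="stable")


def _bin_lower(name: str) -> float:
    try:
        _, _, b = parse_covariate_name(name)
        return b.lower
    except ValueError:
        return float("inf")  # non-exposure covariates never win the low-bin rule


def select_interpretation_variable(
    importance: pd.Series, cluster_tolerance: float = 0.20
) -> str:
    """Pick the covariate to interpret from the importance ranking.

    If the 2nd and 3rd importances are within ``cluster_tolerance``
    (relative) of the leader, the top three are "tightly grouped" and the
    one with the lowest salinity bin is chosen; otherwise the most important
    variable wins.
    """
    if len(importance) < 3:
        raise ValueError("need at least 3 ranked variables")
    ranked = importance.sort_values(ascending=False, kind="stable")
    top3 = ranked.iloc[:3]
    leader = float(top3.iloc[0])
    grouped = cluster_tolerance > 0 and all(
        float(v) >= (1.0 - cluster_tolerance) * leader for v in top3
    )
    if grouped:
        return min(top3.index, key=_bin_lower)
    return str(ranked.index[0])


def partial_dependence(fit: RFFit, variable: str, grid: np.ndarray | None = None) -> PDPCurve:
    """Brute-force partial dependence: average prediction over training rows
    with ``variable`` substituted by each grid value.

    The default grid is the integers spanning the observed range of the
    variable.
    """
    if variable not in fit.feature_names:
        raise KeyError(f"variable {variable!r} not in model ({fit.feature_names})")
    col = fit.X[variable].to_numpy(dtype=float)
    if grid is None:
        grid = np.arange(int(np.floor(col.min())), int(np.ceil(col.max())) + 1)
    grid = np.asarray(grid, dtype=float)
    Xn = fit.X.to_numpy(dtype=float)
    j = fit.feature_names.index(variable)
    values = np.empty(len(grid))
    work = Xn.copy()
    for i, g in enumerate(grid):
        work[:, j] = g
        values[i] = float(fit.model.predict(work).mean())
    return PDPCurve(variable=variable, grid=grid, values=values)


def _smooth(values: np.ndarray, width: int = 3) -> np.ndarray:
    """Centred moving average; ends use the shorter one-sided windows."""
    if len(values) < width:
        return values.copy()
    half = width // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def detect_changepoint(
    curve: PDPCurve,
    floor: float = 0.0,
    override: int | None = None,
) -> float | None:
    """Grid day with the largest absolute jump of the smoothed curve.

    Returns the left grid value of the steepest first difference; ties go to
    the smaller day.  If the largest jump does not exceed ``floor`` the
    curve is considered flat and None is returned.  ``override`` bypasses
    detection (it must lie on the grid).
    """
    if override is not None:
        if not curve.grid.min() <= override <= curve.grid.max():
            raise ValueError(f"override {override} outside grid range")
        return float(override)
    if len(curve.grid) < 3:
        raise ValueError("need at least 3 grid points")
    smoothed = np.asarray(_smooth(curve.values, width=3))
    jumps = np.abs(np.diff(smoothed))
    peak = float(jumps.max())
    if peak <= floor:
        return None
    # first (smallest-day) maximum, treating round-off-level differences as ties
    best = int(np.flatnonzero(jumps >= peak - 1e-9 * max(1.0, abs(peak)))[0])
    # A clean step between grid days d and d+1 smears over the three first
    # differences ending at d+2; the first of those starts at d-1, so the
    # right endpoint of the first maximal difference recovers d — the last
    # day before the change.
    return float(curve.grid[best + 1])


def plot_pdp(curve: PDPCurve, path: str, changepoint: float | None = None) -> None:
    """Save a simple partial-dependence figure (optional diagnostics output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.grid, curve.values, lw=1.5)
    if changepoint is not None:
        ax.axvline(changepoint, color="firebrick", ls="--", lw=1)
    ax.set_xlabel(f"{curve.variable} (days)")
    ax.set_ylabel("predicted abundance (oysters per dredge)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
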