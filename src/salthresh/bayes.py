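"""Hierarchical Bayesian multilevel model of oyster abundance, fit by Gibbs sampling.

The response A_ijk (mean dredge abundance at station j in basin i in year k)
is modelled as normal around a linear predictor built from low-salinity
exposure covariates and nested random intercepts::

    A_ijk        ~ Normal(mu_ijk, sigma^2)
    mu_ijk       = beta_ij0 + lambda_k0 + sum_m gamma_m * S_m
    beta_ij0     ~ Normal(alpha_i0, sigma_station^2)     (station nested in basin)
    alpha_i0     ~ Normal(0, sigma_basin^2)
    lambda_k0    ~ Normal(0, sigma_year^2)
    gamma_m      ~ Normal(0, 1e6)                        (flat)
    variances    ~ InverseGamma(0.001, 0.001)            (flat)

All priors are conjugate, so every full conditional is a normal (location
parameters) or an inverse gamma (variances) and the model is sampled by a
bespoke Gibbs sampler.  Five level structures are supported — station nested
in basin + year, station nested in basin, basin + year, basin only, year
only — by dropping the corresponding intercept blocks (a grand intercept
replaces them when neither station nor basin level is present).

Model comparison uses DIC (Spiegelhalter: D_bar + p_D with
p_D = D_bar - D(posterior means); models within 2 DIC of the best are
co-best) and the Gelfand-Ghosh squared-error posterior-predictive loss
(goodness-of-fit sum of squared residuals against posterior-predictive means
plus the sum of posterior-predictive variances), which is the criterion used
across differing hierarchy levels.  Covariate effects are classified by
equal-tailed credible intervals: negative-95 / negative-50 / positive-95 /
positive-50 / indeterminate.

Default prior hyperparameters (Normal(0, 1e6); InverseGamma(0.001, 0.001))
and MCMC settings (3 chains x 20,000 iterations, 5,000 burn-in, thinning 5,
Gelman-Rubin limit 1.1) are deliberately weak/conventional and configurable.
Covariates enter on their natural day scale so coefficients are directly
interpretable as abundance change per day of exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVEL_STRUCTURES = ("station+year", "station", "basin+year", "basin", "year")


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: level structure, covariate columns, optional response filter."""

    levels: str
    covariates: tuple[str, ...]
    quadratic: bool = False
    season: str | None = None
    stage: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.levels not in LEVEL_STRUCTURES:
            raise ValueError(
                f"levels must be one of {LEVEL_STRUCTURES}, got {self.levels!r}"
            )
        if self.quadratic and len(self.covariates) != 1:
            raise ValueError("quadratic variant requires exactly one covariate")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def has_station(self) -> bool:
        return self.levels.startswith("station")

    @property
    def has_basin(self) -> bool:
        return self.has_station or self.levels.startswith("basin")

    @property
    def has_year(self) -> bool:
        return self.levels.endswith("year")


@dataclass(frozen=True)
class PriorSpec:
    """Conjugate prior hyperparameters.

    ``location_mean``/``location_var`` parametrise the normal priors on the
    slopes and the grand intercept and the hyper-mean of the basin
    intercepts; the four variance components share one inverse-gamma prior.
    """

    location_mean: float = 0.0
    location_var: float = 1.0e6
    ig_shape: float = 0.001
    ig_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.location_var <= 0 or self.ig_shape <= 0 or self.ig_rate <= 0:
            raise ValueError("prior variance, shape and rate must be positive")


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    rhat_limit: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations <= self.burn_in or self.thin < 1:
            raise ValueError("invalid MCMC settings")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """MCMC samples keyed by parameter name.

    ``params[name]`` has shape (chains * draws_per_chain,); ``per_chain[name]``
    keeps the (chains, draws_per_chain) layout for convergence diagnostics.
    """

    params: dict[str, np.ndarray]
    per_chain: dict[str, np.ndarray]
    settings: McmcSettings

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[0]


@dataclass
class FitResult:
    spec: ModelSpec
    draws: PosteriorDraws
    dic: float
    ppl: float
    rhat: dict[str, float]
    converged: bool
    # design data, kept so DIC/PPL can be recomputed from saved draws
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    covariate_names: tuple[str, ...] = ()
    station_ids: tuple[str, ...] = ()
    basin_ids: tuple[str, ...] = ()
    year_ids: tuple[int, ...] = ()
    s_idx: np.ndarray = field(default=None, repr=False)
    b_idx: np.ndarray = field(default=None, repr=False)
    k_idx: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------


def _assemble_design(
    abundance: pd.DataFrame, exposure: pd.DataFrame, spec: ModelSpec
) -> dict:
    ab = abundance.copy()
    for colname, val in (("season", spec.season), ("stage", spec.stage)):
        if val is not None:
            if colname not in ab.columns:
                raise ValueError(f"abundance table has no {colname!r} column to filter on")
            ab = ab[ab[colname] == val]
    if spec.region is not None:
        from .collate import region_split

        ab = ab[ab["basin_id"].map(region_split) == spec.region]
    if ab.empty:
        raise ValueError("no abundance rows after applying the response selector")

    if "bin" in exposure.columns:  # tidy layout -> wide
        from .exposure import exposure_wide

        exposure = exposure_wide(exposure)
    missing = [c for c in spec.covariates if c not in exposure.columns]
    if missing:
        raise KeyError(f"exposure table is missing covariate column(s): {missing}")

    keep = ["station_id", "year", *spec.covariates]
    merged = ab.merge(exposure[keep], on=["station_id", "year"], how="left")
    if merged[list(spec.covariates)].isna().any().any():
        bad = merged[merged[list(spec.covariates)].isna().any(axis=1)]
        pairs = sorted(set(zip(bad["station_id"], bad["year"])))
        raise ValueError(f"no exposure covariates for station-years: {pairs[:5]}")

    X = merged[list(spec.covariates)].to_numpy(dtype=float)
    names = list(spec.covariates)
    if spec.quadratic:
        X = np.column_stack([X, X[:, 0] ** 2])
        names.append(f"{spec.covariates[0]}^2")

    stations = sorted(merged["station_id"].astype(str).unique())
    basins = sorted(merged["basin_id"].astype(str).unique())
    years = sorted(int(y) for y in merged["year"].unique())
    s_idx = merged["station_id"].astype(str).map({s: i for i, s in enumerate(stations)}).to_numpy()
    b_idx = merged["basin_id"].astype(str).map({b: i for i, b in enumerate(basins)}).to_numpy()
    k_idx = merged["year"].astype(int).map({y: i for i, y in enumerate(years)}).to_numpy()

    basin_of_station = np.empty(len(stations), dtype=int)
    for s, b in zip(s_idx, b_idx):
        basin_of_station[s] = b

    if spec.has_station and len(stations) < 2:
        raise ValueError(
            "station-level variance requested but the design has a single station"
        )

    return {
        "y": merged["abundance"].to_numpy(dtype=float),
        "X": X,
        "names": tuple(names),
        "stations": tuple(stations),
        "basins": tuple(basins),
        "years": tuple(years),
        "s_idx": s_idx,
        "b_idx": b_idx,
        "k_idx": k_idx,
        "basin_of_station": basin_of_station,
    }


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


class GibbsSampler:
    """Gibbs sampler for the nested normal model.

    Exposes each full-conditional's distribution parameters
    (``cond_*`` methods) so they can be verified independently against
    brute-force grid evaluation of the unnormalised conditional density.
    """

    def __init__(self, design: dict, spec: ModelSpec, priors: PriorSpec):
        self.spec = spec
        self.priors = priors
        self.y = design["y"]
        self.X = design["X"]
        self.names = design["names"]
        self.s_idx = design["s_idx"]
        self.b_idx = design["b_idx"]
        self.k_idx = design["k_idx"]
        self.basin_of_station = design["basin_of_station"]
        self.n = len(self.y)
        self.S = len(design["stations"])
        self.B = len(design["basins"])
        self.K = len(design["years"])
        self.M = self.X.shape[1]
        self._n_s = np.bincount(self.s_idx, minlength=self.S).astype(float)
        self._n_b = np.bincount(self.b_idx, minlength=self.B).astype(float)
        self._n_k = np.bincount(self.k_idx, minlength=self.K).astype(float)
        self._J_b = np.bincount(self.basin_of_station, minlength=self.B).astype(float)

    # -- state ------------------------------------------------------------

    def initial_state(self, rng: np.random.Generator) -> dict:
        y = self.y
        v = float(np.var(y)) or 1.0
        state = {
            "beta": np.zeros(self.S),
            "alpha": np.zeros(self.B),
            "lam": np.zeros(self.K),
            "mu0": float(np.mean(y)),
            "gamma": np.zeros(self.M),
            "sigma2": v,
            "sigma2_station": v,
            "sigma2_basin": v,
            "sigma2_year": v,
        }
        if self.spec.has_basin:
            for b in range(self.B):
                state["alpha"][b] = float(np.mean(y[self.b_idx == b]))
        if self.spec.has_station:
            for s in range(self.S):
                state["beta"][s] = float(np.mean(y[self.s_idx == s]))
        # jitter so chains start apart
        state["beta"] = state["beta"] + rng.normal(0, np.sqrt(v) / 2, self.S)
        state["alpha"] = state["alpha"] + rng.normal(0, np.sqrt(v) / 2, self.B)
        state["mu0"] += float(rng.normal(0, np.sqrt(v) / 2))
        return state

    def linear_predictor(self, state: dict) -> np.ndarray:
        mu = self.X @ state["gamma"]
        if self.spec.has_station:
            mu = mu + state["beta"][self.s_idx]
        elif self.spec.has_basin:
            mu = mu + state["alpha"][self.b_idx]
        else:
            mu = mu + state["mu0"]
        if self.spec.has_year:
            mu = mu + state["lam"][self.k_idx]
        return mu

    # -- full conditionals -------------------------------------------------
    # Each cond_* returns the parameters of the conjugate conditional given
    # the current values of every other parameter in `state`.

    def cond_beta(self, state: dict) -> tuple[np.ndarray, np.ndarray]:
        r = self.y - (self.linear_predictor(state) - state["beta"][self.s_idx])
        prec = self._n_s / state["sigma2"] + 1.0 / state["sigma2_station"]
        num = (
            np.bincount(self.s_idx, weights=r, minlength=self.S) / state["sigma2"]
            + state["alpha"][self.basin_of_station] / state["sigma2_station"]
        )
        return num / prec, 1.0 / prec

    def cond_alpha(self, state: dict) -> tuple[np.ndarray, np.ndarray]:
        m0 = self.priors.location_mean
        if self.spec.has_station:
            prec = self._J_b / state["sigma2_station"] + 1.0 / state["sigma2_basin"]
            num = (
                np.bincount(self.basin_of_station, weights=state["beta"], minlength=self.B)
                / state["sigma2_station"]
                + m0 / state["sigma2_basin"]
            )
        else:
            r = self.y - (self.linear_predictor(state) - state["alpha"][self.b_idx])
            prec = self._n_b / state["sigma2"] + 1.0 / state["sigma2_basin"]
            num = (
                np.bincount(self.b_idx, weights=r, minlength=self.B) / state["sigma2"]
                + m0 / state["sigma2_basin"]
            )
        return num / prec, 1.0 / prec

    def cond_lam(self, state: dict) -> tuple[np.ndarray, np.ndarray]:
        r = self.y - (self.linear_predictor(state) - state["lam"][self.k_idx])
        prec = self._n_k / state["sigma2"] + 1.0 / state["sigma2_year"]
        num = np.bincount(self.k_idx, weights=r, minlength=self.K) / state["sigma2"]
        return num / prec, 1.0 / prec

    def cond_mu0(self, state: dict) -> tuple[float, float]:
        r = self.y - (self.linear_predictor(state) - state["mu0"])
        prec = self.n / state["sigma2"] + 1.0 / self.priors.location_var
        num = r.sum() / state["sigma2"] + self.priors.location_mean / self.priors.location_var
        return num / prec, 1.0 / prec

    def cond_gamma(self, state: dict) -> tuple[np.ndarray, np.ndarray]:
        r = self.y - (self.linear_predictor(state) - self.X @ state["gamma"])
        A = self.X.T @ self.X / state["sigma2"] + np.eye(self.M) / self.priors.location_var
        b = self.X.T @ r / state["sigma2"] + self.priors.location_mean / self.priors.location_var
        cov = np.linalg.inv(A)
        return cov @ b, cov

    def cond_sigma2(self, state: dict) -> tuple[float, float]:
        resid = self.y - self.linear_predictor(state)
        return (
            self.priors.ig_shape + 0.5 * self.n,
            self.priors.ig_rate + 0.5 * float(resid @ resid),
        )

    def cond_sigma2_station(self, state: dict) -> tuple[float, float]:
        dev = state["beta"] - state["alpha"][self.basin_of_station]
        return (
            self.priors.ig_shape + 0.5 * self.S,
            self.priors.ig_rate + 0.5 * float(dev @ dev),
        )

    def cond_sigma2_basin(self, state: dict) -> tuple[float, float]:
        dev = state["alpha"] - self.priors.location_mean
        return (
            self.priors.ig_shape + 0.5 * self.B,
            self.priors.ig_rate + 0.5 * float(dev @ dev),
        )

    def cond_sigma2_year(self, state: dict) -> tuple[float, float]:
        return (
            self.priors.ig_shape + 0.5 * self.K,
            self.priors.ig_rate + 0.5 * float(state["lam"] @ state["lam"]),
        )

    # -- sampling ----------------------------------------------------------

    @staticmethod
    def _draw_inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
        return float(rate / rng.gamma(shape))

    def step(self, rng: np.random.Generator, state: dict) -> dict:
        """One full Gibbs scan, updating ``state`` in place."""
        spec = self.spec
        if spec.has_station:
            m, v = self.cond_beta(state)
            state["beta"] = rng.normal(m, np.sqrt(v))
            m, v = self.cond_alpha(state)
            state["alpha"] = rng.normal(m, np.sqrt(v))
            sh, ra = self.cond_sigma2_station(state)
            state["sigma2_station"] = self._draw_inv_gamma(rng, sh, ra)
            sh, ra = self.cond_sigma2_basin(state)
            state["sigma2_basin"] = self._draw_inv_gamma(rng, sh, ra)
        elif spec.has_basin:
            m, v = self.cond_alpha(state)
            state["alpha"] = rng.normal(m, np.sqrt(v))
            sh, ra = self.cond_sigma2_basin(state)
            state["sigma2_basin"] = self._draw_inv_gamma(rng, sh, ra)
        else:
            m, v = self.cond_mu0(state)
            state["mu0"] = float(rng.normal(m, np.sqrt(v)))
        if spec.has_year:
            m, v = self.cond_lam(state)
            state["lam"] = rng.normal(m, np.sqrt(v))
            sh, ra = self.cond_sigma2_year(state)
            state["sigma2_year"] = self._draw_inv_gamma(rng, sh, ra)
        if self.M:
            m, cov = self.cond_gamma(state)
            state["gamma"] = rng.multivariate_normal(m, cov, method="cholesky")
        sh, ra = self.cond_sigma2(state)
        state["sigma2"] = self._draw_inv_gamma(rng, sh, ra)
        return state

    def tracked_params(self, design: dict) -> list[str]:
        names = []
        if self.spec.has_station:
            names += [f"beta[{s}]" for s in design["stations"]]
        if self.spec.has_basin:
            names += [f"alpha[{b}]" for b in design["basins"]]
        if not self.spec.has_basin:
            names += ["mu0"]
        if self.spec.has_year:
            names += [f"lam[{k}]" for k in design["years"]]
        names += [f"gamma[{c}]" for c in self.names]
        names += ["sigma2"]
        if self.spec.has_station:
            names += ["sigma2_station", "sigma2_basin"]
        elif self.spec.has_basin:
            names += ["sigma2_basin"]
        if self.spec.has_year:
            names += ["sigma2_year"]
        return names

    def flatten_state(self, state: dict, design: dict) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.spec.has_station:
            for i, s in enumerate(design["stations"]):
                out[f"beta[{s}]"] = state["beta"][i]
        if self.spec.has_basin:
            for i, b in enumerate(design["basins"]):
                out[f"alpha[{b}]"] = state["alpha"][i]
        else:
            out["mu0"] = state["mu0"]
        if self.spec.has_year:
            for i, k in enumerate(design["years"]):
                out[f"lam[{k}]"] = state["lam"][i]
        for i, c in enumerate(self.names):
            out[f"gamma[{c}]"] = state["gamma"][i]
        out["sigma2"] = state["sigma2"]
        if self.spec.has_station:
            out["sigma2_station"] = state["sigma2_station"]
            out["sigma2_basin"] = state["sigma2_basin"]
        elif self.spec.has_basin:
            out["sigma2_basin"] = state["sigma2_basin"]
        if self.spec.has_year:
            out["sigma2_year"] = state["sigma2_year"]
        return out


def _potential_scale_reduction(arr: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for an array shaped (chains, draws)."""
    import arviz as az

    c, d = arr.shape
    if c * 2 > d:  # too few draws to split meaningfully
        return float("nan")
    return float(az.rhat(arr))


def gibbs_fit(
    abundance: pd.DataFrame,
    exposure: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> FitResult:
    """Fit the multilevel model by Gibbs sampling and score it by DIC and PPL.

    ``abundance`` needs columns station_id, basin_id, year, abundance (plus
    season/stage if the spec filters on them); ``exposure`` is the wide (or
    tidy) exposure table.  Multi-chain, reproducible given ``mcmc.seed``;
    non-convergence (any split-R-hat above ``mcmc.rhat_limit``) sets
    ``converged=False`` and logs a warning rather than failing.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcSettings()
    design = _assemble_design(abundance, exposure, spec)
    sampler = GibbsSampler(design, spec, priors)

    tracked = sampler.tracked_params(design)
    per_chain = {name: np.empty((mcmc.chains, mcmc.draws_per_chain)) for name in tracked}
    for chain in range(mcmc.chains):
        rng = np.random.default_rng([mcmc.seed, chain])
        state = sampler.initial_state(rng)
        kept = 0
        for it in range(mcmc.iterations):
            sampler.step(rng, state)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                if kept < mcmc.draws_per_chain:
                    flat = sampler.flatten_state(state, design)
                    for name in tracked:
                        per_chain[name][chain, kept] = flat[name]
                    kept += 1

    params = {name: arr.reshape(-1) for name, arr in per_chain.items()}
    draws = PosteriorDraws(params=params, per_chain=per_chain, settings=mcmc)

    rhat: dict[str, float] = {}
    if mcmc.chains >= 2:
        rhat = {name: _potential_scale_reduction(arr) for name, arr in per_chain.items()}
    worst = max((v for v in rhat.values() if np.isfinite(v)), default=1.0)
    converged = bool(worst <= mcmc.rhat_limit)
    if not converged:
        logger.warning(
            "chains may not have converged: max split-R-hat %.3f > %.2f", worst, mcmc.rhat_limit
        )

    fit = FitResult(
        spec=spec,
        draws=draws,
        dic=float("nan"),
        ppl=float("nan"),
        rhat=rhat,
        converged=converged,
        y=design["y"],
        X=design["X"],
        covariate_names=design["names"],
        station_ids=design["stations"],
        basin_ids=design["basins"],
        year_ids=design["years"],
        s_idx=design["s_idx"],
        b_idx=design["b_idx"],
        k_idx=design["k_idx"],
    )
    fit.dic = dic(fit)
    fit.ppl = ppl(fit)
    return fit


def fit_quadratic_variant(
    abundance: pd.DataFrame,
    exposure: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> FitResult:
    """Refit a single-covariate spec with an added squared term."""
    if len(spec.covariates) != 1:
        raise ValueError("quadratic variant requires a single-covariate spec")
    return gibbs_fit(abundance, exposure, replace(spec, quadratic=True), priors, mcmc)


# ---------------------------------------------------------------------------
# Draw-based summaries
# ---------------------------------------------------------------------------


def _mu_draws(fit: FitResult) -> np.ndarray:
    """Per-draw linear predictor matrix, shape (n_draws, n_obs)."""
    d = fit.draws
    spec = fit.spec
    n_draws = d.n_draws
    mu = np.zeros((n_draws, len(fit.y)))
    for i, c in enumerate(fit.covariate_names):
        mu += np.outer(d[f"gamma[{c}]"], fit.X[:, i])
    if spec.has_station:
        beta = np.column_stack([d[f"beta[{s}]"] for s in fit.station_ids])
        mu += beta[:, fit.s_idx]
    elif spec.has_basin:
        alpha = np.column_stack([d[f"alpha[{b}]"] for b in fit.basin_ids])
        mu += alpha[:, fit.b_idx]
    else:
        mu += d["mu0"][:, None]
    if spec.has_year:
        lam = np.column_stack([d[f"lam[{k}]"] for k in fit.year_ids])
        mu += lam[:, fit.k_idx]
    return mu


def _deviance(y: np.ndarray, mu: np.ndarray, sigma2: np.ndarray | float) -> np.ndarray:
    """-2 log normal likelihood; vectorised over draws when mu is 2-D."""
    sigma2 = np.asarray(sigma2, dtype=float)
    sq = ((y - mu) ** 2).sum(axis=-1)
    n = y.shape[-1] if y.ndim else len(y)
    return n * np.log(2 * np.pi * sigma2) + sq / sigma2


def dic(fit: FitResult) -> float:
    """Deviance information criterion, D_bar + p_D (Spiegelhalter form)."""
    if fit.draws.n_draws == 0:
        raise ValueError("no posterior draws")
    mu = _mu_draws(fit)
    sigma2 = fit.draws["sigma2"]
    d_bar = float(_deviance(fit.y, mu, sigma2).mean())
    d_hat = float(_deviance(fit.y, mu.mean(axis=0), float(sigma2.mean())))
    p_d = d_bar - d_hat
    return d_bar + p_d


def ppl(fit: FitResult) -> float:
    """Gelfand-Ghosh posterior-predictive loss: sum (y - E[y_rep])^2 + sum Var[y_rep]."""
    if fit.draws.n_draws == 0:
        raise ValueError("no posterior draws")
    mu = _mu_draws(fit)
    pred_mean = mu.mean(axis=0)
    # law of total variance over draws: Var(mu) + E[sigma^2]
    pred_var = mu.var(axis=0) + float(fit.draws["sigma2"].mean())
    g = float(((fit.y - pred_mean) ** 2).sum())
    p = float(pred_var.sum())
    return g + p


@dataclass(frozen=True)
class ModelRanking:
    order: tuple[int, ...]  # indices into the input list, best first
    criterion: str
    values: tuple[float, ...]  # criterion value per input fit
    co_best: tuple[int, ...]  # indices within 2 DIC (or PPL) of the best


def compare_models(fits: Sequence[FitResult], criterion: str = "dic") -> ModelRanking:
    """Rank fits by DIC (or PPL); all models within 2 of the best are co-best.

    All fits must share the same response data.  PPL is the criterion to use
    when the fits differ in hierarchy levels.
    """
    if len(fits) == 0:
        raise ValueError("no fits to compare")
    if criterion not in ("dic", "ppl"):
        raise ValueError("criterion must be 'dic' or 'ppl'")
    ref = np.sort(fits[0].y)
    for f in fits[1:]:
        if len(f.y) != len(ref) or not np.allclose(np.sort(f.y), ref):
            raise ValueError("fits were made on different response data")
    values = tuple(getattr(f, criterion) for f in fits)
    order = tuple(int(i) for i in np.argsort(values, kind="stable"))
    best = values[order[0]]
    co_best = tuple(i for i in order if values[i] <= best + 2.0)
    return ModelRanking(order=order, criterion=criterion, values=values, co_best=co_best)


def classify_effect(fit: FitResult, coefficient: str) -> str:
    """Sign classification of a coefficient from equal-tailed credible intervals.

    Returns 'negative-95' (95% CI entirely below 0), 'negative-50' (50% CI
    below 0 but 95% CI overlapping), symmetric positive labels, or
    'indeterminate'.
    """
    key = coefficient if coefficient in fit.draws.params else f"gamma[{coefficient}]"
    if key not in fit.draws.params:
        raise KeyError(f"coefficient {coefficient!r} not among posterior draws")
    g = fit.draws[key]
    q025, q25, q75, q975 = np.quantile(g, [0.025, 0.25, 0.75, 0.975])
    if q975 < 0:
        return "negative-95"
    if q025 > 0:
        return "positive-95"
    if q75 < 0:
        return "negative-50"
    if q25 > 0:
        return "positive-50"
    return "indeterminate"


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """One column per parameter, one row per retained iteration."""
    return pd.DataFrame(draws.params)


def summarize_fit(fit: FitResult, covariate: str | None = None) -> dict:
    """Table-style summary row: levels, covariate, median sign, CI class, scores."""
    cov = covariate or (fit.covariate_names[0] if fit.covariate_names else None)
    row = {
        "levels": fit.spec.levels,
        "covariate": cov,
        "dic": fit.dic,
        "ppl": fit.ppl,
        "converged": fit.converged,
    }
    if cov is not None:
        g = fit.draws[f"gamma[{cov}]"]
        row["median"] = float(np.median(g))
        row["classification"] = classify_effect(fit, cov)
    return row
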