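import numpy as np
import pandas as pd
import pytest

from salthresh.bayes import (
    FitResult,
    McmcSettings,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
)


def make_series(values, start="2018-05-01", station="s1", basin="barataria"):
    """A SalinitySeries from a plain list (NaN allowed), daily from `start`."""
    from salthresh.exposure import SalinitySeries

    idx = pd.date_range(start, periods=len(values), freq="D")
    return SalinitySeries(station, basin, pd.Series(np.asarray(values, dtype=float), index=idx))


def point_mass_fit(intercept: float, gamma: float, basin: str = "b1", n: int = 200) -> FitResult:
    """A FitResult whose posterior is a point mass — handy analytic oracle."""
    spec = ModelSpec(levels="basin", covariates=("x",))
    settings = McmcSettings(chains=1, iterations=n + 1, burn_in=1, thin=1)
    draws = PosteriorDraws(
        params={
            f"alpha[{basin}]": np.full(n, float(intercept)),
            "gamma[x]": np.full(n, float(gamma)),
            "sigma2": np.ones(n),
            "sigma2_basin": np.ones(n),
        },
        per_chain={},
        settings=settings,
    )
    return FitResult(
        spec=spec,
        draws=draws,
        dic=0.0,
        ppl=0.0,
        rhat={},
        converged=True,
        y=np.zeros(3),
        X=np.zeros((3, 1)),
        covariate_names=("x",),
        basin_ids=(basin,),
    )


def ks_pvalue_against_grid(draws, grid, log_density):
    """KS p-value of draws against a density known only up to a constant,
    evaluated by brute force on a grid (trapezoid-normalised CDF)."""
    from scipy import stats
    from scipy.interpolate import interp1d

    lp = np.array([log_density(g) for g in grid], dtype=float)
    lp -= lp.max()
    dens = np.exp(lp)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    F = interp1d(grid, cdf, bounds_error=False, fill_value=(0.0, 1.0))
    return stats.kstest(draws, F).pvalue


@pytest.fixture(scope="session")
def toy_design():
    """A 3-observation design with 2 stations in 1 basin and 2 years."""
    abundance = pd.DataFrame(
        {
            "station_id": ["s1", "s1", "s2"],
            "basin_id": ["b1", "b1", "b1"],
            "year": [2016, 2017, 2016],
            "abundance": [10.0, 12.0, 8.0],
        }
    )
    exposure = pd.DataFrame(
        {
            "station_id": ["s1", "s1", "s2"],
            "basin_id": ["b1", "b1", "b1"],
            "year": [2016, 2017, 2016],
            "x": [3.0, 5.0, 1.0],
        }
    )
    return abundance, exposure


@pytest.fixture(scope="session")
def small_mcmc():
    return McmcSettings(chains=2, iterations=1500, burn_in=500, thin=2, seed=11)


@pytest.fixture(scope="session")
def flat_priors():
    return PriorSpec()
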