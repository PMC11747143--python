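"""Gibbs sampler correctness, DIC/PPL behaviour, effect classification."""

import numpy as np
import pandas as pd
import pytest

from salthresh.bayes import (
    FitResult,
    GibbsSampler,
    McmcSettings,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    _assemble_design,
    classify_effect,
    compare_models,
    dic,
    fit_quadratic_variant,
    gibbs_fit,
    ppl,
)
from salthresh.synthetic import make_recovery_dataset

from conftest import ks_pvalue_against_grid, point_mass_fit


# -- full-conditional correctness against grid oracles -----------------------


@pytest.fixture(scope="module")
def toy_sampler(toy_design):
    abundance, exposure = toy_design
    spec = ModelSpec(levels="station+year", covariates=("x",))
    design = _assemble_design(abundance, exposure, spec)
    smp = GibbsSampler(design, spec, PriorSpec())
    state = {
        "beta": np.array([10.5, 8.2]),
        "alpha": np.array([9.5]),
        "lam": np.array([0.3, -0.2]),
        "mu0": 0.0,
        "gamma": np.array([0.4]),
        "sigma2": 2.0,
        "sigma2_station": 1.5,
        "sigma2_basin": 4.0,
        "sigma2_year": 1.0,
    }
    return smp, state


def _mu(smp, state, **over):
    beta = over.get("beta", state["beta"])
    lam = over.get("lam", state["lam"])
    gamma = over.get("gamma", state["gamma"])
    return beta[smp.s_idx] + lam[smp.k_idx] + smp.X @ gamma


def test_gamma_conditional_matches_grid(toy_sampler):
    smp, state = toy_sampler
    rng = np.random.default_rng(1)
    m, cov = smp.cond_gamma(state)
    draws = rng.normal(m[0], np.sqrt(cov[0, 0]), 5000)

    def logp(g):
        resid = smp.y - _mu(smp, state, gamma=np.array([g]))
        return -0.5 * resid @ resid / state["sigma2"] - 0.5 * g**2 / 1e6

    p = ks_pvalue_against_grid(draws, np.linspace(-3, 4, 4001), logp)
    assert p > 0.01


def test_station_intercept_conditional_matches_grid(toy_sampler):
    smp, state = toy_sampler
    rng = np.random.default_rng(2)
    m, v = smp.cond_beta(state)
    draws = rng.normal(m[0], np.sqrt(v[0]), 5000)

    def logp(b0):
        beta = state["beta"].copy()
        beta[0] = b0
        resid = (smp.y - _mu(smp, state, beta=beta))[smp.s_idx == 0]
        prior = -0.5 * (b0 - state["alpha"][0]) ** 2 / state["sigma2_station"]
        return -0.5 * resid @ resid / state["sigma2"] + prior

    p = ks_pvalue_against_grid(draws, np.linspace(0, 20, 4001), logp)
    assert p > 0.01


def test_variance_conditional_matches_grid(toy_sampler):
    smp, state = toy_sampler
    rng = np.random.default_rng(3)
    sh, ra = smp.cond_sigma2(state)
    draws = ra / rng.gamma(sh, 1.0, 5000)
    resid = smp.y - _mu(smp, state)
    ssr = float(resid @ resid)

    def logp(s2):
        lik = -0.5 * smp.n * np.log(s2) - 0.5 * ssr / s2
        prior = (-0.001 - 1) * np.log(s2) - 0.001 / s2
        return lik + prior

    p = ks_pvalue_against_grid(draws, np.linspace(1e-3, 80, 8001), logp)
    assert p > 0.01


# -- degenerate and recovery behaviour ---------------------------------------


def test_intercept_only_recovers_constant_data():
    """With flat priors and constant data c, the grand intercept posterior -> c."""
    c = 17.0
    abundance = pd.DataFrame(
        {
            "station_id": ["s1", "s2"] * 5,
            "basin_id": ["b1"] * 10,
            "year": np.repeat([2016, 2017, 2018, 2019, 2020], 2),
            "abundance": c,
        }
    )
    exposure = abundance[["station_id", "basin_id", "year"]].drop_duplicates().copy()
    spec = ModelSpec(levels="basin", covariates=())
    mcmc = McmcSettings(chains=2, iterations=1200, burn_in=400, thin=2, seed=5)
    fit = gibbs_fit(abundance, exposure, spec, mcmc=mcmc)
    post = fit.draws["alpha[b1]"]
    assert abs(post.mean() - c) < 3 * post.std() / np.sqrt(20) + 0.05


def test_slope_recovery_on_synthetic_truth(small_mcmc):
    """95% interval for the exposure slope covers the generating value."""
    bundle = make_recovery_dataset(seed=2)
    spec = ModelSpec(levels="station+year", covariates=("c.d_su0.1",))
    fit = gibbs_fit(bundle.abundance, bundle.exposure, spec, mcmc=small_mcmc)
    g = fit.draws["gamma[c.d_su0.1]"]
    lo, hi = np.quantile(g, [0.025, 0.975])
    assert lo <= -0.6 <= hi
    assert fit.converged


def test_chains_agree_across_seeds():
    bundle = make_recovery_dataset(seed=9)
    spec = ModelSpec(levels="station+year", covariates=("c.d_su0.1",))
    means = []
    for seed in (21, 22):
        mcmc = McmcSettings(chains=1, iterations=1600, burn_in=600, thin=2, seed=seed)
        fit = gibbs_fit(bundle.abundance, bundle.exposure, spec, mcmc=mcmc)
        g = fit.draws["gamma[c.d_su0.1]"]
        means.append((g.mean(), g.std() / np.sqrt(len(g) / 10)))  # crude ESS deflation
    (m1, se1), (m2, se2) = means
    assert abs(m1 - m2) < 4 * np.hypot(se1, se2)


def test_draw_count_contract(toy_design, small_mcmc):
    abundance, exposure = toy_design
    spec = ModelSpec(levels="year", covariates=("x",))
    fit = gibbs_fit(abundance, exposure, spec, mcmc=small_mcmc)
    expected = small_mcmc.chains * small_mcmc.draws_per_chain
    assert fit.draws.n_draws == expected
    assert (fit.draws["sigma2"] > 0).all()


# -- errors ------------------------------------------------------------------


def test_single_station_with_station_level_errors():
    abundance = pd.DataFrame(
        {"station_id": ["s1"] * 3, "basin_id": ["b1"] * 3,
         "year": [2016, 2017, 2018], "abundance": [1.0, 2.0, 3.0]}
    )
    exposure = abundance[["station_id", "basin_id", "year"]].assign(x=[0.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="single station"):
        gibbs_fit(abundance, exposure, ModelSpec(levels="station", covariates=("x",)))


def test_missing_covariate_column_errors(toy_design):
    abundance, exposure = toy_design
    with pytest.raises(KeyError, match="nope"):
        gibbs_fit(abundance, exposure, ModelSpec(levels="basin", covariates=("nope",)))


# -- DIC / PPL ---------------------------------------------------------------


def constant_draw_fit(y, mu_value, sigma2_value):
    """A fit whose draws are a single repeated point (basin intercept only)."""
    n = 50
    spec = ModelSpec(levels="basin", covariates=())
    settings = McmcSettings(chains=1, iterations=n + 1, burn_in=1, thin=1)
    draws = PosteriorDraws(
        params={"alpha[b1]": np.full(n, mu_value), "sigma2": np.full(n, sigma2_value),
                "sigma2_basin": np.ones(n)},
        per_chain={},
        settings=settings,
    )
    return FitResult(
        spec=spec, draws=draws, dic=0.0, ppl=0.0, rhat={}, converged=True,
        y=np.asarray(y, dtype=float), X=np.zeros((len(y), 0)), covariate_names=(),
        basin_ids=("b1",), b_idx=np.zeros(len(y), dtype=int),
    )


def test_dic_point_mass_has_zero_complexity():
    """Draws collapsed to one point: p_D = 0 so DIC equals the plug-in deviance."""
    y = np.array([1.0, 2.0, 3.0])
    fit = constant_draw_fit(y, mu_value=2.0, sigma2_value=1.5)
    expected_deviance = float(
        len(y) * np.log(2 * np.pi * 1.5) + np.sum((y - 2.0) ** 2) / 1.5
    )
    assert dic(fit) == pytest.approx(expected_deviance, abs=1e-9)


def test_dic_and_ppl_deterministic_given_draws(toy_design, small_mcmc):
    abundance, exposure = toy_design
    spec = ModelSpec(levels="station+year", covariates=("x",))
    fit = gibbs_fit(abundance, exposure, spec, mcmc=small_mcmc)
    assert dic(fit) == fit.dic == dic(fit)
    assert ppl(fit) == fit.ppl == ppl(fit)


def test_irrelevant_covariate_changes_dic_by_about_two():
    """On null data an extra useless covariate costs ~1 DIC unit (within ~2)."""
    bundle = make_recovery_dataset(seed=31, gamma=0.0)
    mcmc = McmcSettings(chains=2, iterations=1500, burn_in=500, thin=2, seed=13)
    base = gibbs_fit(bundle.abundance, bundle.exposure,
                     ModelSpec(levels="basin", covariates=()), mcmc=mcmc)
    extra = gibbs_fit(bundle.abundance, bundle.exposure,
                      ModelSpec(levels="basin", covariates=("c.d_su0.1",)), mcmc=mcmc)
    assert abs(extra.dic - base.dic) < 4.0  # similar models per the delta-2 rule


def test_ppl_drops_when_true_covariate_included():
    bundle = make_recovery_dataset(seed=17)  # strong negative slope
    mcmc = McmcSettings(chains=2, iterations=1500, burn_in=500, thin=2, seed=13)
    without = gibbs_fit(bundle.abundance, bundle.exposure,
                        ModelSpec(levels="basin", covariates=()), mcmc=mcmc)
    with_cov = gibbs_fit(bundle.abundance, bundle.exposure,
                         ModelSpec(levels="basin", covariates=("c.d_su0.1",)), mcmc=mcmc)
    assert with_cov.ppl < without.ppl
    assert with_cov.dic < without.dic


def ranking_stub(y, dic_value):
    fit = constant_draw_fit(y, mu_value=0.0, sigma2_value=1.0)
    fit.dic = dic_value
    return fit


def test_co_best_set_within_two_dic():
    y = [0.0, 1.0]
    fits = [ranking_stub(y, 100.0), ranking_stub(y, 101.5), ranking_stub(y, 110.0)]
    r = compare_models(fits)
    assert r.order[0] == 0
    assert set(r.co_best) == {0, 1}


def test_compare_single_fit_is_itself():
    r = compare_models([ranking_stub([0.0, 1.0], 50.0)])
    assert r.order == (0,) and r.co_best == (0,)


def test_ranking_invariant_to_input_order():
    y = [0.0, 1.0]
    fits = [ranking_stub(y, 110.0), ranking_stub(y, 100.0), ranking_stub(y, 101.5)]
    r = compare_models(fits)
    assert [r.values[i] for i in r.order] == [100.0, 101.5, 110.0]


def test_compare_different_responses_errors():
    with pytest.raises(ValueError, match="different response"):
        compare_models([ranking_stub([0.0, 1.0], 1.0), ranking_stub([5.0, 6.0], 2.0)])


# -- classification ----------------------------------------------------------


def classified(draws):
    fit = point_mass_fit(0.0, 0.0)
    fit.draws.params["gamma[x]"] = np.asarray(draws, dtype=float)
    return classify_effect(fit, "x")


def test_all_negative_draws_classify_negative95():
    assert classified(-np.abs(np.random.default_rng(0).normal(5, 1, 1000))) == "negative-95"


def test_symmetric_draws_are_indeterminate():
    rng = np.random.default_rng(1)
    assert classified(rng.normal(0, 1, 4001)) == "indeterminate"


def test_negative50_construction():
    """2.5% quantile below zero, 97.5% above, but both quartiles negative."""
    draws = np.concatenate([np.full(60, -1.0), np.full(30, -0.1), np.full(10, 0.5)])
    assert classified(draws) == "negative-50"


def test_unknown_coefficient_errors():
    with pytest.raises(KeyError):
        classify_effect(point_mass_fit(0.0, 0.0), "missing")


# -- quadratic variant -------------------------------------------------------


@pytest.fixture(scope="module")
def quadratic_data():
    rng = np.random.default_rng(23)
    n_st, years = 6, (2016, 2017, 2018, 2019, 2020)
    rows, exp_rows = [], []
    for i in range(n_st):
        for y in years:
            x = float(rng.uniform(0, 60))
            mu = 20.0 + 0.8 * x - 0.012 * x**2
            rows.append({"station_id": f"s{i}", "basin_id": "b1", "year": y,
                         "abundance": mu + rng.normal(0, 2.0)})
            exp_rows.append({"station_id": f"s{i}", "basin_id": "b1", "year": y, "x": x})
    return pd.DataFrame(rows), pd.DataFrame(exp_rows)


def test_quadratic_model_wins_on_quadratic_truth(quadratic_data):
    abundance, exposure = quadratic_data
    spec = ModelSpec(levels="basin", covariates=("x",))
    mcmc = McmcSettings(chains=2, iterations=2000, burn_in=800, thin=2, seed=3)
    lin = gibbs_fit(abundance, exposure, spec, mcmc=mcmc)
    quad = fit_quadratic_variant(abundance, exposure, spec, mcmc=mcmc)
    assert quad.dic < lin.dic - 2.0
    g1 = quad.draws["gamma[x]"]
    g2 = quad.draws["gamma[x^2]"]
    assert np.quantile(g1, 0.025) <= 0.8 <= np.quantile(g1, 0.975)
    assert np.quantile(g2, 0.025) <= -0.012 <= np.quantile(g2, 0.975)


def test_quadratic_requires_single_covariate(toy_design):
    abundance, exposure = toy_design
    with pytest.raises(ValueError):
        fit_quadratic_variant(abundance, exposure, ModelSpec(levels="basin", covariates=()))
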