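# Methods

This note documents the models, numerical choices and known limitations of
`salthresh`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Exposure covariates

Daily mean salinity per station is discretised into five bins — 0–1, >1–3,
>3–5, >5–7, >7–9 psu — and summarised per window as total days and maximum
consecutive days in each bin. Two windows are supported: summer (May 1 –
Aug 31, a fixed 123 days in every year) and the calendar year (365/366 by
the leap rule; the random-forest interpretation rule uses the constant 365).

Choices the bin notation leaves open, fixed here and configurable:

* **Edge convention.** Bins are lower-open/upper-closed except 0–1, which is
  closed on both ends; a day at exactly 5.0 psu counts in 3–5. "Below level
  x" is strictly `value < x`, so a day at exactly 1.0 is not "below 1".
  Daily means are continuous, so edge days are rare in practice; the
  convention only matters for synthetic data held exactly at an edge.
* **Missing days** are never counted and break a consecutive run — the
  conservative choice for run statistics, since a gap could hide a
  higher-salinity day. Per-station missingness is logged at warning level.

Both statistics are verified exactly against a day-by-day brute-force scan
on random series (property tests plus a 1,000-series audit in the
acceptance script).

## Multilevel Bayesian model

Abundance A_ijk (mean oysters per dredge at station j in basin i in year k)
is modelled as normal around a linear function of exposure covariates with
nested random intercepts:

    A_ijk     ~ N(mu_ijk, sigma^2)
    mu_ijk    = beta_ij0 + lambda_k0 + sum_m gamma_m S_m
    beta_ij0  ~ N(alpha_i0, sigma_station^2)
    alpha_i0  ~ N(0, sigma_basin^2)
    lambda_k0 ~ N(0, sigma_year^2)

Five level structures are supported (station-in-basin + year,
station-in-basin, basin + year, basin, year); dropping the station and
basin levels introduces a grand intercept with the same flat prior, since
the year effects are centred at zero. Year effects are pooled around a
common variance `sigma_year^2` rather than given per-year priors.

**Priors.** All location parameters get Normal(0, 1e6); all four variance
components get InverseGamma(0.001, 0.001). These are conventional
weakly-informative defaults — with tens of observations the likelihood
dominates — and every hyperparameter is configurable through `PriorSpec`.

**Sampler.** All full conditionals are conjugate (normal for locations,
joint multivariate normal for the slope block, inverse gamma for
variances), so the model is sampled by a bespoke Gibbs sampler. Defaults:
3 chains × 20,000 iterations, 5,000 burn-in, thinning 5; chains are
initialised at group means jittered by half a residual SD; convergence is
monitored by split-R̂ (via arviz) with limit 1.1 — exceeding it sets a
`converged=False` flag and logs a warning rather than failing, because a
non-converged comparison model is still informative to record. Every
conditional's distributional parameters are exposed (`cond_*` methods) so
tests can verify them against brute-force grid evaluation of the
unnormalised conditional density (Kolmogorov–Smirnov on 5,000 draws).

**Covariate scale.** Covariates enter on their natural day scale (no
standardisation), so a slope is directly "oysters per dredge per day of
exposure" and the day-threshold arithmetic needs no back-transformation.
With collinear covariate pairs (total vs consecutive days can coincide)
the flat slope prior keeps the joint update proper; the affected slopes are
then individually poorly identified, which the R̂ flag surfaces.

**Model comparison.** DIC = D̄ + p_D with p_D = D̄ − D(posterior means)
(the Spiegelhalter form); models within 2 DIC are co-best. Across differing
hierarchy levels the Gelfand–Ghosh squared-error posterior predictive loss
is used instead: G + P where G is the squared distance of observations from
posterior-predictive means and P the summed predictive variances (law of
total variance over draws). Both are deterministic functions of saved
draws. The full selection protocol — level comparison on the full
covariate set, then single-covariate finals, then quadratic variants for
positive relations — is orchestrated in the pipeline; single-covariate
finals are a `ModelSpec` mode, not a separate code path.

**Effect classification.** Equal-tailed credible intervals of the slope:
`negative-95` if the 95% CI is entirely below zero, `negative-50` if only
the 50% CI is, symmetrically for positive, else `indeterminate`.

## Threshold derivation

**Bayesian sweep.** For a negatively classified single-covariate final
model, predicted abundance is evaluated on the integer grid d = 0..123:
per-draw basin intercept plus the posterior year effects averaged over
years plus slope × d. The threshold is the smallest d whose posterior
median falls below the critical abundance (half the 5-year basin mean over
station-year rows); "more than 50% probability below critical" is
operationalised as the posterior median of the predicted mean lying below
it, equivalent under a continuous posterior. If the median never crosses
within the window the result is recorded with `days=None`. Sweeps refuse
(raise) on non-negative classifications — a day threshold is undefined when
more exposure does not predict lower abundance.

**RF interpretation rule.** A partial-dependence changepoint of d days in a
safe bin (abundance rising with days in it) converts to (window − d) days
below the bin's lower bound, with window constants 123 (summer) and 365
(calendar). When the dependence declines within a low bin itself the
changepoint is the threshold directly and the level is the bin's upper
bound. The pipeline picks the mode from the sign of the smoothed curve's
net change.

## Random-forest branch

scikit-learn's `RandomForestRegressor` backs the forest itself; defaults
mirror conventional regression-forest settings (500 trees, p/3 candidate
features per split, minimum node size 5). Retention uses out-of-bag r² =
1 − OOB-MSE/Var(y) with threshold 0.75; OOB was chosen over in-sample r²
because the in-sample value of a forest is nearly always high and would
make the screen vacuous. Importance is the impurity-decrease (node-purity)
measure; scikit-learn normalises it, which leaves the ranking — all the
selection rule consumes — unchanged. "Tightly grouped" top-three
importances are quantified as the 2nd and 3rd lying within 20% of the
leader (configurable); ties of the grouped rule resolve to the lowest
salinity bin, parsed from the covariate name.

Partial dependence is computed by brute-force averaging (each grid day
substituted into every training row) on the integer grid spanning the
observed range. The changepoint is the grid day with the largest absolute
first difference of the curve smoothed by a centred width-3 moving
average; round-off-level differences are treated as ties and ties resolve
to the smaller day, so a clean step between days d and d+1 is reported as
d. A configurable floor declares curves flat (no changepoint), and a
manual-override channel lets changepoints read off published plots feed the
interpretation rule directly — the source analysis read its changepoints by
eye, and the explicit detector is this package's replacement for that
visual step.

## Synthetic data

The generator emulates the monitoring design — stations nested in basins,
2016–2020, daily salinity and seasonal abundance — not Louisiana
hydrology. Daily salinity is basin baseline + seasonal sinusoid (minimum on
day-of-year 152, when high river flow depresses salinity) + stationary
AR(1) noise, clamped at 0. The AR(1) autocorrelation is this package's
choice of a minimal realistic daily process; no empirical autocorrelation
was available to copy. Injected low-salinity events overwrite the process
with the target level plus N(0, 0.05) noise, giving runs of exactly known
length; overlapping events on a station are rejected.

Abundance is drawn from the same multilevel model the Bayesian branch fits
(one value per station-season-year, the model's finest unit). Negative
draws are retained — the likelihood is an unbounded normal — but when
abundance is re-expressed as dredge records (two replicate monthly samples
per season at A±1, averaged back by collation), counts are clipped at zero
as physical counts must be.

Canned scenarios (`make_fixture`): `null` (slopes zero), `negative-slope-east`
(slope −0.6 on consecutive days < 1 psu; event durations capped at 60 days
and basin intercepts 28–32 keep basin means positive), and `rf-step`
(abundance drops by 25 once consecutive days in the 1–3 bin exceed 40, with
event durations deliberately straddling 38/42 so tree splits bracket the
changepoint). In `rf-step` one event per station-year makes the total- and
consecutive-day columns coincide, concentrating the signal in that column
pair; the planted covariate is therefore identified by its bin. The
recovery dataset (3 basins × 6 stations × 5 years, slope −0.6, residual SD
5) uses basin intercepts of 45–51 so that five-year basin means — and hence
critical abundances — stay positive at the planted slope.

What passing tests on these data do **not** show: robustness to
non-normal/zero-inflated counts (real dredge data are overdispersed with
many zeros), to spatially correlated salinity errors, to missing-data
patterns beyond isolated gaps, or to confounding between exposure and
unmeasured stressors. The generator's covariate variation is injected by
design; real exposure gradients are narrower and collinear across bins.

## Problem sizes and reproducibility

Tests and the acceptance script run reduced problem sizes chosen to make
Monte-Carlo checks stable on one CPU: 2 chains × 3,000 iterations for
recovery fits (slope R̂ ≈ 1.0 at this length), 20 replicates for coverage
and false-positive rates, 1,000 series for the exposure audit, 5,000 draws
for conditional KS checks. A single pipeline seed fans out to per-stage
seeds via CRC32 of the stage name, so every stage is independently
reproducible and no global RNG state exists anywhere.

## Known limitations

* The normal likelihood admits negative predicted abundance; near-zero
  basins can yield early threshold crossings that a count model would not.
* DIC/PPL are implemented for the normal likelihood only.
* With a single basin the basin-variance posterior is driven by one
  deviation and is essentially the prior; interpret accordingly.
* The changepoint detector reports one changepoint; curves with several
  comparable jumps report only the steepest (smallest-day on ties).
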