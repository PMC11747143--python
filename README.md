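# salthresh

Low-salinity exposure thresholds for eastern oyster (*Crassostrea
virginica*) populations, estimated from daily station salinity and dredge
monitoring data with two complementary statistical definitions of a
threshold.

Estuarine oysters tolerate wide salinity ranges, but extended summer
freshwater exposure depresses recruitment and survival. Given per-station
daily salinity series and per-dredge abundance counts, this package asks:
*below which salinity, and after how many days of exposure, does oyster
abundance collapse?* It is written for quantitative ecologists and fishery
analysts working with fishery-independent monitoring data, and ships a
synthetic-data generator that reproduces the assumed data structure
(stations nested in basins, five years, seasonal salinity with injectable
low-salinity events) so the full pipeline is testable without any download.

## The two threshold definitions

Exposure covariates are, per station, year and window (summer = May 1-Aug
31 = 123 days, or the calendar year), the **total days** and the **maximum
consecutive days** of daily mean salinity inside each bin 0-1, >1-3, >3-5,
>5-7, >7-9 psu (columns `s_d_su0.1` ... `c.d_su7.9`).

**Hierarchical Bayesian branch.** Abundance A_ijk (station j, basin i,
year k) follows a multilevel normal model

    A_ijk    ~ N(mu_ijk, sigma^2)
    mu_ijk   = beta_ij0 + lambda_k0 + sum_m gamma_m S_m
    beta_ij0 ~ N(alpha_i0, sigma_j^2),  alpha_i0 ~ N(0, sigma_i^2),
    lambda_k0 ~ N(0, sigma_k^2)

with conjugate (flat normal / inverse-gamma) priors, sampled by a bespoke
multi-chain Gibbs sampler. Level structures are compared by posterior
predictive loss, single-covariate final models by DIC (within 2 = co-best),
and effects classified by 95%/50% credible intervals. For negatively
classified models the fitted curve is swept over d = 0..123 days; the
threshold is the first day the posterior median of predicted abundance
drops below the **critical abundance** (50% of the 5-year basin mean).

**Random-forest branch.** A regression forest (500 trees, p/3 variables per
split) is screened by out-of-bag r² > 0.75, the interpretation variable is
chosen from the node-purity importance ranking (lowest salinity bin among
the top three when they are tightly grouped), and the changepoint is the
largest jump of its partial-dependence curve. A changepoint of d days in a
"safe" bin converts to a threshold of (123 − d) days below the bin's lower
bound; a decline within a low bin itself is the threshold directly.

## Worked example

Run the pipeline end-to-end on the bundled synthetic scenario with a
planted slope of −0.6 oysters/dredge per consecutive day of salinity < 1:

```python
import dataclasses
import pandas as pd
from salthresh import PipelineConfig, run_pipeline
from salthresh.bayes import McmcSettings

cfg = PipelineConfig(
    scenario="negative-slope-east",
    mcmc=McmcSettings(chains=2, iterations=4000, burn_in=1000, thin=3),
    seed=0,
)
res = run_pipeline(cfg, "out")
thr = pd.DataFrame([dataclasses.asdict(t) for t in res["thresholds"]])
print(thr[["method", "basin", "salinity", "exposure_kind", "days"]].to_string(index=False))
```

```
method         basin salinity exposure_kind  days
 bayes     barataria      < 1         total    52
 bayes pontchartrain      < 1         total    41
 bayes    terrebonne      < 1         total    45
 bayes     barataria      < 1    continuous    52
 bayes pontchartrain      < 1    continuous    41
 bayes    terrebonne      < 1    continuous    45
    rf          None      < 1         total    42
```

Reading: the Bayesian branch predicts that, e.g., Pontchartrain abundance
has a > 50% probability of falling below half its 5-year mean after 41
consecutive summer days of salinity below 1 psu (the total-days rows are
the same signal — with one injected event per station-year the two
statistics coincide); the random-forest partial dependence on days below 1
drops sharply at 42 days, in line with the planted decline. The RF model
passed retention with out-of-bag r² = 0.78.

The same run is available from the shell:

```bash
salthresh run --seed 0 --out out && salthresh report --out out
```

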