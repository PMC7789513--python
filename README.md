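# bymtrend

Bayesian spatio-temporal disease mapping for areal birth/death panels:
a binomial-logit model with BYM (Besag–York–Mollié) spatial effects,
an overall time trend, area-specific differential trends, and
exceedance-probability risk classification. Built for small-area
child-mortality analysis — epidemiologists or health-geography analysts
with a complete municipality × year table of live births and child
deaths and a contiguity map — but applicable to any areal count panel
with the same structure.

## The model

For deaths `y_it` out of births `n_it` in area `i`, year `t`:

    y_it ~ Binomial(n_it, mu_it)
    logit(mu_it) = alpha + (s_i + u_i) + d0*t* + v_t + d1_i*t* + eps_it

`s_i` (ICAR prior on the contiguity graph) and `u_i` (exchangeable
Gaussian) form the BYM convolution; `d0*t* + v_t` is the common
linear-plus-wiggle trend in the centred time index `t*`; `d1_i*t*` (ICAR
across areas) lets each area's trend depart from the common one;
`eps_it` absorbs overdispersion. Half-Gaussian N+(0, 10) priors on all
five standard deviations (a Gamma-on-precision alternative is
available). The model is fit by Metropolis-within-Gibbs MCMC with plain
Gelman–Rubin convergence checks (threshold 1.04).

Areas are then classified by posterior exceedance probabilities:
`Pr(exp(u_i + s_i) > 1 | data) > 0.8` → high risk, `< 0.2` → low risk,
otherwise medium; the same 0.8/0.2 rule on `Pr(d1_i > 0 | data)` labels
each area's trend increasing / decreasing / stable relative to the
common trend.

See `docs/methods.md` for assumptions, sampler design and limitations.

## Worked example

Simulate a calibrated 75-municipality, 7-year panel with known truth,
run the preliminary autocorrelation diagnostics, fit, and classify:

```python
import numpy as np
from bymtrend import (PriorConfig, SamplerConfig, classification_report,
                      classify_areas, mean_lag1_acf, moran_table,
                      run_chains, summarize, yearly_summary)
from bymtrend.simulate import default_scenario, simulate_panel

ds = simulate_panel(default_scenario(seed=1))
print("per-year mean rate:", np.round(yearly_summary(ds.panel).rate_mean, 1))
print("Moran's I per year:", np.round(
    moran_table(ds.panel, ds.adj, seed=1)["I"].to_numpy(), 2))
print("mean lag-1 ACF: %.2f" % mean_lag1_acf(ds.panel))

samples = run_chains(
    ds.panel, ds.adj, ds.time_index, PriorConfig(),
    SamplerConfig(n_iterations=5000, n_burnin=1000, n_chains=2, seed=1))
post = summarize(samples)
print(post.loc[["alpha", "d0"]].round(3))

counts = classification_report(classify_areas(samples))
print(counts[counts["trend_category"] == "all"][
    ["risk_category", "count", "percent"]].to_string(index=False))
```

Output:

```
per-year mean rate: [19.2 17.5 16.9 15.9 16.  15.4 15.7]
Moran's I per year: [0.24 0.2  0.02 0.01 0.11 0.22 0.33]
mean lag-1 ACF: 0.35
        mean     sd   q2.5    q50  q97.5   rhat
alpha -4.131  0.024 -4.178 -4.131 -4.083  1.005
d0    -0.035  0.005 -0.045 -0.035 -0.021  1.096
risk_category  count  percent
         high     35       47
       medium      6        8
          low     34       45
```

The generating values here are `alpha = logit(0.016) ≈ -4.135` and
`d0 = -0.03`: both 95% credible intervals cover the truth, and the mean
rate declines over the window as the negative `d0` dictates. The
per-year Moran's I of this particular panel realisation is positive
every year (the scenario's long-run mean is ≈ 0.32, with wide
seed-to-seed spread), and with registry-scale birth counts most areas'
spatial effects are resolved decisively, so few land in the medium
class. At this reduced run length `d0`'s R-hat (1.096) still sits above
the 1.04 threshold — the `fit` command would flag it and longer default
chains resolve it.

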