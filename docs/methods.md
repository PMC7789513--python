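# Methods

## The model

`bymtrend` fits a Bayesian spatio-temporal binomial model for areal panels
of child deaths `y_it` out of live births `n_it` over N areas and T
consecutive years:

    y_it ~ Binomial(n_it, mu_it)
    logit(mu_it) = alpha + (s_i + u_i) + d0*t* + v_t + d1_i*t* + eps_it

* `alpha` — overall logit risk across the window.
* `s_i` — spatially structured effect with an intrinsic CAR (ICAR) prior
  on the binary contiguity graph W: conditionally Gaussian around the mean
  of its neighbours with variance `sigma_s^2 / m_i` (`m_i` = neighbour
  count). Together with the exchangeable Gaussian `u_i ~ N(0, sigma_u^2)`
  this is the Besag–York–Mollié (BYM) convolution.
* `d0*t* + v_t` — overall time trend: a linear part in the centred time
  index `t*` plus an i.i.d. Gaussian wiggle `v_t ~ N(0, sigma_v^2)` that
  allows non-linearity.
* `d1_i*t*` — the differential trend: each area's linear departure from
  the common trend, with an ICAR prior across areas so neighbouring areas
  have similar trend departures.
* `eps_it ~ N(0, sigma_eps^2)` — cell-level effect absorbing
  extra-binomial (overdispersed) variation.

`t*` is centred at the mid-observation year (integer offsets −3..3 for a
7-year window); for an even or gappy year set it is centred at the mean.

### Identification

The ICAR prior is improper (the graph Laplacian `Q = diag(m) − W` has rank
N−1 on a connected map) and any constant can be exchanged between `alpha`
and the fields. We impose sum-to-zero constraints on `s`, `d1` and `v`;
`u` and `eps` remain unconstrained and are identified through their
proper priors. Disconnected maps and islands are rejected at ingest
rather than silently patched, since the intended study regions are
connected and islands usually indicate data errors.

### Priors

Flat (improper) priors on `alpha` and `d0`. Each of the five standard
deviations gets a half-Gaussian prior N+(0, 10) by default — weakly
informative at the logit scale of disease-mapping applications. A
Gamma(0.001, 0.001)-on-precision alternative is available per component
(`PriorConfig.gamma_on_precisions()`), reproducing the classic
WinBUGS-era setup and enabling exact conjugate variance draws. The ICAR
log-density carries the rank-aware normalisation `−((N−1)/2)·log sigma^2`,
which the variance updates require; the constrained `v` uses T−1
degrees of freedom in its variance update for the same reason.

## Sampling

Metropolis-within-Gibbs, all blocks random-walk Metropolis on the joint
log-posterior:

* `alpha`, `d0`: scalar random walks.
* `s`, `d1`: single-site updates vectorised over the colour classes of a
  greedy colouring of the contiguity graph (sites in one class share no
  edge, so their full conditionals are mutually independent and may be
  updated simultaneously).
* `u`, `eps`: all sites at once (conditionally independent).
* `v`: one block proposal *within* the sum-to-zero subspace. The iid
  Gaussian prior of `v` is not shift-invariant, so the
  recentre-after-update trick that is exact for the ICAR fields would
  distort it; a projected symmetric proposal with a single accept/reject
  targets the constrained prior exactly.
* variances: random walk on `log sigma` under the half-Gaussian prior;
  exact conjugate Gamma draws of the precision under the Gamma prior.
  Proposals outside `sigma in (1e-6, 1e3)` are rejected outright as a
  numerical guard.
* Two kinds of likelihood-invariant or near-invariant extra moves improve
  mixing along known ridges:
  1. a joint shift `(alpha + delta, u − delta)` — the intercept and the
     mean of the unconstrained heterogeneity field are confounded in the
     likelihood, and single-site updates traverse that ridge extremely
     slowly;
  2. a group rescale `(field, sigma) -> (e^z field, e^z sigma)` per
     variance component — the prior quadratic form and the `sigma^-rank`
     normalisation cancel against the transform Jacobian, so the accept
     ratio reduces to the likelihood change plus the hyperprior ratio
     plus `z`. This is what lets the chains cross the variance-field
     "funnel"; without it the variance components mix poorly and
     credible intervals for `d0` come out too narrow.

After every sweep `s`, `v`, `d1` are re-centred, with the removed means
absorbed into `alpha` and `d0` (the likelihood is untouched; for the
shift-invariant ICAR priors this is an exact reparameterisation).

Proposal scales adapt multiplicatively toward a 35% acceptance rate in
windows of 50 iterations during the first `adapt_until` iterations only
(default: the burn-in), so retained draws come from a fixed kernel.
Chains start overdispersed: `alpha` at the empirical pooled logit plus a
chain-indexed offset, fields at zero, SDs alternating between 0.1 and 1.

Defaults mirror common practice for this model class: 2 chains of
100,000 iterations with 30,000 burn-in and the plain (non-split)
Gelman–Rubin factor with a 1.04 convergence threshold. The reduced
settings used in the validation suite (5,000 iterations, 1,000 burn-in)
were chosen as the smallest runs at which the recovery checks are stable.

## Classification

Risk: `p_i = Pr(exp(u_i + s_i) > 1 | data)` is the pooled-draw fraction
with `u_i + s_i > 0`; `p_i > 0.8` → high (code 1), `p_i < 0.2` → low
(code 2), otherwise medium (code 3). Trend: the same rule on
`Pr(d1_i > 0 | data)` gives increasing / decreasing / stable relative to
the common trend. Boundary values (exactly 0.8 or 0.2) fall in the middle
class because the extreme classes are defined by strict inequalities.
No additional credible-interval filter is applied on top of the
threshold rule.

## Synthetic data

`simulate_panel` draws every component from the model's own generative
reading: ICAR fields via the Laplacian eigenbasis, Gaussian `u`, `v`
(recentred), `eps`, log-uniform births per cell (default 1,000–60,000,
mimicking heterogeneous municipality sizes), binomial deaths. The default
scenario (`default_scenario()`) is a 75-area (5×15 rook lattice), 7-year
panel calibrated once to the magnitudes of a metropolitan
child-mortality registry: baseline risk `logit(0.016)`, overall slope
−0.03 per year, `sigma_s^2 = 0.025`, `sigma_u^2 = 0.035`,
`sigma_v^2 = 0.0009`, `sigma_d^2 = 0.035`, `sigma_eps^2 = 0.001`. Under
these settings per-year mean rates fall near 16–19 per 1000 with
across-area SDs near 7, mean per-year Moran's I ≈ 0.32, and clear
overdispersion relative to a binomial-only control.

What the generator does **not** emulate: the only serial dependence it
can produce is linear area trends plus white noise, and a pure linear
trend over 7 points has lag-1 autocorrelation 16/28 ≈ 0.57 — an upper
bound that sampling noise further dilutes (the default scenario sits near
0.31). Real registry series with smooth non-linear persistence can exceed
this. Likewise the lattice geometry is more regular than a real
municipality map, and births are independent across cells (no population
drift). Passing tests therefore demonstrate correctness of the machinery
and calibration to first- and second-moment magnitudes, not a
reproduction of any particular registry's values.

## Numerical choices

* Likelihood evaluated as `y*eta − n*log(1 + e^eta)` (stable for large
  |eta|); binomial coefficients included in the public `log_likelihood`
  but dropped inside the sampler where they cancel.
* ICAR draws by eigendecomposition of `Q`, independent Gaussian mass
  `sigma^2/lambda_k` on each non-null eigenvector, re-centred against
  floating-point drift.
* Sample (N−1) standard deviation in descriptive summaries; unweighted
  across-area means (no births weighting).
* Moran's I permutation test is one-sided (positive autocorrelation) with
  the `(1 + count)/(n_perm + 1)` correction; the lag-1 ACF uses the
  plug-in estimator with the series mean, skipping constant series with a
  warning.
* Draws persist to CSV with shortest-round-trip float formatting and are
  reloaded with `float_precision="round_trip"`, so reclassification from
  persisted draws is bit-exact.

## Known limitations

* Single-site Metropolis mixes slowly for very strong spatial fields;
  the sampler is tuned for the moderate-variance regime of mortality
  mapping.
* The BYM convolution's split between `s` and `u` is weakly identified
  (only their sum enters the likelihood); their individual variances
  carry wide posteriors, which is inherent to the model, not a sampler
  defect. The classification depends only on `s + u` and is unaffected.
* No covariates, no row-standardised or distance-based weights, no
  CAR-proper/Leroux alternatives, no record-level data handling.
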