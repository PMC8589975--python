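# snowphen

Breeding-phenology inference for alpine birds from citizen-science
records — built around the white-winged snowfinch (*Montifringilla
nivalis*), a high-alpine specialist whose broods hatch during snowmelt.

Citizen-science portals yield opportunistic sightings of breeding
behaviour ("atlas codes": nest building, incubation, adults with food for
young, …) rather than dated nests. `snowphen` turns such records into
interval-censored hatching dates, deduplicates repeated observations of
the same brood, derives snowmelt and spring-climate predictors per 1×1 km
grid cell, and fits hierarchical Bayesian regression models that propagate
the dating and location uncertainty into the estimates. A synthetic-data
module emulates the whole observation process with stored ground truth, so
every stage is testable without any data download.

Intended users: quantitative ecologists analysing opportunistic breeding
records, and methods developers who need a reference implementation of
interval-censored phenology regression with measurement error.

## The model

A record with atlas code *c* on day *d* implies a hatching interval
[*d* − max offset(*c*), *d* − min offset(*c*)] from known stage durations
(nest building 8 d, incubation 14 d, nestling 20 d, fledgling dependence
14 d by default). Per cell and year, a maximum set of mutually exclusive
intervals gives the minimum number of distinct broods (earliest-endpoint
greedy, provably optimal); one representative record is drawn uniformly
per slot.

For brood *i* with interval midpoint *h*ᵒᵇˢᵢ and width *w*ᵢ:

    hᵒᵇˢᵢ ~ Normal(hᵢ, wᵢ/4)                       observation layer
    hᵢ    ~ Normal(μᵢ, σ)                          process layer
    μᵢ    = α_region(i) + Σₖ βₖ zₖᵢ + γ_year(i)
    γ_y   ~ Normal(0, σ_year)

so the true hatching date falls inside its interval with ≈95%
probability. Standardized covariates zₖ are elevation (linear +
quadratic), mean observer day (person-weighted mean activity day per
cell-year, Apr 1–Aug 31 — the observer-bias correction), year, an
elevation × year interaction, and, in the environmental model, winter
intensity (PC1 of winter temperature and snow depth), spring
precipitation, snowmelt onset and spring temperature. Covariates measured
with location or sub-grid uncertainty (elevation, temperature,
precipitation) are latent: zₖᵢ ~ Normal(zᵒᵇˢₖᵢ, sdₖᵢ), with latent
elevation propagating through both the linear and quadratic terms.

Priors: α ~ Normal(mean hatching date, 50 d); β ~ Normal(0, 5); σ ~
half-Cauchy(20); σ_year ~ half-Cauchy(5). Sampling is a blocked Gibbs
scheme (conjugate normal blocks, a joint coefficient/year-effect block, a
slice sampler for σ_year on its collapsed conditional, and
Metropolis-within-Gibbs for latent elevation); convergence is gated on
split-R̂ < 1.01, proportionally scaled effective sample size, and Monte
Carlo SE < 5% of the posterior SD.

Around the core model: snowmelt metrics (meltstart = first day after
maximal snow cover, meltend = first day at the post-onset minimum),
sliding-window selection of climate predictors (windows of 7 lengths
between 1 and 90 days ending by May 15; a window qualifies when its 20
best end-days are consecutive), REML mixed-model trend surfaces with
joint-posterior simulation under flat priors, bivariate-KDE observer-bias
diagnostics, and residual semivariograms.

## Worked example

`examples/05_hierarchical_model.py` simulates the default 20-year
scenario (~120 cells, ~700 true broods, ~620 observed after
deduplication), runs the full preparation chain and fits the
environmental model:

```
fitting environmental model on 616 broods, 20 years, 4 chains x 2000 iterations ...
     parameter  std_mean   std_sd     q2.5    q97.5    unstd                 unit
    region[EA]    173.72     0.90   171.93   175.47   173.72          day-of-year
    ...
 precipitation      1.04     0.44     0.24     1.91     1.82           per 100 mm
   temperature     -1.22     0.54    -2.28    -0.16    -0.57            per deg C
         sigma      9.67     0.34     9.04    10.35     9.67                 days
    sigma_year      1.28     0.72     0.08     2.78     1.28                 days

convergence: pass=True (max split-R-hat 1.004, min ESS 1092, gate 200)
generating coefficients inside their 95% CI: 8/8

precipitation effect 1.04 d per SD -> one-day hatching delay per 55 mm of
additional spring precipitation
```

Standardized coefficients are days of hatching-date shift per SD of the
predictor; the `unstd` column converts them to natural reporting units
(per 100 m, per decade, per 100 mm of window-total precipitation, …) by
dividing by the raw SD. All eight data-generating coefficients sit inside
their 95% compatibility intervals, and the posterior predictive check
shows no misfit. The other examples walk through record preparation,
snowmelt metrics, window selection, trend surfaces and the diagnostics.

A thin CLI mirrors the pipeline stages
(`snowphen simulate | prepare | demo`), e.g.

```bash
snowphen demo --seed 1 --out demo_run
```

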