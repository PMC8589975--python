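# Methods

This note documents the statistical procedures, the synthetic study
system, the numerical choices and the known limitations of `snowphen`.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. From records to broods

**Calendar.** All dates are 1-based day-of-year on a 365-day grid; Feb 29
observations map to Feb 28, so days are comparable across years.

**Hatching intervals.** Each atlas code carries bounds on
(observation day − hatch day), assembled from stage durations (defaults:
nest building 8 d, incubation 14 d, nestling 20 d, fledgling dependence
14 d; shipped as an editable YAML because local atlas-code catalogues
differ). The hatching interval of a record is
[obs − max offset, obs − min offset]; its midpoint is the working date and
its width the dating uncertainty. Laying and nest-building events shift
the interval back by the incubation (and nest-building) duration; the
nestling event is the nest-occupancy window. Intervals extending outside
the year are clamped with a warning.

**Deduplication.** Within a cell-year, overlap is defined on *closed*
intervals — hatching days are integer-valued, and a shared endpoint is
compatible with a single brood. A maximum pairwise-disjoint subset is
found by the earliest-endpoint greedy algorithm (optimal for interval
scheduling; ties broken by earlier start, then record id, so the slots are
deterministic). Every input interval is pooled with the selected slot it
overlaps most (ties to the earlier slot — the assignment rule is not
dictated by the method, so we fixed the simplest deterministic one), and
one representative per slot is drawn uniformly with an explicit seeded
generator. Records where one observer reported several distinguishable
broods on the same day are additionally retained. Cell-years with
systematic monitoring keep only the monitoring records.

**Covariates.** Mean observer day is the person-weighted mean activity
day per cell-year between Apr 1 and Aug 31 (a plain-mean option exists;
the person-weighted reading follows from effort being counted in
persons per day). Elevation uncertainty follows the location-precision
class: known nests get a precise elevation with SD 0.5 m; 200-m records
get the 200-m DEM value with the SD of the 3×3 sub-cell neighbourhood
(clipped at the cell edge); coarser records get the mean and SD of all
200-m sub-cells in the 1-km cell. Sample SDs (ddof = 1) throughout.

## 2. Environmental predictors

**Snowmelt.** Meltstart is the first day after maximal snow cover; ties
at the maximum resolve to the last tied day, so meltstart is the first
day from which cover can only decrease. Meltend is the first day
attaining the post-meltstart minimum. A constant series (or a maximum on
the final day) has no defined melt and yields a missing value. The melt
window is closed on both ends for event classification. Both metrics are
translation-equivariant and recover the synthetic generator's stored
truth exactly on all series the suite generates.

**Climate windows.** For each candidate length L ∈ {1, 7, 14, 30, 45,
61, 90} days (seven lengths between 1 and 90; 61 is included because a
two-month spring window has that length), a window slides by end-day up
to May 15 (day 135). The window aggregate is the mean; the score is the
Pearson correlation with brood mean hatching dates pooled over years. A
length qualifies when its 20 highest-|r| end-days are consecutive; among
qualifying lengths the maximal |r| wins. With fewer than 20 valid
end-days a length is disqualified with a warning; when nothing qualifies
the scan returns no window plus full diagnostics. Selection is invariant
to affine rescaling of the climate variable (a Pearson property, tested).

**Winter intensity.** PC1 of the standardized winter-temperature and
snow-depth station series. The sign is fixed so colder-and-snowier
winters score higher; scores are mean-centred. For two standardized
variables the eigen-structure is closed-form (loadings (±1, ±1)/√2 when
|r| = 1), which the tests exploit.

**Attachment.** Per brood: window means of temperature and precipitation
plus the mean of the daily sub-grid SDs over the window (the spatial
pattern of sub-grid variation is persistent, so the average daily SD is
the natural uncertainty for the window mean); the cell-year meltstart;
the year's winter score (a yearly scalar, measurement SD 0). Broods with
incomplete climate coverage are flagged and excluded from the
environmental model, with counts logged.

## 3. Trend models

Hatching, meltstart and meltend dates are regressed on elevation
(centred at 2450 m — the species' density optimum — and scaled by its
SD), its square, scaled year and the elevation × year interaction, with a
year random intercept, fitted by REML (statsmodels `MixedLM`; singular
fits fall back to OLS with a warning). Uncertainty propagation simulates
the joint posterior under flat coefficient priors and p(σ) ∝ 1/σ: σ² is
drawn from df·σ̂²/χ²(df) and the coefficients from the conditional normal
scaled accordingly, with the among-year variance held at its REML
estimate. This "sim"-style shortcut is orders of magnitude faster than
MCMC and adequate for prediction bands; predictions are invariant to the
centering constants (tested).

## 4. Hierarchical measurement-error models

Two models share a backbone (see README for the likelihood): the
spatiotemporal model (region, elevation, elevation², observer day, year,
elevation × year, year random effect) and the environmental model adding
winter intensity, precipitation, meltstart and temperature. Responses are
interval midpoints with observation SD = width/4, so the true date lies
inside its interval with ≈95% probability; widths of 0 (monitoring
records) pin the latent date exactly. The quadratic elevation term is the
square of the standardized linear term, and latent elevation propagates
through both terms and the interaction. Region uses cell-means coding
(four intercepts). Priors: intercepts Normal(overall mean hatching date,
50 d) — of which 77.3% of the mass falls between May 1 and Aug 31, the
value the package's prior-mass function computes analytically;
coefficients Normal(0, 5); σ half-Cauchy with scale 20 (a half-Cauchy has
no finite SD, so a quoted "SD" of 20 is read as the scale, the standard
usage); σ_year half-Cauchy(5). Year effects are
Normal(0, 1) × σ_year in the model statement.

**Sampler.** A blocked Gibbs scheme, authored here:

- latent hatch dates: conjugate normal, vectorised;
- coefficients *and* year effects in one joint Gaussian block — the year
  covariate is constant within years, so separate updates of β_year and
  the year effects would crawl along their posterior ridge (this single
  change moves the worst-parameter effective sample size from ~400 to
  >1000 at 4 × 2000 iterations);
- σ_year: slice sampling on its conditional with the year effects
  integrated out (a partially collapsed Gibbs step; the year effects are
  redrawn afterwards inside the joint block), which removes the classic
  centred-parameterization coupling — this replaces a non-centred
  parameterization, which targets the same pathology but suits gradient
  samplers rather than Gibbs;
- σ: inverse-gamma draw after inverse-gamma parameter expansion of the
  half-Cauchy prior (Makalic & Schmidt 2016);
- latent elevation: vectorised random-walk Metropolis (it enters the
  predictor quadratically, so its conditional is non-Gaussian); step size
  1.2 × the per-brood measurement SD, acceptance ≈ 0.6–0.7;
- latent temperature/precipitation: conjugate normal (linear entry).

Chains start from overdispersed initial values. The full-scale
configuration is 6 chains × 10,000 iterations with the second half kept;
the default is 4 × 2000, which finishes in seconds at n ≈ 600 and passes
all gates. Convergence gates: split-R̂ < 1.01 (classic split potential
scale reduction, cross-checked in the tests against an independent
reimplementation to 1e-8), effective sample size above 1500 scaled
proportionally to the kept draws, and MCSE < 5% of the posterior SD, per
model parameter (latent per-brood quantities are excluded from the gates:
width-0 records make them degenerate by construction).

**Reporting.** Standardized coefficients convert to natural units as
β/SD_raw × factor (×100 per 100 m, ×10 per decade, ×7 per week; the
interaction per 100 m per decade; precipitation per 100 mm of
window-total via ×100/window-days). The precipitation delay equivalent —
millimetres of additional window precipitation per one-day hatching
shift — is window_days/(β/SD_raw). Posterior predictive checks replicate
datasets from the fitted observation model at posterior draws (using
observed covariates; latent-covariate draws change the replicates
negligibly) and report tail probabilities of mean/SD/quantile statistics.
Partial-effect curves hold other covariates at their means and use the
average region intercept.

## 5. The synthetic study system

The generator emulates a 20-year Alpine citizen-science dataset: ~120
1-km cells between 1500 and 3100 m in four contiguous regions, each cell
a 5×5 grid of 200-m elevations; ~700 true broods sampled with a cell
weight peaking at 2450 m (brood elevation SD ≈ 240 m). True hatching
dates follow the linear predictor with region intercepts 175/176/177/171
(late June), residual SD 9 d and among-year SD 1.9 d. Default
standardized effects (days per SD): elevation −0.6, elevation² 0.92,
year −0.68, elevation × year −0.12, winter −0.05, precipitation 1.14,
meltstart 0.6, temperature −1.05 — documented scenario defaults, not
estimates. The observer-day effect is zero in the generator: observer
timing is an artefact of the observation process, not a cause of hatching
dates, and the fitted observer-day coefficient absorbs exactly the
selection the covariate exists to correct (it comes out positive on
synthetic data for the same reason it does on real data).

Snow series are idealised noise-free curves — winter plateau, strictly
decreasing melt segment, summer minimum — so melt metrics admit exact
recovery tests; onset rises with elevation (0.03 d/m), carries shared
year anomalies (SD 13 d) and a long-term trend (−2 d/decade at 2450 m,
increasing by 0.005 d/decade per metre, so melt advances at low and
delays at high elevations); duration is Normal(70 d, 16 d). These
choices keep the across-brood meltstart SD near 17–20 d and all predictor
correlations below ~0.6. Climate fields are seasonal cycles plus
cell-year anomalies at monthly resolution plus daily noise, with sub-grid
SDs scaling with cell relief; the generator's "true" windows are the
59-day Feb–Mar temperature window and the 61-day precipitation window
ending May 15 (the scan's latest admissible end-day). Winter stations
give correlated temperature/depth series (r = −0.6).

Observer effort is a log-Gaussian intensity over date × elevation, wider
than the brood distribution on both axes (date SD 55 d vs ≈11 d; elevation
SD 700 m vs ≈240 m), with Poisson person counts per cell-day. Detection is
per person, day and stage (nestling stage most visible); each observer
files at most one record per cell-day (configurable), mirroring how
portals collapse a visit into one record per species and site — without
this cap the same brood can enter the analysis twice and
pseudo-replication shrinks the intervals. Location-precision classes are
drawn per record (5% nest / 35% 200-m / 60% 1-km); the observed 200-m
sub-cell is drawn with weights matching the downstream measurement model,
and nest-precision records carry a reported elevation within ±0.5 m. A
fraction of cells (4%) host systematic monitoring yielding exact hatch-day
records. Standardization constants are computed from the observable side
of each covariate, matching the analysis convention of scaling by raw
observed SDs. An optional second-brood mixture (offset + proportion)
defaults to proportion 0 because the real proportion is unknown and
first/second broods are indistinguishable in this record type.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial autocorrelation in residuals (generated
iid, so the semivariogram diagnostic is flat by construction), realistic
topography, weather persistence beyond monthly anomalies, observer
heterogeneity in code usage, nest failure and renesting, and any
dependence of detectability on elevation beyond the effort surface.

## 6. Numerical choices and scale

Interval midpoints of detected records deviate from the true hatch date
roughly uniformly within ±width/2 (SD ≈ width/3.46) while the model
assumes width/4; the estimated σ absorbs the small difference. The
measurement-error monotonicity property (wider intervals ⇒ no smaller
posterior SDs) is exercised with heterogeneous widths, because with
homogeneous widths the residual SD is unidentified after inflating the
widths and the property degenerates. Problem sizes in the test suite are
desk-scale by design: recovery uses 3 replicates of ~600 broods at
4 × 2000 iterations, window recovery 100 planted-signal replicates,
dedup 1000 random instances against an exhaustive oracle; the full suite
runs in about a minute on one CPU. Empirical CI coverage of the 8
generating coefficients, pooled over replicates, is required to be
statistically compatible with 95% (≥90% of checks), the correct
operational form of "the intervals cover the truth" — the joint event
*all* coefficients covered simultaneously has probability ≈ 0.95⁸ ≈ 0.66
per replicate even for perfectly calibrated intervals.

## 7. Known limitations

- The Gibbs sampler is model-specific; adding covariates is easy, but
  structural changes (non-normal errors, spatial effects) need new
  blocks.
- The width/4 observation SD treats the interval as an approximate 95%
  normal range; strongly asymmetric stage windows would warrant an
  explicit interval-censored likelihood.
- Window selection pools broods across years; with few cells the
  effective sample for the correlation is smaller than the brood count.
- First and second broods are indistinguishable; the optional mixture in
  the generator exists to study the sensitivity, not to estimate it.
- The KDE observer diagnostic uses Scott's-rule bandwidths; at small n
  the 95% mass regions are inflated by smoothing (the tests allow 5% on
  the area of a known normal).
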