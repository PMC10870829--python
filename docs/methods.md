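# Methods

This note documents the models implemented in `coalburden`, the defaults of
the synthetic world, the numerical choices, and what the package's tests do
and do not establish about real data.

## The synthetic world

Geography is a `grid_size × grid_size` lattice of unit cells; one cell plays
the role of one ZIP code (`zip_id = j·grid_size + i`, `i` increasing
eastward). There are no real coordinates: the analysis depends only on the
spatial structure of exposure relative to population, which the lattice
preserves while removing geodesy.

**Emissions.** Each EGU gets a fixed random cell and a lognormal base
emission rate (median 100 arbitrary mass units, σ = 1.0 — heavy-tailed, so a
few large plants dominate cumulative emissions as real fleets do). Annual
emissions decline geometrically (`emissions_decline = 0.92` per year,
roughly matching two decades of deep SO₂ reductions), drop multiplicatively
to `scrubber_effect = 0.25` from the scrubber year onward (flue-gas
desulfurization removes most but not all SO₂), and go to zero from the
retirement year. Half the plants receive a scrubber, 15% retire, with event
years drawn uniformly from the configured windows.

**Transport truth.** The ground-truth coal PM₂.₅ field is the *expectation*
of the trajectory model: a parcel's position at step *t* is exactly
N(source + t·wind, t·σ²I), so the expected survival-weighted residence in a
cell is a product of 1-D normal CDF differences summed over steps. The truth
field is `truth_scale` × Σ_EGU emissions × this kernel — exactly linear in
emissions by construction, which is what makes per-plant attribution
well-defined. `truth_scale = 0.1` μg/m³ per unit puts early-study mean coal
PM₂.₅ near 2–3 μg/m³ with single-cell peaks of several μg/m³, the
observed magnitude for sulfate from coal. Wind defaults to (0.35, 0.05)
cells/step — predominantly eastward, giving the east-skewed exposure
gradients seen downwind of coal regions — with `diffusion_sd = 0.6`,
`parcel_lifetime = 4` steps (e-folding survival, proxying the multi-day
SO₂→sulfate conversion and deposition) and a 10-step horizon.

**Population and mortality.** Strata default to 2 age bands × 2 sexes with
baseline all-cause rates 0.018–0.075 deaths per person-year (Medicare-like
magnitudes for 65–74 and 75+). Person-years per zip-stratum are lognormal
around 2000 (σ = 0.5) and constant over time; this world has far fewer,
larger ZIPs than reality, deliberately, so that desk-scale runs leave the
regression well identified. Deaths are Poisson with mean
`person_years · baseline_s · exp(β_true·x + γ·u)`, with
`β_true = ln(1.0125)` per μg/m³ by default.

**Confounding scenario.** When enabled, a time-invariant covariate `u` is
the standardized long-run spatial pattern of coal PM₂.₅ plus independent
noise (restandardized), entering mortality as `exp(γ·u)`. This produces
strong exposure–confounder correlation with a tunable mortality effect;
default off (γ = 0).

**RNG.** One root seed; each stage (inventory, truth, deaths, parcels per
EGU-year, background, NO₂, confounder, population) draws from its own
`SeedSequence` spawn key, so any stage is reproducible in isolation and
adding a stream never perturbs the others.

## Exposure model

The dispersion module is a 2-D discrete-time advection–diffusion random walk
with exponential parcel survival — a deliberate, desk-scale stand-in for a
full trajectory model driven by meteorological reanalysis. It preserves the
structure that matters for the method (trajectory counts × emissions,
linearity, source separability) and nothing else: no vertical structure,
chemistry, deposition distinctions or real winds. Residence counting uses
the parcel's cell at each step (release step included, weight 1), with no
within-cell plume spread. `n_parcels = 500` per release and 6 releases per
year keep Monte Carlo noise in the exposure field a few percent of the cell
means while the full default pipeline completes in well under a minute.

## Calibration

A single national coefficient is fitted by zero-intercept least squares of
the training-year reference concentrations on raw exposure totals
(closed form Σxy/Σx², clipped at zero with a logged warning if the inputs
are anticorrelated). A free intercept would create concentration mass
attributable to no plant; spatially varying or nonlinear scaling schemes are
intentionally out of scope. Alternative metrics — the unscaled raw counts
and a user-supplied annual sulfate adjustment factor — feed the sensitivity
analyses; deriving adjustment factors from monitor data is not implemented.

## CRF estimation

Stratum intercepts enter as explicit fixed effects rather than via a
conditional likelihood; for Poisson regression the two give identical β (a
standard result), and fixed effects keep a single code path for prediction.
Fitting is IRLS (statsmodels GLM) with a log person-time offset,
`tol = 1e-10`, 100 iterations maximum; nonconvergence raises with the
deviance trace. Identifiability preconditions (≥ 2 distinct exposure values,
positive person-time, nonzero deaths) are checked up front. The 95% interval
is Wald on the log scale. No overdispersion adjustment is applied — the
generator is exactly Poisson; for real data a quasi-Poisson scale factor
would be the first extension. The package reports `exp(β)` and
`100·(exp(β)−1)` as the percent increase per μg/m³.

Residual PM₂.₅ (total minus coal) is computed before co-pollutant fits;
negative values are clipped at zero with a logged count (impossible under
the generator's defaults, possible with user-supplied fields).

## Burden accounting

The attributable fraction `1 − exp(−β·x)` is applied to *observed* deaths,
not model-predicted baselines — standard health-impact-function practice,
and consistent with a counterfactual of zero coal SO₂ emissions. Years
beyond the observed record can be filled per ZIP with the trailing-3-year
mean of observed deaths. Burden CIs propagate only the CRF interval (β at
its Wald endpoints), not Poisson noise in the counts, so burden uncertainty
scales with RR uncertainty. Per-EGU deaths are apportioned proportionally to
each plant's share of the zip-year's coal PM₂.₅ — equivalent, to first order
in β·x, to separate single-plant counterfactuals, and exactly conservative:
plant-level deaths sum to the zip-year totals at machine precision. The
emissions-concentration statistic sorts plants by study-period emissions
(descending) and reports the attributed-death share of the smallest prefix
holding a given emissions share; sorting by emissions rather than by deaths
is a deliberate choice where either reading is defensible. Headline numbers
are rounded to 2 significant figures.

## Sensitivity analyses

**E-value**: `E = RR + √(RR(RR−1))`, reported to 4 significant figures,
applied to the RR per 1 μg/m³ exactly as estimated (no rescaling of the
contrast); reciprocal transformation for protective RRs.

**First differences**: WLS of within-zip changes in death rate on changes in
exposure, intercept included, weights the pair-mean person-years; year pairs
are consecutive-pooled by default, endpoints-only as an option. The default
runs on the rate-difference scale because zip-year death counts can be zero;
a log-rate mode (dropping zero-rate pairs) is the flag `scale="log"`.
The scale choice matters for what "removing confounding" means under this
generator: the confounder is *multiplicative* on the rate, so log-scale
differencing cancels it exactly (Δlog rate = β·Δx when the stratum mix is
time-constant), whereas rate-scale differencing retains a leverage
interaction between the confounder and the size of exposure changes. The
tests therefore check the rate-scale estimator against its own noise-free
estimand and use the log scale for exact confounder removal. A naive pooled
cross-sectional estimator (year fixed effects, no zip controls) is provided
purely as the biased comparator.

**Invariance audit**: refits the CRF and burden under raw and scaled
exposure metrics and reports the β ratio (equal to the scaling coefficient
for a pure rescaling) and the relative difference in total excess deaths
(zero for a pure rescaling, since burden depends on β·x only). It reports
rather than asserts, so genuinely different metrics produce a quantified
discrepancy instead of an error.

## Problem sizes and test design

The default world — 25 EGUs, 400 ZIPs, 12 years, 4 strata, 500 parcels ×
6 releases per EGU-year — was sized so the CRF standard error is small
relative to β_true (≈ 1.5% of it) and a complete pipeline run takes seconds.
The coverage check refits the model on 100 independently re-simulated death
panels over a fixed exposure field and requires the 95% Wald CI to cover
β_true at least 93 times — a calibrated binomial bound on a nominal-95%
procedure. Exact invariants (linearity in emissions, additivity of
apportionment, rescaling invariance of burden, likelihood-oracle agreement)
are tested at tolerances of 1e-9 to 1e-12 because they hold algebraically,
not statistically.

## What passing tests do and do not show

The generator matches the analysis model by construction. Passing parameter
recovery therefore validates the *estimation machinery* — not the
correctness of the log-linear CRF for real populations, the accuracy of any
real exposure model, or robustness to confounding structures other than the
time-invariant multiplicative one implemented. Not emulated: real
meteorology and chemistry, population migration, enrollment dynamics,
exposure measurement error correlated over space, model misspecification of
the dose–response shape, and the richer covariate sets real analyses adjust
for. Results on this world say nothing about the magnitude of real-world
burdens; they say the pipeline computes what it claims to compute.
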