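# Methods

This note documents the models, numerical choices and known limits of each
stage, in the order the pipeline runs them.

## Synthetic scenarios

The generator replaces closed national monitoring databases with synthetic
stand-ins that share their statistical structure; its defaults *are* the
study conditions the rest of the package is tested under.

**Reference grid.** Planar coordinates in km on a synthetic CRS, square
cells of 3 km (9 km² cells), cell-centre georeferencing. No geographic
projection handling: the package targets method-level fidelity, not
cartographic fidelity.

**Random fields.** Stationary Gaussian fields are simulated by circulant
embedding on a torus twice the grid size; the rare negative embedding
eigenvalues at these range/extent ratios are clipped to zero, and the
nugget is added as white noise. The empirical variogram of the output
converges to the requested model as the grid grows (checked at 200×200).

**Water panel.** Latent log-concentrations follow a single-factor model: a
common component (unit random effect 45%, smooth time trend 35%, shared
record noise 20% of the factor) with total share λ = 0.3, plus a residual
multivariate normal whose correlations are rescaled so the *total*
cross-substance correlation equals the configured matrix (0.9 by default,
matching the strong between-substance correlations these panels show).
Sampling dates are a homogeneous Poisson process per unit over 2000-01-01 …
2012-12-31 (the panels have no periodicity). Concentrations are
exponentiated log-normals — the marginal distribution is nowhere stated for
the real data, so log-normality is this package's modelling choice for
positive, right-skewed concentrations. Detection limits default to the
marginal quantile that yields the configured censoring target (0.88,
the water panel's observed censoring level); censored records store the DL.

Two water marginals are used. The exposure scenario itself uses a
PAH-in-drinking-water scale (median 10 ng/L, geometric SD ≈ 3.3, mg/L
units). The imputation *validation* panel instead mimics a more complete
pollutant pair (arsenic-with-selenium style, µg/L): its marginal
(μ = −0.7027, σ = 1.9677 on the log scale) is solved analytically from the
two quantile equations so that DL thresholds of 3 and 5 µg/L censor 82% and
88% of records — the validation design's stated censoring levels.

**Soil survey.** Fourteen smooth covariate rasters (spherical, 30 km
range); the latent log field adds a linear trend on two covariates, a
nonlinear term in a third (`threshold`: max(c,0); `abs`: |c|, used where a
pronounced nonlinear link is wanted), an inverse-distance contribution from
each polluted site within 3 km (the same functional form the source proxy
estimates, so buffer-radius recovery is well-posed), and a spherical
residual (nugget 0.05, partial sill 0.30, range 20 km). The survey samples
a regular grid (default every 5th cell ≈ 16 km at 3 km cells); the DL sits
at the field's 68% quantile, the soil network's observed censoring level.
Base level exp(−3.7) ≈ 0.025 mg/kg is a typical median topsoil
concentration for a 5-ring PAH.

**Air years.** Station annual means are additive in the standardized
emission proxy (coefficient 0.4), altitude (0.5 × `year_effect`) and log
population (0.2), plus an exponential-variogram residual (sill 0.15²,
range 15 km) and 0.05 ng/m³ measurement noise, floored at 0.01 ng/m³.
`year_effect` toggles the altitude term to emulate the cold-winter /
mild-winter contrast between consecutive years (wood combustion at
altitude). The altitude field is generated independently of emissions and
population so that with `year_effect = 0` the station–altitude correlation
vanishes. 76 stations by default, with rural/suburban/urban ×
background/traffic/industrial types carried as metadata for stratified
cross-validation reporting.

**Receptors.** Two age classes, children 0–17 (17 y) and adults 17–70
(53 y), partitioning the 70-year lifetime. Body weights (30/70 kg), intake
rates and the 0.25 self-consumption fraction are plausible round numbers
for a national population — they are configuration defaults, not survey
values, and carry no authority.

## Censored-panel multiple imputation

The panel is reshaped to one row per (unit, date) with one column per
substance; a cubic polynomial in scaled time is appended as always-observed
columns, pooled across units (the functional form of the real panels' time
trends is unstated; a low-order polynomial is this package's choice). EM
runs on log-concentrations.

**Censoring-aware E-step.** Censored cells are *not* treated as
missing-at-random: at 82–88% censoring that would estimate the
between-substance regression from the top ~18% of the target substance — a
truncated-dependent-variable selection that biases every imputation toward
the DL (measured: it erases the method's advantage over DL/2 entirely).
Instead each unknown cell contributes the mean and variance of its
conditional normal truncated above at log DL. Rows with a single censored
cell (the dominant case when a well-observed helper substance exists) are
handled exactly via univariate truncated-normal moments, with the inverse
Mills ratio switched to its asymptotic expansion below α = −8 for
stability; rows with several jointly censored cells use per-cell truncated
moments with conditional cross-covariances scaled by the per-cell variance
shrinkage — a standard componentwise approximation, adequate because those
rows carry little information in any case. Plainly missing cells (substance
not measured on that date) get an infinite bound, recovering the classical
E-step.

**Bootstrap and draws.** Each of the m imputations resamples rows with
replacement, runs EM (tolerance 1e-5 on parameter shift, ≤100 iterations,
1e-8 ridge; non-PSD Σ from round-off is eigenvalue-clipped with a warning),
then draws the original panel's censored cells jointly from their
conditional MVN by rejection against the DL bounds (≤50 attempts), falling
back to componentwise truncated normals. Draws are truncated to (0, DL] —
physical consistency requires imputations below the limit that triggered
censoring. m defaults to 8; five is usually sufficient but heavy censoring
warrants more. Each replicate has an independent RNG substream; uncensored
cells are bit-identical across imputations. Units with every record
censored draw from the pooled conditional distribution (only the
between-substance correlation informs them).

Evaluation restricts AME/RMSE to originally-censored cells and scores the
across-imputation mean. The validation experiment censors the target
substance only, leaving the partner observed — that is the configuration in
which a "more complete" helper pollutant makes the imputation informative,
and it is what produces the large imputation-vs-substitution bias gap.

## Water aggregation

Segment weights are a partition of unity by construction (property-tested).
Imputations are pooled at the unit-mean stage: the order is immaterial for
the means (everything downstream is linear) but defines the uncertainty
layer — the across-imputation standard deviation of each unit mean is
propagated to municipalities as √(Σ w² sd²) and rasterized alongside the
value. Municipality→cell assignment uses Voronoi tessellation of synthetic
municipality seeds (real boundary polygons are out of scope); rasterization
copies each municipality's value exactly, with no smoothing, and flags the
cells of unserved municipalities missing.

## Geostatistics engine

Matheron's estimator on half-open lag bins [a, b) (ties to the lower bin);
bins with zero pairs are omitted. Variogram fitting is weighted least
squares with pair-count weights — the fitting criterion is a policy choice;
initial values come from the empirical moments, and the optimizer falls
back to them with a warning if it fails. The spherical model reaches its
sill at the range; the exponential uses the effective-range convention
(95% at the range).

Kriging is global-neighbourhood (all points in every system): the synthetic
n stays small enough, and it removes a tuning axis. The semivariance form
of the ordinary-kriging system is solved with a Lagrange multiplier;
duplicate coordinates are averaged (with a warning) before solving, and a
tiny jitter is added only if the system is numerically singular. Weights
sum to one to 1e-8; variance is clipped at zero. Indicator kriging codes
exceedance 1{not censored}, kriges the indicators and clips to [0, 1];
single-class inputs return a constant surface with a warning. Residual
kriging fits the trend (OLS or a seeded 500-tree random forest), fits the
residual variogram, and adds the kriged residual to the trend surface;
LOOCV refits the trend per fold but holds the residual variogram fixed by
default (refitting is available) to keep folds comparable. Anisotropy is
not modelled.

## Soil mapping

The AIC buffer regression runs on log concentrations (Gaussian likelihood
on right-skewed data) with the covariate stack included, so the proxy term
only has to explain the hotspot structure; AIC applies to this linear
auxiliary regression, not the random forest — a forest has no likelihood to
base an information criterion on. Ties go to the smaller radius; radii
whose proxy is identically zero are skipped. d_min is half a cell width to
bound 1/d at colocation, and the proxy sums over all sites in the buffer
(nearest-site-only is the unstated alternative). Censored observations
enter the trend/residual value model at DL/2 — the exceedance-probability
covariate is how censoring information reaches the map — and predictions
are clipped at zero. OOB covariate selection: backward elimination dropping
the lowest permutation importance, keeping the subset with minimum OOB MSE;
deterministic under the seed.

The buffer-recovery experiment needs observations inside the 3 km buffers
to be estimable at all, so it runs on a denser survey (every 2nd cell on a
60-cell grid, 40 sites, site amplitude 1.5); the default 16 km survey
spacing leaves the 1 km proxy literally zero at every observation.

## Air mapping

All subsets of {emission proxy, altitude, population} plus intercept-only
are scored by LOOCV of the full regression-kriging predictor; the lowest
RMSE wins, ties to the smaller model, collinear terms dropped up front.
Year combination uses inverse-variance-style weights w ∝ 1/RMSE²
(normalized); the validity mask is the conjunction altitude > 1800 m AND
density < 30 persons/km², with density = population raster / cell area.

## Exposure

Risk is linear no-threshold, EIR = SF × LADD per route — at these dose
scales (LADD ≲ 1e-5 mg/kg/day) the difference from 1 − exp(−SF·LADD) is
far below every other uncertainty. The two age classes are computed
independently; no lifetime-spliced receptor. The vegetable transfer is a
deliberately simplified stand-in for a full multimedia fate model: an
air-deposition term (C_air · v_dep · interception/weathering ÷ yield) plus
a linear soil-to-plant term, both linear in their input; soil-to-plant
factors are small (2e-3 … 5e-3) as befits a log K_ow ≈ 6 compound.
Commercial food concentrations are spatially constant configuration values.
Slope factors (7.3 oral, 3.9 inhalation per mg/kg/day) are defaults to be
overridden, not toxicological guidance. Homegrown vegetable intake is the
receptor's vegetable intake × self-consumption fraction; the remaining
(1 − f) scores against the commercial concentration of the same category.
Cell masks propagate: a cell missing water data or outside the air model's
validity is flagged in every dose and risk layer that depends on it, never
silently filled.

## Orchestration and problem sizes

One master seed drives named substreams for every generator and stage; a
JSON manifest records config hash, seeds, per-stage diagnostics (censoring
rates, selected radius/covariates/terms, LOOCV ME/RMSE, combination
weights) and output checksums. Re-runs with an identical config and intact
outputs skip completed stages unless forced; independent runs with the same
seed produce byte-identical outputs.

Tests and the reproduction script run at scaled-down sizes chosen to keep
the statistical structure intact: grids of 20–60 cells per side, ~80–400
soil points, 76 stations, 60–300 forest trees inside LOOCV loops, 5–20
replicate seeds per experiment. These sizes are the package's documented
study conditions for its own claims.

## What the synthetic tests do and do not show

Passing tests demonstrate that each algorithm recovers the structures the
generator builds in — censoring-consistent imputation under a correct
log-normal factor model, variogram and buffer-radius recovery, drift-term
selection under strong effects — and that the pipeline's plumbing (masks,
weights, units, determinism) is correct. Real monitoring data violate the
generator's assumptions in known ways: non-log-normal marginals, varying
per-record DLs, non-stationarity (indicator kriging in particular leans on
a stationarity assumption the data need not satisfy), preferential station
siting, and transfer processes far richer than the two-term vegetable
model. Results on real databases therefore inherit those caveats; the
validity masks and the across-imputation uncertainty layer exist precisely
to keep the weakest cells visible.
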