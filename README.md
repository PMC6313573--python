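# geoexpose

Spatialization of sparse, heavily left-censored environmental monitoring
data and multimedia exposure mapping for a carcinogenic PAH indicator
(benzo[a]pyrene-style), on a national-scale reference grid of 3 × 3 km
cells.

## Who this is for

Environmental-health modellers who need to turn routine monitoring
databases — a drinking-water panel where ~88% of records sit below the
detection limit, a 16 km-spaced topsoil survey with ~68% censoring, fewer
than a hundred air-quality stations — into per-cell exposure and excess-risk
indicators, with the uncertainty of every processing step carried along.
Because such databases are closed, the package ships a first-class synthetic
scenario generator that reproduces their statistical structure (censoring
rates, cross-substance correlation, spatial autocorrelation, covariate
links), so every stage is testable offline against known ground truth.

## The methods

**Left-censored water panel → municipal concentrations.** Records below the
detection limit (DL) are multiply imputed with a bootstrap-EM algorithm on
the joint log-normal model of all substances plus a cubic time polynomial:
for each of *m* = 8 imputations, the model (μ, Σ) is estimated by EM on a
bootstrap resample — censored cells contributing truncated-normal
conditional moments — and each censored cell is drawn from its conditional
distribution given the observed cells of its row, truncated to (0, DL].
Unit means use segments-of-influence weights (each observation owns the
interval between the midpoints of its flanking gaps over the 2000–2012
window), municipalities aggregate unit means weighted by served population,
and cells inherit their municipality's value exactly. Naive baselines
(DL/2, DL/√2, 0 substitution) and an artificial-censoring harness quantify
the bias each method leaves on known data (AME, RMSE).

**Topsoil mapping.** Residual kriging with a random-forest trend: the
covariate stack combines an indicator-kriged probability of exceeding the
DL, an inverse-distance polluted-site proxy Σ 1/max(d, d_min) inside a
buffer whose radius is chosen by AIC over candidates {1, 2, 3, 5, 10} km,
and 14 exhaustive soil-property covariates; covariates are selected by
backward elimination on permutation importance at minimum out-of-bag MSE;
residuals are kriged with a spherical variogram fitted by pair-count-
weighted least squares.

**Air mapping.** Regression kriging: drift terms chosen by leave-one-out
ME/RMSE among {emission proxy (inventory emissions distance-weighted within
20 km), altitude, population}; exponential residual variogram; the two
annual maps are combined with weights ∝ 1/RMSE², and cells with altitude
> 1800 m and population density < 30 km⁻² are masked as outside the model's
validity.

**Exposure.** For each age class (children 0–17, adults 17–70) and pathway
(drinking water, soil, home-grown vegetables via a simplified air-deposition
+ root-uptake transfer, commercial food, inhalation):

    LADD = C · IR · ED / (BW · LT)   [mg·kg⁻¹·day⁻¹]
    EIR_route = SF_route · Σ LADD_route,  reported ×10⁶

with IR the intake rate, ED the class's exposure duration, LT = 70 y, BW
body weight and SF the route's slope factor (configuration values).
Water-missing and air-invalid cells propagate as grey-border and
cross-hatch overlays on the rendered risk map.

## Worked example

`python examples/01_impute_censored_panel.py` builds a complete
two-substance panel (log-scale correlation 0.9, ~4900 records per
substance), censors it at 3 and 5 µg/L, and scores each completion method
on the censored cells:

```
 threshold        method  censoring_fraction   AME  RMSE
       3.0    imputation               0.829 0.327 0.494
       3.0       half_dl               0.829 1.068 1.149
       3.0 dl_over_sqrt2               0.829 1.586 1.689
       5.0    imputation               0.884 0.499 0.753
       5.0       half_dl               0.884 1.897 2.009
       5.0 dl_over_sqrt2               0.884 2.806 2.945
```

The imputation's error is 3–4× smaller than either constant substitution at
both censoring levels because the correlated second substance pins down
each censored value. `examples/07_full_pipeline.py` runs every stage on a
20 × 20-cell territory and ends with:

```
pathway contributions (%):
age_class        adult_17_70  child_0_17
commercial_food         54.4        53.8
homegrown_veg           11.5        10.8
inhalation               6.0         6.6
soil                     2.4         7.6
water                   25.7        21.3

adult total EIR x1e6: median 13.7, P95 19.5 over 353 valid cells
```

— commercial food dominates the dose, drinking water is second, vegetables
a close third, soil smallest, and ingestion risk far exceeds inhalation.
The other examples (`02`–`06`) demonstrate each stage in isolation.

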