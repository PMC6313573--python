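"""Topsoil mapping: source proxy, AIC buffer selection, RF residual kriging.

Generates a coarse censored soil survey over a field with a 3 km polluted-
site decay, then runs the full mapping pipeline: indicator-kriged exceedance
probability, inverse-distance source proxy at the AIC-selected buffer
radius, OOB covariate selection, random-forest trend + spherical residual
kriging.
"""

import warnings

from geoexpose.kriging import ObservationSet
from geoexpose.scenario import ScenarioConfig, simulate_soil_survey
from geoexpose.soil import map_soil

cfg = ScenarioConfig(seed=6, grid_nx=30, grid_ny=30, soil_spacing_cells=2,
                     n_polluted_sites=20)
obs_df, covariates, sites, truth = simulate_soil_survey(cfg, site_amplitude=1.5)
print(f"{len(obs_df)} survey points, {obs_df['censored'].mean():.0%} censored, "
      f"{len(sites)} polluted sites")

obs = ObservationSet.from_frame(obs_df)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = map_soil(obs, covariates, sites, cfg.template(),
                      candidate_radii=(1, 2, 3, 5, 10), seed=6, rf_trees=200,
                      run_loocv=True)

print(f"AIC-selected buffer radius: {result.proxy_radius_km} km "
      f"(generator truth: 3 km)")
print(f"OOB-selected covariates: {result.selected_covariates}")
print(f"LOOCV: ME {result.loocv['me']:.3f}, RMSE {result.loocv['rmse']:.3f} mg/kg")
print(f"mapped concentrations, mg/kg: min {result.raster.values.min():.3f}, "
      f"max {result.raster.values.max():.3f}")
print("\nThe exceedance-probability covariate carries the censoring")
print("information into the map; the proxy radius should recover the 3 km")
print("decay built into the generator, and LOOCV states the map's accuracy.")
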