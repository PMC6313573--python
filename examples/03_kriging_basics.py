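"""Variogram fitting, ordinary kriging and indicator kriging on a toy field.

Simulates a stationary Gaussian field with a known spherical variogram,
samples it at 300 points, refits the variogram, and kriges back onto the
grid; then kriges detection-limit exceedance indicators into an exceedance
probability surface.
"""

import numpy as np

from geoexpose.kriging import ObservationSet, indicator_krige, ordinary_krige
from geoexpose.scenario import simulate_gaussian_field
from geoexpose.variogram import VariogramModel, fit_empirical

true = VariogramModel("spherical", nugget=0.1, partial_sill=0.9, range_km=20.0)
field = simulate_gaussian_field(80, 80, 3.0, true, rng=4)
gx, gy = field.cell_centers()

rng = np.random.default_rng(5)
idx = rng.choice(gx.size, 300, replace=False)
obs = ObservationSet(gx[idx], gy[idx], field.values.ravel()[idx])

fitted = fit_empirical(obs.x, obs.y, obs.values, family="spherical")
print(f"true variogram:   nugget 0.10, partial sill 0.90, range 20.0 km")
print(f"fitted variogram: nugget {fitted.nugget:.2f}, "
      f"partial sill {fitted.partial_sill:.2f}, range {fitted.range_km:.1f} km")

pred, var = ordinary_krige(obs, fitted, gx, gy)
err = pred - field.values.ravel()
print(f"kriging RMSE over the grid: {np.sqrt(np.mean(err**2)):.3f} "
      f"(field sd {field.values.std():.3f})")

dl = np.quantile(obs.values, 0.6)
cens = obs.values <= dl
iobs = ObservationSet(obs.x, obs.y, obs.values, censored=cens)
prob, _ = indicator_krige(iobs, gx, gy)
print(f"exceedance probability surface in [{prob.min():.2f}, {prob.max():.2f}], "
      f"mean {prob.mean():.2f} (share of uncensored points: {(~cens).mean():.2f})")
print("\nKriging reduces the error well below the field's own spread, and the")
print("indicator map gives the probability of exceeding the detection limit.")
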