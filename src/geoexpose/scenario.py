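"""Synthetic monitoring scenarios with the structure the analysis assumes.

The real analysis runs on closed national databases: a heavily left-censored
multi-substance drinking-water panel over distribution units, a coarse
regular topsoil survey with covariate-driven trend and polluted-site
hotspots, a sparse network of air-quality stations correlated with an
emission inventory, altitude and population, plus receptor consumption
profiles.  This module generates stand-ins for all of them on a planar
synthetic grid, with tunable censoring rates, cross-substance correlation
and spatial autocorrelation, so that every downstream stage is testable
offline under known ground truth.

Concentrations are generated on the log scale and exponentiated
(environmental concentrations are positive and right-skewed); detection
limits are applied on the natural scale.  All generators are deterministic
under a fixed seed, with one named substream per product.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd
from scipy.stats import norm

from .air import build_emission_proxy
from .exposure import ReceptorProfile, default_receptors
from .grids import RasterField
from .soil import build_source_proxy
from .variogram import VariogramModel

# Marginal of the two-substance *validation* panel (log scale, values in
# ug/L, arsenic-with-selenium style), solved so that DL thresholds of 3 and
# 5 ug/L censor 82% and 88% of records respectively:
#   (ln 3 - mu)/sigma = z_0.82,  (ln 5 - mu)/sigma = z_0.88.
VALIDATION_LOG_MU = -0.7027
VALIDATION_LOG_SIGMA = 1.9677

# Default water marginal for the exposure scenario itself: a hydrophobic
# PAH-like indicator in drinking water, mg/L — median 1e-5 mg/L (10 ng/L),
# geometric SD ~e^1.2.
WATER_LOG_MU = float(np.log(1e-5))
WATER_LOG_SIGMA = 1.2


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from (seed, name)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclasses.dataclass
class ScenarioConfig:
    """Study-condition knobs for the synthetic scenario.

    Defaults are the conditions of the emulated national study, scaled to a
    synthetic territory: ~88% water censoring, ~68% soil censoring,
    76 stations, 3 km reference cells, a 2000-2012 water window, and strong
    (0.9) cross-substance correlation.
    """

    grid_nx: int = 40
    grid_ny: int = 40
    cell_size_km: float = 3.0
    n_substances: int = 2
    substance_correlation: float | np.ndarray = 0.9
    detection_limits: dict | None = None   # substance -> DL; derived if None
    censoring_target: float = 0.88
    soil_censoring_target: float = 0.68
    n_units: int = 200
    n_municipalities: int = 120
    n_stations: int = 76
    n_polluted_sites: int = 25
    soil_spacing_cells: int = 5            # ~16 km survey grid on 3 km cells
    mean_obs_per_unit: float = 25.0
    date_window: tuple = ("2000-01-01", "2012-12-31")
    water_log_mu: float = WATER_LOG_MU
    water_log_sigma: float = WATER_LOG_SIGMA
    common_factor_share: float = 0.3       # unit effect + time trend share
    soil_variogram: VariogramModel = dataclasses.field(
        default_factory=lambda: VariogramModel("spherical", 0.05, 0.30, 20.0))
    air_residual_variogram: VariogramModel = dataclasses.field(
        default_factory=lambda: VariogramModel("exponential", 0.0, 0.0225, 15.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_target < 1.0:
            raise ValueError("censoring_target must lie in [0, 1)")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        R = self.correlation_matrix()
        if not np.allclose(R, R.T):
            raise ValueError("substance correlation matrix must be symmetric")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("substance correlation matrix must be PSD")

    def correlation_matrix(self) -> np.ndarray:
        p = self.n_substances
        if np.isscalar(self.substance_correlation):
            R = np.full((p, p), float(self.substance_correlation))
            np.fill_diagonal(R, 1.0)
            return R
        R = np.asarray(self.substance_correlation, float)
        if R.shape != (p, p):
            raise ValueError("correlation matrix shape mismatch")
        return R

    def substances(self) -> list[str]:
        return [f"S{i}" for i in range(self.n_substances)]

    def template(self) -> RasterField:
        return RasterField(
            np.zeros((self.grid_ny, self.grid_nx)), cell_size_km=self.cell_size_km
        )

    @property
    def extent_km(self) -> tuple[float, float]:
        return (self.grid_nx * self.cell_size_km, self.grid_ny * self.cell_size_km)


# ---------------------------------------------------------------------------
# Gaussian random fields (circulant embedding)
# ---------------------------------------------------------------------------

def simulate_gaussian_field(
    nx: int,
    ny: int,
    cell_size_km: float,
    model: VariogramModel,
    rng: np.random.Generator | int | None = None,
) -> RasterField:
    """Stationary Gaussian field on the grid with the given variogram.

    The structured component is simulated by circulant embedding on a torus
    twice the grid size (negative embedding eigenvalues, rare at these
    range/extent ratios, are clipped); the nugget is added as white noise.
    The empirical variogram of the output converges to the model as the grid
    grows.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    vals = np.zeros((ny, nx))
    if model.partial_sill > 0:
        my, mx = 2 * ny, 2 * nx
        iy = np.minimum(np.arange(my), my - np.arange(my))
        ix = np.minimum(np.arange(mx), mx - np.arange(mx))
        H = np.hypot(iy[:, None] * cell_size_km, ix[None, :] * cell_size_km)
        base = model.partial_sill * model.correlation(H)
        lam = np.clip(np.fft.fft2(base).real, 0.0, None)
        w = rng.standard_normal((my, mx)) + 1j * rng.standard_normal((my, mx))
        X = np.fft.fft2(np.sqrt(lam) * w) / np.sqrt(mx * my)
        vals += X.real[:ny, :nx] / np.sqrt(2.0) * np.sqrt(2.0)  # unit-variance parts
    if model.nugget > 0:
        vals += np.sqrt(model.nugget) * rng.standard_normal((ny, nx))
    return RasterField(vals, cell_size_km=cell_size_km)


def _smooth_field(config: ScenarioConfig, rng, range_km: float = 30.0,
                  sill: float = 1.0) -> np.ndarray:
    m = VariogramModel("spherical", 0.0, sill, range_km)
    return simulate_gaussian_field(
        config.grid_nx, config.grid_ny, config.cell_size_km, m, rng
    ).values


# ---------------------------------------------------------------------------
# Water panel + distribution network
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / (s if s > 0 else 1.0)


def simulate_water_panel(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Censored multi-substance water panel + distribution network.

    Latent log-concentrations follow a factor model: a common component
    (unit random effect + smooth time trend + shared noise, total share
    ``common_factor_share``) plus a residual MVN whose correlations are set
    so the *total* cross-substance correlation equals the configured matrix.
    Sampling dates are a homogeneous point process per unit (no
    periodicity).  Values under the substance's DL are flagged censored and
    stored at the DL.

    Returns (panel, network, municipality seeds).
    """
    if config.n_substances < 2:
        raise ValueError("need at least two substances")
    seed = config.seed if seed is None else seed
    rng = substream(seed, "water")
    R = config.correlation_matrix()
    lam = config.common_factor_share
    off = R[~np.eye(config.n_substances, dtype=bool)]
    if off.size and lam > off.min():
        lam = max(float(off.min()), 0.0)  # keep the residual correlations valid
    p = config.n_substances
    R_res = np.eye(p)
    if lam < 1.0:
        R_res = (R - lam * (np.ones((p, p)) - np.eye(p)) - lam * np.eye(p)) / (1 - lam)
        np.fill_diagonal(R_res, 1.0)
    wmin = np.linalg.eigvalsh(R_res).min()
    if wmin < -1e-10:
        raise ValueError("infeasible correlation matrix given the common-factor share")
    L = np.linalg.cholesky(R_res + np.eye(p) * max(0.0, -wmin + 1e-12))

    t0, t1 = pd.Timestamp(config.date_window[0]), pd.Timestamp(config.date_window[1])
    span = (t1 - t0).days

    unit_eff = rng.standard_normal(config.n_units)
    rows = []
    for u in range(config.n_units):
        n_obs = max(1, rng.poisson(config.mean_obs_per_unit))
        days = np.sort(rng.uniform(0, span, n_obs))
        rows.append((u, days))

    all_u = np.concatenate([np.full(len(d), u) for u, d in rows]).astype(int)
    all_days = np.concatenate([d for _, d in rows])
    n = all_days.size
    uu = all_days / span
    trend = np.sin(2 * np.pi * 1.5 * uu) + (uu - 0.5)
    # common factor: unit effect + time trend + shared record noise, unit variance
    g = (np.sqrt(0.45) * unit_eff[all_u]
         + np.sqrt(0.35) * _standardize(trend)
         + np.sqrt(0.20) * rng.standard_normal(n))
    e = rng.standard_normal((n, p)) @ L.T
    z = np.sqrt(lam) * g[:, None] + np.sqrt(1 - lam) * e
    logv = config.water_log_mu + config.water_log_sigma * z
    values = np.exp(logv)

    substances = config.substances()
    if config.detection_limits is not None:
        dls = np.array([config.detection_limits[s] for s in substances])
    elif config.censoring_target > 0:
        q = norm.ppf(config.censoring_target)
        dls = np.exp(config.water_log_mu + config.water_log_sigma * q) * np.ones(p)
    else:
        dls = np.full(p, 1e-12)  # nothing will fall below

    dates = (t0 + pd.to_timedelta(np.floor(all_days), unit="D")).strftime("%Y-%m-%d")
    recs = []
    for j, s in enumerate(substances):
        cens = (values[:, j] < dls[j]) & (config.censoring_target > 0)
        recs.append(pd.DataFrame({
            "unit_id": [f"U{u:04d}" for u in all_u],
            "date": dates,
            "substance": s,
            "value": np.where(cens, dls[j], values[:, j]),
            "censored": cens,
            "dl": dls[j],
        }))
    panel = pd.concat(recs, ignore_index=True)

    # municipalities: random seeds on the grid, each served by 1-2 units
    mrng = substream(seed, "network")
    ex, ey = config.extent_km
    seeds_df = pd.DataFrame({
        "municipality_id": [f"M{i:04d}" for i in range(config.n_municipalities)],
        "x_km": mrng.uniform(0, ex, config.n_municipalities),
        "y_km": mrng.uniform(0, ey, config.n_municipalities),
    })
    links = []
    # guarantee every unit serves someone: round-robin primary assignment
    primaries = mrng.permutation(config.n_units)
    for i, mid in enumerate(seeds_df["municipality_id"]):
        pop = float(np.round(mrng.lognormal(7.0, 1.0)))
        u1 = int(primaries[i % config.n_units])
        if mrng.random() < 0.3:
            u2 = int(mrng.integers(config.n_units))
            if u2 != u1:
                share = mrng.uniform(0.2, 0.8)
                links.append((f"U{u1:04d}", mid, round(pop * share)))
                links.append((f"U{u2:04d}", mid, round(pop * (1 - share))))
                continue
        links.append((f"U{u1:04d}", mid, pop))
    network = pd.DataFrame(links, columns=["unit_id", "municipality_id", "served_population"])
    return panel, network, seeds_df


# ---------------------------------------------------------------------------
# Soil survey
# ---------------------------------------------------------------------------

def simulate_soil_survey(
    config: ScenarioConfig,
    seed: int | None = None,
    n_covariates: int = 14,
    n_informative: int = 3,
    site_decay_radius_km: float = 3.0,
    site_amplitude: float = 1.0,
    covariate_link: str = "threshold",
    base_level: float = -3.7,  # exp(-3.7) ~ 0.025 mg/kg median topsoil level
) -> tuple[pd.DataFrame, dict[str, RasterField], np.ndarray, RasterField]:
    """Regular coarse soil survey over a covariate-driven censored field.

    The latent log-concentration is a nonlinear function of the first
    ``n_informative`` covariates — the third enters through
    ``covariate_link``: "threshold" (max(c, 0), mildly nonlinear) or "abs"
    (|c|, non-monotone, invisible to a linear trend) — plus an
    inverse-distance contribution from
    each polluted site inside ``site_decay_radius_km``, plus a spatially
    correlated residual.  The survey samples every ``soil_spacing_cells``-th
    cell; values under the DL (set at the ``soil_censoring_target`` quantile
    of the field) are censored.

    Returns (observations frame, covariate rasters, polluted site coords,
    true latent concentration raster).
    """
    seed = config.seed if seed is None else seed
    rng = substream(seed, "soil")
    tmpl = config.template()
    gx, gy = tmpl.cell_centers()
    ex, ey = config.extent_km

    covs = {}
    for k in range(n_covariates):
        covs[f"cov{k:02d}"] = tmpl.copy_with(_smooth_field(config, rng, range_km=30.0))

    sites = np.column_stack([
        rng.uniform(0, ex, config.n_polluted_sites),
        rng.uniform(0, ey, config.n_polluted_sites),
    ]) if config.n_polluted_sites > 0 else np.empty((0, 2))

    c = [covs[f"cov{k:02d}"].values.ravel() for k in range(max(n_informative, 1))]
    latent = base_level + 0.8 * c[0]
    if n_informative >= 2:
        latent = latent + 0.6 * c[1]
    if n_informative >= 3:
        if covariate_link == "threshold":
            latent = latent + 0.9 * np.maximum(c[2], 0.0)
        elif covariate_link == "abs":
            latent = latent + 1.2 * np.abs(c[2])
        else:
            raise ValueError(f"unknown covariate link {covariate_link!r}")
    proxy = build_source_proxy(sites, gx, gy, site_decay_radius_km,
                               d_min_km=config.cell_size_km / 2.0)
    latent = latent + site_amplitude * proxy
    resid = simulate_gaussian_field(
        config.grid_nx, config.grid_ny, config.cell_size_km,
        config.soil_variogram, rng,
    ).values.ravel()
    latent = latent + resid
    conc = np.exp(latent)
    truth = tmpl.copy_with(conc.reshape(tmpl.shape))

    s = config.soil_spacing_cells
    jj, ii = np.meshgrid(np.arange(s // 2, config.grid_ny, s),
                         np.arange(s // 2, config.grid_nx, s), indexing="ij")
    jj, ii = jj.ravel(), ii.ravel()
    ox = (ii + 0.5) * config.cell_size_km
    oy = (jj + 0.5) * config.cell_size_km
    ovals = conc.reshape(tmpl.shape)[jj, ii]
    dl = float(np.quantile(conc, config.soil_censoring_target)) \
        if config.soil_censoring_target > 0 else 0.0
    cens = ovals < dl
    obs = pd.DataFrame({
        "id": [f"P{k:04d}" for k in range(len(ox))],
        "x_km": ox, "y_km": oy,
        "value": np.where(cens, dl, ovals),
        "censored": cens,
        "dl": dl if dl > 0 else 1e-12,
    })
    return obs, covs, sites, truth


# ---------------------------------------------------------------------------
# Air year
# ---------------------------------------------------------------------------

STATION_TYPES = ("rural_background", "suburban_background", "urban_background",
                 "urban_traffic", "industrial")


def simulate_air_year(
    config: ScenarioConfig,
    year_effect: float = 1.0,
    seed: int | None = None,
    emission_coef: float = 0.4,
    altitude_coef: float = 0.5,
    population_coef: float = 0.2,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, RasterField, RasterField, RasterField]:
    """One year of station annual means plus emission/altitude/population rasters.

    Station means are an additive function of the (standardized) emission
    proxy, altitude — toggled by ``year_effect`` to emulate the cold-winter /
    mild-winter contrast between consecutive years — and population, plus a
    spatially correlated residual and measurement noise.  The altitude field
    is independent of the emission and population fields, so with
    ``year_effect=0`` the station-altitude correlation vanishes.

    Returns (stations frame, emission raster, altitude raster, population
    raster); values in ng/m^3.
    """
    if config.n_stations < 10:
        raise ValueError("need at least 10 stations")
    seed = config.seed if seed is None else seed
    rng = substream(seed, "air_fields")
    tmpl = config.template()

    emission = tmpl.copy_with(np.exp(1.0 + 1.2 * _smooth_field(config, rng, range_km=25.0)))
    alt_raw = _smooth_field(config, rng, range_km=45.0)
    altitude = tmpl.copy_with(np.clip(900.0 + 700.0 * alt_raw, 0.0, None))
    population = tmpl.copy_with(np.round(np.exp(5.0 + 1.5 * _smooth_field(config, rng, range_km=20.0))))

    srng = substream(seed, f"air_stations_{year_effect}")
    ncell = config.grid_nx * config.grid_ny
    cells = srng.choice(ncell, size=config.n_stations, replace=False)
    gx, gy = tmpl.cell_centers()
    sx, sy = gx[cells], gy[cells]
    # jitter stations off cell centres (metres-scale siting noise)
    sx = sx + srng.uniform(-0.3, 0.3, config.n_stations)
    sy = sy + srng.uniform(-0.3, 0.3, config.n_stations)

    proxy = build_emission_proxy(emission, sx, sy, radius_km=20.0)
    alt_s = altitude.sample(sx, sy)
    pop_s = population.sample(sx, sy)

    resid_field = simulate_gaussian_field(
        config.grid_nx, config.grid_ny, config.cell_size_km,
        config.air_residual_variogram, srng,
    )
    resid = resid_field.sample(sx, sy)

    value = (0.6
             + emission_coef * _standardize(proxy)
             + year_effect * altitude_coef * _standardize(alt_s)
             + population_coef * _standardize(np.log1p(pop_s))
             + resid
             + noise_sd * srng.standard_normal(config.n_stations))
    value = np.clip(value, 0.01, None)

    types = srng.choice(STATION_TYPES, size=config.n_stations)
    stations = pd.DataFrame({
        "id": [f"A{k:03d}" for k in range(config.n_stations)],
        "x_km": sx, "y_km": sy,
        "value": value,
        "censored": False,
        "dl": 1e-6,
        "station_type": types,
    })
    return stations, emission, altitude, population


def validation_panel_config(seed: int, n_units: int = 200) -> ScenarioConfig:
    """Config for the imputation-validation panel (arsenic-with-selenium style).

    A complete (uncensored) two-substance panel in ug/L whose marginal is
    calibrated so that DL thresholds of 3 and 5 ug/L censor ~82% and ~88% of
    records; 200 units over the 13-year window give ~5000 records per
    substance.
    """
    return ScenarioConfig(
        seed=seed, n_units=n_units, censoring_target=0.0,
        water_log_mu=VALIDATION_LOG_MU, water_log_sigma=VALIDATION_LOG_SIGMA,
    )


def make_receptors(config: ScenarioConfig | None = None) -> list[ReceptorProfile]:
    """Two age-class receptor profiles (0-17 and 17-70, durations sum to 70 y)."""
    return default_receptors()
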