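"""Ambient-air concentration mapping from a sparse station network.

With under a hundred monitoring stations nationally, ordinary kriging alone
misrepresents the concentration field; the map therefore leans on auxiliary
variables: an emission proxy (inventory emissions aggregated within a 20 km
buffer around each location, weighted by inverse distance), altitude and
population.  A linear drift on the selected terms is followed by kriging of
the residuals with an exponential variogram; term sets are compared by
leave-one-out ME/RMSE (overall and per station type).  Annual maps are
combined across years by inverse-RMSE^2 weights, and a validity mask flags
high-altitude, quasi-unpopulated cells where the statistical model has no
support (altitude > 1800 m and density < 30 persons/km^2).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import RasterField
from .kriging import ObservationSet, loocv_residual, residual_krige

DEFAULT_TERMS = ("emission_proxy", "altitude", "population")
ALTITUDE_LIMIT_M = 1800.0
DENSITY_LIMIT_PER_KM2 = 30.0


def build_emission_proxy(
    emissions: RasterField,
    loc_x: np.ndarray,
    loc_y: np.ndarray,
    radius_km: float = 20.0,
    d_min_km: float | None = None,
) -> np.ndarray:
    """Distance-weighted aggregation of emissions within a buffer.

    proxy(x) = sum over emission cells whose centroid lies within
    ``radius_km`` of emission * 1/max(d, d_min).  The cell-location
    neighbourhood is built once with a KD-tree and reused.  Locations with an
    empty buffer get proxy 0 with a warning.
    """
    if d_min_km is None:
        d_min_km = emissions.cell_size_km / 2.0
    cx, cy = emissions.cell_centers()
    em = emissions.values.ravel()
    tree = cKDTree(np.column_stack([cx, cy]))
    loc = np.column_stack([np.asarray(loc_x, float), np.asarray(loc_y, float)])
    neighbours = tree.query_ball_point(loc, r=radius_km)
    out = np.zeros(loc.shape[0])
    empty = 0
    for i, idx in enumerate(neighbours):
        if not idx:
            empty += 1
            continue
        d = np.linalg.norm(np.column_stack([cx[idx], cy[idx]]) - loc[i], axis=1)
        out[i] = np.sum(em[idx] / np.maximum(d, d_min_km))
    if empty:
        warnings.warn(f"{empty} locations had no emission cell within {radius_km} km")
    return out


@dataclasses.dataclass
class DriftModel:
    terms: list[str]
    coefficients: np.ndarray  # intercept first
    loocv: dict
    candidates: pd.DataFrame

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(covariates))] + [covariates[t].to_numpy(float) for t in self.terms]
        )
        return X @ self.coefficients


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def fit_drift(
    obs: ObservationSet,
    covariates: pd.DataFrame,
    include_terms=DEFAULT_TERMS,
    family: str = "exponential",
) -> DriftModel:
    """Select the drift term set by LOOCV of the full regression-kriging step.

    Every subset of ``include_terms`` (including the intercept-only model) is
    scored by leave-one-out RMSE of residual kriging with that drift; the
    subset with the lowest RMSE wins, ties going to the smaller model.
    Collinear terms are dropped with a warning before enumeration.
    """
    terms = [t for t in include_terms if t in covariates.columns]
    if len(terms) < len(include_terms):
        missing = set(include_terms) - set(terms)
        raise ValueError(f"covariates missing requested terms {missing}")
    # drop collinear columns
    keep = []
    for t in terms:
        cand = keep + [t]
        X = covariates[cand].to_numpy(float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) == len(cand) + 1:
            keep.append(t)
        else:
            warnings.warn(f"term {t!r} collinear with previous terms; dropped")
    terms = keep

    rows = []
    best = None
    for k in range(0, len(terms) + 1):
        for subset in itertools.combinations(terms, k):
            subset = list(subset)
            if subset:
                cv = loocv_residual(
                    obs, covariates[subset].to_numpy(float),
                    trend_fitter="linear", family=family,
                )
            else:
                cv = _loocv_constant(obs, family)
            row = {"terms": tuple(subset), "k": k,
                   "me": cv["me"], "rmse": cv["rmse"]}
            rows.append(row)
            if best is None or (row["rmse"], row["k"]) < (best[0]["rmse"], best[0]["k"]):
                best = (row, cv)
    table = pd.DataFrame(rows)
    chosen, cv = best
    subset = list(chosen["terms"])
    X = np.column_stack(
        [np.ones(len(obs))] + [covariates[t].to_numpy(float) for t in subset]
    )
    beta = _ols(obs.values, X)
    return DriftModel(terms=subset, coefficients=beta, loocv=cv, candidates=table)


def _loocv_constant(obs: ObservationSet, family: str) -> dict:
    const = np.ones((len(obs), 1))
    return loocv_residual(obs, const, trend_fitter="linear", family=family)


@dataclasses.dataclass
class AirMapResult:
    raster: RasterField
    drift: DriftModel
    loocv: dict
    residual_model: object


def map_air_year(
    obs: ObservationSet,
    drift: DriftModel,
    cell_covariates: pd.DataFrame,
    obs_covariates: pd.DataFrame,
    template: RasterField,
    family: str = "exponential",
) -> AirMapResult:
    """Regression kriging of one year's annual means onto the grid."""
    gx, gy = template.cell_centers()
    if drift.terms:
        Xo = obs_covariates[drift.terms].to_numpy(float)
        Xc = cell_covariates[drift.terms].to_numpy(float)
    else:
        Xo = np.ones((len(obs), 1))
        Xc = np.ones((len(gx), 1))
    pred, diag = residual_krige(
        obs, Xo, Xc, gx, gy, trend_fitter="linear", family=family
    )
    raster = template.copy_with(
        np.clip(pred, 0.0, None).reshape(template.shape),
        mask_missing=np.zeros(template.shape, bool),
        mask_invalid=np.zeros(template.shape, bool),
    )
    return AirMapResult(
        raster=raster, drift=drift, loocv=drift.loocv,
        residual_model=diag["residual_model"],
    )


def combine_years(maps: list[RasterField], rmse_per_year: list[float]) -> RasterField:
    """Accuracy-weighted multi-year mean: w_y proportional to 1/RMSE_y^2."""
    if len(maps) != len(rmse_per_year) or not maps:
        raise ValueError("one RMSE per map required")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape or m.cell_size_km != maps[0].cell_size_km:
            raise ValueError("mismatched grids")
    rmse = np.asarray(rmse_per_year, float)
    if np.any(rmse <= 0):
        raise ValueError("RMSEs must be positive")
    w = 1.0 / rmse**2
    w = w / w.sum()
    vals = sum(wi * m.values for wi, m in zip(w, maps))
    invalid = np.zeros(shape, bool)
    missing = np.zeros(shape, bool)
    for m in maps:
        invalid |= m.mask_invalid
        missing |= m.mask_missing
    return RasterField(
        vals, cell_size_km=maps[0].cell_size_km, origin=maps[0].origin,
        mask_missing=missing, mask_invalid=invalid,
    )


def validity_mask(
    altitude: RasterField, population: RasterField
) -> np.ndarray:
    """Cells where the air model is not relevant: high and quasi-unpopulated.

    A cell is invalid iff altitude > 1800 m AND population density
    < 30 persons/km^2.  Population density is the population raster divided
    by the cell area.
    """
    if altitude.shape != population.shape:
        raise ValueError("altitude and population rasters must be aligned")
    area = population.cell_size_km**2
    density = population.values / area
    return (altitude.values > ALTITUDE_LIMIT_M) & (density < DENSITY_LIMIT_PER_KM2)
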