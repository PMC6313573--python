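"""Topsoil concentration mapping with auxiliary variables.

The soil map combines three kinds of information: the probability of a
measurement exceeding the detection limit (indicator kriging of the
censoring flags), a source proxy built from the inventory of polluted sites
(inverse distance summed within a buffer whose radius is selected by AIC),
and a stack of exhaustive soil-property covariates.  A random-forest trend
captures nonlinear covariate links; its residuals are kriged with a
spherical variogram.  Covariates are selected by backward elimination on
random-forest permutation importance, keeping the subset with the lowest
out-of-bag (OOB) mean squared error.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .grids import RasterField
from .kriging import (
    ObservationSet,
    RandomForestTrend,
    indicator_krige,
    loocv_residual,
    residual_krige,
)


def build_source_proxy(
    sites_xy: np.ndarray,
    loc_x: np.ndarray,
    loc_y: np.ndarray,
    radius_km: float,
    d_min_km: float = 1.5,
) -> np.ndarray:
    """Inverse-distance source proxy (km^-1), zero outside every buffer.

    proxy(x) = sum over polluted sites within ``radius_km`` of
    1 / max(d, d_min); ``d_min`` (half a cell width by default) floors the
    singularity when a location sits on a site.
    """
    if radius_km <= 0:
        raise ValueError("buffer radius must be positive")
    loc = np.column_stack([np.asarray(loc_x, float), np.asarray(loc_y, float)])
    out = np.zeros(loc.shape[0])
    sites_xy = np.atleast_2d(np.asarray(sites_xy, float))
    if sites_xy.size == 0:
        return out
    tree = cKDTree(sites_xy)
    pairs = tree.query_ball_point(loc, r=radius_km)
    for i, idx in enumerate(pairs):
        if idx:
            d = np.linalg.norm(sites_xy[idx] - loc[i], axis=1)
            out[i] = np.sum(1.0 / np.maximum(d, d_min_km))
    return out


def select_buffer_radius(
    candidate_radii,
    obs: ObservationSet,
    sites_xy: np.ndarray,
    extra_covariates: np.ndarray | None = None,
    d_min_km: float = 1.5,
) -> tuple[float, pd.DataFrame]:
    """Pick the buffer radius whose proxy best explains the observations (AIC).

    For each candidate radius a Gaussian-likelihood linear regression of the
    observed concentration on the proxy (plus any extra covariates) is fit;
    the radius minimizing AIC wins, ties going to the smaller radius.
    Radii whose proxy is identically zero are skipped with a warning.
    The AIC is computed on the linear auxiliary regression — a random forest
    has no likelihood to base an information criterion on.
    """
    radii = sorted(set(float(r) for r in candidate_radii))
    if len(radii) < 1:
        raise ValueError("no candidate radii")
    rows = []
    for r in radii:
        proxy = build_source_proxy(sites_xy, obs.x, obs.y, r, d_min_km=d_min_km)
        if np.allclose(proxy, 0.0):
            warnings.warn(f"proxy identically zero at radius {r}; candidate skipped")
            continue
        X = proxy[:, None]
        if extra_covariates is not None:
            X = np.column_stack([X, np.atleast_2d(extra_covariates.T).T])
        fit = sm.OLS(obs.values, sm.add_constant(X)).fit()
        rows.append({"radius_km": r, "aic": float(fit.aic)})
    if not rows:
        raise ValueError("all candidate radii produced degenerate proxies")
    table = pd.DataFrame(rows)
    # sorted radii ascending + stable idxmin => ties resolve to the smaller radius
    best = float(table.loc[table["aic"].idxmin(), "radius_km"])
    return best, table


def select_covariates_oob(
    obs_values: np.ndarray,
    covariates: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 500,
    n_permutation_repeats: int = 5,
) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination on permutation importance, scored by OOB MSE.

    Starting from the full candidate stack, the least important covariate
    (random-forest permutation importance) is dropped and the forest refit;
    the subset with the smallest OOB mean squared error is returned.
    Deterministic under a fixed seed.
    """
    if covariates.shape[1] < 1:
        raise ValueError("need at least one candidate covariate")
    y = np.asarray(obs_values, float)
    current = list(covariates.columns)
    history = []
    best_subset, best_mse = None, np.inf
    step = 0
    while current:
        rf = RandomForestRegressor(
            n_estimators=n_estimators, oob_score=True, random_state=seed,
            n_jobs=1, bootstrap=True,
        )
        X = covariates[current].to_numpy(float)
        rf.fit(X, y)
        oob_mse = float(np.mean((rf.oob_prediction_ - y) ** 2))
        history.append({"step": step, "subset": tuple(current), "oob_mse": oob_mse})
        if oob_mse < best_mse:
            best_mse, best_subset = oob_mse, list(current)
        if len(current) == 1:
            break
        imp = permutation_importance(
            rf, X, y, n_repeats=n_permutation_repeats,
            random_state=seed, n_jobs=1,
        ).importances_mean
        current = [c for i, c in enumerate(current) if i != int(np.argmin(imp))]
        step += 1
    return best_subset, pd.DataFrame(history)


@dataclasses.dataclass
class SoilMapResult:
    raster: RasterField
    probability: RasterField
    proxy_radius_km: float
    selected_covariates: list[str]
    loocv: dict
    diagnostics: dict


def map_soil(
    obs: ObservationSet,
    covariate_rasters: dict[str, RasterField],
    sites_xy: np.ndarray,
    template: RasterField,
    candidate_radii=(1.0, 2.0, 3.0, 5.0, 10.0),
    seed: int = 0,
    rf_trees: int = 300,
    run_loocv: bool = True,
    select_covariates: bool = True,
) -> SoilMapResult:
    """End-to-end soil pipeline on the reference grid.

    Steps: indicator kriging of the censoring flags -> exceedance-probability
    covariate; AIC buffer selection and source proxy; OOB covariate
    selection over {probability, proxy, soil covariates}; random-forest
    trend + spherical residual kriging.  Censored observations enter the
    value model at DL/2 — the probability covariate is how the censoring
    information itself reaches the map.  Output clipped at zero.
    """
    gx, gy = template.cell_centers()

    prob_cells, _ = indicator_krige(obs, gx, gy)
    prob_raster = template.copy_with(
        prob_cells.reshape(template.shape),
        mask_missing=np.zeros(template.shape, bool),
        mask_invalid=np.zeros(template.shape, bool),
    )
    prob_obs, _ = indicator_krige(obs, obs.x, obs.y)

    # censored observations enter the value models at DL/2
    values = obs.values.copy()
    values[obs.censored] = values[obs.censored] / 2.0

    # AIC auxiliary regression runs on log concentration (Gaussian likelihood
    # on right-skewed positive data), with the covariate stack absorbing the
    # regional trend so the proxy term only has to explain the hotspots
    cov_obs_extra = np.column_stack(
        [r.sample(obs.x, obs.y) for r in covariate_rasters.values()]
    ) if covariate_rasters else None
    log_obs = ObservationSet(obs.x, obs.y, np.log(np.maximum(values, 1e-12)))
    radius, aic_table = select_buffer_radius(
        candidate_radii, log_obs, sites_xy, extra_covariates=cov_obs_extra,
        d_min_km=template.cell_size_km / 2.0,
    )
    proxy_obs = build_source_proxy(sites_xy, obs.x, obs.y, radius,
                                   d_min_km=template.cell_size_km / 2.0)
    proxy_cells = build_source_proxy(sites_xy, gx, gy, radius,
                                     d_min_km=template.cell_size_km / 2.0)

    stack_obs = {"probability": prob_obs, "source_proxy": proxy_obs}
    stack_cells = {"probability": prob_cells, "source_proxy": proxy_cells}
    for name, r in covariate_rasters.items():
        stack_obs[name] = r.sample(obs.x, obs.y)
        stack_cells[name] = r.values.ravel()
    cov_obs_df = pd.DataFrame(stack_obs)
    vobs = ObservationSet(obs.x, obs.y, values, station_type=obs.station_type)

    if select_covariates and cov_obs_df.shape[1] > 1:
        selected, oob_history = select_covariates_oob(
            vobs.values, cov_obs_df, seed=seed, n_estimators=rf_trees
        )
    else:
        selected = list(cov_obs_df.columns)
        oob_history = pd.DataFrame()

    Xo = cov_obs_df[selected].to_numpy(float)
    Xc = np.column_stack([stack_cells[c] for c in selected])
    trend = RandomForestTrend(n_estimators=rf_trees, seed=seed)
    pred, diag = residual_krige(
        vobs, Xo, Xc, gx, gy, trend_fitter=trend, family="spherical"
    )
    raster = template.copy_with(
        np.clip(pred, 0.0, None).reshape(template.shape),
        mask_missing=np.zeros(template.shape, bool),
        mask_invalid=np.zeros(template.shape, bool),
    )

    cv = {}
    if run_loocv:
        cv = loocv_residual(
            vobs, Xo, trend_fitter=RandomForestTrend(n_estimators=rf_trees, seed=seed),
            family="spherical",
        )
    return SoilMapResult(
        raster=raster,
        probability=prob_raster,
        proxy_radius_km=radius,
        selected_covariates=selected,
        loocv=cv,
        diagnostics={"aic_table": aic_table, "oob_history": oob_history,
                     "residual_model": diag["residual_model"]},
    )
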