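"""Ordinary, indicator and residual (regression) kriging, plus LOOCV.

All kriging is global-neighbourhood: every observation enters every system.
The synthetic scenarios stay small enough (<~2000 points) that this removes
search-neighbourhood tuning entirely.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .variogram import VariogramModel, fit_empirical, pairwise_distances


@dataclasses.dataclass
class ObservationSet:
    """Georeferenced point measurements (coordinates in km).

    Duplicate coordinates are averaged on construction (with a warning):
    kriging systems need distinct support points.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    censored: np.ndarray | None = None
    station_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.values = np.asarray(self.values, float)
        n = self.x.size
        if not (self.y.size == n and self.values.size == n):
            raise ValueError("coordinate/value length mismatch")
        if self.censored is None:
            self.censored = np.zeros(n, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if self.station_type is not None:
            self.station_type = np.asarray(self.station_type)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite observation values")
        self._dedupe()

    def _dedupe(self) -> None:
        coords = np.round(np.column_stack([self.x, self.y]), 9)
        _, first, inv, counts = np.unique(
            coords, axis=0, return_index=True, return_inverse=True, return_counts=True
        )
        if np.any(counts > 1):
            warnings.warn("duplicate coordinates averaged before kriging")
            vals = np.bincount(inv, weights=self.values) / counts
            self.x = coords[first, 0]
            self.y = coords[first, 1]
            self.values = vals
            self.censored = self.censored[first]
            if self.station_type is not None:
                self.station_type = self.station_type[first]

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "value") -> "ObservationSet":
        return cls(
            x=df["x_km"].to_numpy(),
            y=df["y_km"].to_numpy(),
            values=df[value_col].to_numpy(),
            censored=df["censored"].to_numpy() if "censored" in df else None,
            station_type=df["station_type"].to_numpy() if "station_type" in df else None,
        )


def ordinary_krige(
    obs: ObservationSet,
    model: VariogramModel,
    target_x: np.ndarray,
    target_y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging BLUP at target points.

    Solves the semivariance form of the kriging system with the Lagrange
    multiplier enforcing that weights sum to one.  Returns (predictions,
    kriging variance); the variance is clipped at zero against round-off.
    With a zero nugget the predictor interpolates exactly at data points.
    """
    n = len(obs)
    if n == 0:
        raise ValueError("no observations")
    tx = np.atleast_1d(np.asarray(target_x, float))
    ty = np.atleast_1d(np.asarray(target_y, float))
    if n == 1:
        return np.full(tx.size, obs.values[0]), np.full(tx.size, model.sill)

    D = pairwise_distances(obs.x, obs.y)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model(D)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0

    d0 = cdist(np.column_stack([obs.x, obs.y]), np.column_stack([tx, ty]))
    B = np.empty((n + 1, tx.size))
    B[:n] = model(d0)
    B[n] = 1.0

    try:
        W = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        A[:n, :n] += np.eye(n) * 1e-10 * max(model.sill, 1.0)
        W = np.linalg.solve(A, B)

    pred = W[:n].T @ obs.values
    var = np.einsum("it,it->t", W[:n], B[:n]) + W[n]
    return pred, np.clip(var, 0.0, None)


def indicator_krige(
    obs: ObservationSet,
    target_x: np.ndarray,
    target_y: np.ndarray,
    model: VariogramModel | None = None,
    family: str = "spherical",
) -> tuple[np.ndarray, np.ndarray]:
    """Probability of exceeding the detection limit by kriging of indicators.

    Each observation is coded 1 if it exceeds the detection limit (i.e. is
    not censored), 0 otherwise; the indicator field is ordinary-kriged and
    clipped to [0, 1].  If the variogram is not supplied it is fitted on the
    indicators.  Single-class inputs yield a constant surface with a warning.
    """
    ind = (~obs.censored).astype(float)
    tx = np.atleast_1d(np.asarray(target_x, float))
    if ind.min() == ind.max():
        warnings.warn("indicator kriging input has a single class; constant surface")
        p = np.full(tx.size, float(ind[0]))
        return p, np.zeros(tx.size)
    iobs = ObservationSet(obs.x, obs.y, ind)
    if model is None:
        model = fit_empirical(iobs.x, iobs.y, iobs.values, family=family)
    pred, var = ordinary_krige(iobs, model, target_x, target_y)
    return np.clip(pred, 0.0, 1.0), var


class LinearTrend:
    """Ordinary least squares trend for residual kriging."""

    def __init__(self) -> None:
        self._m = LinearRegression()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearTrend":
        self._m.fit(np.atleast_2d(X), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._m.predict(np.atleast_2d(X))


class RandomForestTrend:
    """Random-forest trend; captures nonlinear covariate links.

    500 trees by default; the forest is seeded so the whole mapping pipeline
    is reproducible.
    """

    def __init__(self, n_estimators: int = 500, seed: int | None = 0, **kw) -> None:
        self._m = RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, **kw
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestTrend":
        self._m.fit(np.atleast_2d(X), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._m.predict(np.atleast_2d(X))


def make_trend(kind) -> object:
    if kind == "linear":
        return LinearTrend()
    if kind == "random_forest":
        return RandomForestTrend()
    if hasattr(kind, "fit") and hasattr(kind, "predict"):
        return kind
    raise ValueError(f"unknown trend fitter {kind!r}")


def residual_krige(
    obs: ObservationSet,
    cov_obs: np.ndarray,
    cov_targets: np.ndarray,
    target_x: np.ndarray,
    target_y: np.ndarray,
    trend_fitter="linear",
    family: str = "spherical",
    residual_model: VariogramModel | None = None,
) -> tuple[np.ndarray, dict]:
    """Regression (residual) kriging: trend on covariates + kriged residual.

    Returns predictions and a diagnostics dict containing the fitted trend,
    the residual variogram and residual values.  With a constant covariate
    column the trend collapses to a constant and the output matches ordinary
    kriging up to the fitted mean.
    """
    cov_obs = np.atleast_2d(np.asarray(cov_obs, float))
    if cov_obs.shape[0] != len(obs):
        cov_obs = cov_obs.T
    cov_targets = np.atleast_2d(np.asarray(cov_targets, float))
    if cov_targets.shape[1] != cov_obs.shape[1]:
        cov_targets = cov_targets.T

    trend = make_trend(trend_fitter)
    trend.fit(cov_obs, obs.values)
    resid = obs.values - trend.predict(cov_obs)
    if residual_model is None:
        if np.allclose(resid, resid[0]):
            residual_model = VariogramModel(family, 0.0, 0.0, 1.0)
        else:
            residual_model = fit_empirical(obs.x, obs.y, resid, family=family)
    robs = ObservationSet(obs.x, obs.y, resid)
    if residual_model.sill == 0:
        kr = np.zeros(np.atleast_1d(target_x).size)
        kv = np.zeros_like(kr)
    else:
        kr, kv = ordinary_krige(robs, residual_model, target_x, target_y)
    pred = trend.predict(cov_targets) + kr
    return pred, {
        "trend": trend,
        "residual_model": residual_model,
        "residuals": resid,
        "kriging_variance": kv,
    }


def loocv(
    obs: ObservationSet,
    predictor: Callable[[ObservationSet, np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    cov_obs: np.ndarray | None = None,
) -> dict:
    """Leave-one-out cross-validation of any point predictor.

    ``predictor(train_obs, train_cov, x0, y0) -> prediction`` is called once
    per held-out point (``train_cov`` is None when no covariates are passed).
    Reports ME = mean(pred - obs) and RMSE overall and per station type;
    folds where the predictor raises are skipped and counted.
    """
    n = len(obs)
    if n < 3:
        raise ValueError("LOOCV needs at least three observations")
    if cov_obs is not None:
        cov_obs = np.atleast_2d(np.asarray(cov_obs, float))
        if cov_obs.shape[0] != n:
            cov_obs = cov_obs.T
    preds = np.full(n, np.nan)
    failed = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        tr = ObservationSet(
            obs.x[keep], obs.y[keep], obs.values[keep],
            censored=obs.censored[keep],
            station_type=None if obs.station_type is None else obs.station_type[keep],
        )
        trc = None if cov_obs is None else cov_obs[keep]
        tgc = None if cov_obs is None else cov_obs[[i]]
        try:
            if cov_obs is None:
                preds[i] = np.atleast_1d(predictor(tr, None, obs.x[[i]], obs.y[[i]]))[0]
            else:
                preds[i] = np.atleast_1d(predictor(tr, trc, obs.x[[i]], obs.y[[i]], tgc))[0]
        except Exception:
            failed += 1
    ok = np.isfinite(preds)
    err = preds[ok] - obs.values[ok]
    out = {
        "me": float(np.mean(err)) if err.size else np.nan,
        "rmse": float(np.sqrt(np.mean(err**2))) if err.size else np.nan,
        "errors": preds - obs.values,
        "predictions": preds,
        "n_failed": failed,
    }
    if obs.station_type is not None:
        by = {}
        for t in np.unique(obs.station_type):
            sel = ok & (obs.station_type == t)
            e = preds[sel] - obs.values[sel]
            if e.size:
                by[str(t)] = {"me": float(e.mean()), "rmse": float(np.sqrt((e**2).mean()))}
        out["by_type"] = by
    return out


def loocv_ordinary(obs: ObservationSet, model: VariogramModel) -> dict:
    """LOOCV of ordinary kriging with a fixed (not refit) variogram."""
    def pred(tr, _cov, x0, y0):
        return ordinary_krige(tr, model, x0, y0)[0]
    return loocv(obs, pred)


def loocv_residual(
    obs: ObservationSet,
    cov_obs: np.ndarray,
    trend_fitter="linear",
    family: str = "spherical",
    refit_variogram: bool = False,
) -> dict:
    """LOOCV of residual kriging; the trend is refit on every fold.

    By default the residual variogram is fitted once on the full-data
    residuals and held fixed across folds, keeping folds comparable.
    """
    fixed = None
    if not refit_variogram:
        _, diag = residual_krige(
            obs, cov_obs, cov_obs, obs.x, obs.y, trend_fitter=trend_fitter, family=family
        )
        fixed = diag["residual_model"]

    def pred(tr, trc, x0, y0, tgc):
        p, _ = residual_krige(
            tr, trc, tgc, x0, y0, trend_fitter=trend_fitter,
            family=family, residual_model=fixed,
        )
        return p

    return loocv(obs, pred, cov_obs=cov_obs)
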