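"""Variogram models, the Matheron empirical estimator, and WLS fitting.

Two model families are supported, matching common practice for soil
(spherical) and air (exponential) concentration fields.  The range is the
*effective* range in km for both families: the spherical model reaches its
sill exactly at the range, the exponential reaches ~95% of it.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

FAMILIES = ("spherical", "exponential")


@dataclasses.dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram gamma(h) = nugget * 1{h>0} + psill * g(h/range)."""

    family: str
    nugget: float
    partial_sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be nonnegative")
        if self.range_km <= 0:
            raise ValueError("range must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def correlation(self, h: np.ndarray) -> np.ndarray:
        """Spatial correlation of the structured (non-nugget) component."""
        h = np.abs(np.asarray(h, dtype=float))
        u = h / self.range_km
        if self.family == "spherical":
            c = np.where(u < 1.0, 1.0 - 1.5 * u + 0.5 * u**3, 0.0)
        else:  # exponential with effective range = 3 * scale
            c = np.exp(-3.0 * u)
        return c

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        gamma = self.partial_sill * (1.0 - self.correlation(h))
        return np.where(h > 0, gamma + self.nugget, 0.0)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h) (nugget at h = 0)."""
        h = np.asarray(h, dtype=float)
        c = self.partial_sill * self.correlation(h)
        return np.where(h > 0, c, c + self.nugget)


def empirical_variogram(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    lag_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matheron estimator per half-open lag bin [a, b).

    Returns (lag centre-of-mass, semivariance, pair count) for bins with at
    least one pair; empty bins are omitted.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    values = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least two points")
    lag_edges = np.asarray(lag_edges, float)
    if np.any(np.diff(lag_edges) <= 0):
        raise ValueError("lag edges must be strictly increasing")
    d = pdist(np.column_stack([x, y]))
    if np.all(d == 0):
        raise ValueError("all points coincident")
    dz2 = pdist(values[:, None], metric="sqeuclidean")
    idx = np.digitize(d, lag_edges) - 1  # ties to the lower bin (half-open)
    nbin = len(lag_edges) - 1
    lags, gammas, counts = [], [], []
    for b in range(nbin):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        lags.append(d[sel].mean())
        gammas.append(0.5 * dz2[sel].mean())
        counts.append(n)
    return np.array(lags), np.array(gammas), np.array(counts)


def fit_variogram(
    lags: np.ndarray,
    gammas: np.ndarray,
    counts: np.ndarray | None = None,
    family: str = "spherical",
) -> VariogramModel:
    """Weighted least squares fit of (nugget, partial sill, range).

    Weights are pair counts (more pairs -> more trust in a bin).  Falls back
    to method-of-moments initial values if the optimizer fails to improve.
    """
    lags = np.asarray(lags, float)
    gammas = np.asarray(gammas, float)
    if lags.size < 3:
        raise ValueError("need at least three non-empty lag bins")
    if counts is None:
        counts = np.ones_like(lags)
    w = np.sqrt(np.asarray(counts, float))

    sill0 = max(float(np.mean(gammas[-max(2, lags.size // 3):])), 1e-12)
    nug0 = float(np.clip(gammas[0], 0.0, sill0))
    rng0 = float(lags[np.argmax(gammas >= 0.95 * sill0)] or lags[-1] / 2)
    rng0 = max(rng0, float(lags[0]), 1e-6)
    x0 = np.array([nug0, max(sill0 - nug0, 1e-12), rng0])

    def resid(p):
        m = VariogramModel(family, max(p[0], 0.0), max(p[1], 0.0), max(p[2], 1e-9))
        return w * (m(lags) - gammas)

    try:
        sol = least_squares(
            resid,
            x0,
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 10 * lags[-1]]),
            xtol=1e-12,
            ftol=1e-12,
        )
        p = sol.x
        if not sol.success or not np.all(np.isfinite(p)):
            raise RuntimeError("optimizer failed")
    except RuntimeError:
        warnings.warn("variogram WLS did not converge; using moment initial values")
        p = x0
    return VariogramModel(family, float(p[0]), float(p[1]), float(max(p[2], 1e-9)))


def fit_empirical(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    family: str = "spherical",
    n_lags: int = 15,
    max_lag: float | None = None,
) -> VariogramModel:
    """Convenience: empirical variogram + WLS fit in one call."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if max_lag is None:
        span = np.hypot(np.ptp(x), np.ptp(y))
        max_lag = span / 2.0
    edges = np.linspace(0, max_lag, n_lags + 1)
    edges[0] = 1e-9  # exclude zero-distance duplicates
    lags, gammas, counts = empirical_variogram(x, y, values, edges)
    return fit_variogram(lags, gammas, counts, family=family)


def pairwise_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.column_stack([np.asarray(x, float), np.asarray(y, float)])))
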