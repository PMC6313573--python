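"""Water pathway: temporal weighting, network aggregation, rasterization.

Distribution units are sampled at irregular dates over a multi-year window
(default 2000-01-01 .. 2012-12-31).  Each observation is weighted by the
"segments of influence" rule: midpoints are traced between neighbouring
sampling dates and each observation owns the days between its two flanking
midpoints (window edges for the first and last observation); its weight is
owned days / window days.  Unit means are aggregated to municipalities with
weights proportional to the population served by each unit in each
municipality, then georeferenced to the reference grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .censoring import ImputedPanelSet
from .grids import RasterField

DEFAULT_WINDOW = ("2000-01-01", "2012-12-31")

NETWORK_COLUMNS = ["unit_id", "municipality_id", "served_population"]


def validate_network(network: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in NETWORK_COLUMNS if c not in network.columns]
    if missing:
        raise ValueError(f"network missing columns {missing}")
    if (network["served_population"] < 0).any():
        raise ValueError("served populations must be nonnegative")
    return network


def segment_weights(dates, window=DEFAULT_WINDOW) -> np.ndarray:
    """Segments-of-influence weights for sorted observation dates.

    Weights are a partition of unity: each observation owns the interval
    between the midpoints of its flanking gaps, first/last observations
    extend to the window edges.
    """
    t = pd.to_datetime(pd.Series(dates))
    if len(t) == 0:
        raise ValueError("empty date list")
    t0, t1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    total = (t1 - t0).days
    if total <= 0:
        raise ValueError("window must span at least one day")
    if (t < t0).any() or (t > t1).any():
        raise ValueError("dates outside the analysis window")
    d = (t - t0).dt.days.to_numpy(float)
    if np.any(np.diff(d) < 0):
        raise ValueError("dates must be sorted ascending")
    mid = (d[:-1] + d[1:]) / 2.0
    edges = np.concatenate([[0.0], mid, [float(total)]])
    w = np.diff(edges) / total
    return w


def unit_mean(
    imputed: ImputedPanelSet,
    unit_id,
    substance=None,
    window=DEFAULT_WINDOW,
) -> tuple[float, float]:
    """Multi-annual segments-weighted mean for one unit, pooled over imputations.

    Returns (pooled mean, across-imputation standard deviation).  The pooled
    estimate is the mean over the m per-imputation weighted means; their
    spread is the imputation-uncertainty attached to the unit.
    """
    means = []
    for p in imputed.panels:
        sub = p[p["unit_id"] == unit_id]
        if substance is not None:
            sub = sub[sub["substance"] == substance]
        if len(sub) == 0:
            raise KeyError(f"unit {unit_id!r} absent from panel")
        sub = sub.sort_values("date")
        w = segment_weights(sub["date"], window=window)
        means.append(float(np.dot(w, sub["value"].to_numpy(float))))
    means = np.asarray(means)
    sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    return float(means.mean()), sd


def all_unit_means(
    imputed: ImputedPanelSet, substance=None, window=DEFAULT_WINDOW
) -> pd.DataFrame:
    """Vectorized unit means for every unit: columns (unit_id, mean, sd)."""
    per_imp = []
    for p in imputed.panels:
        sub = p if substance is None else p[p["substance"] == substance]
        sub = sub.sort_values(["unit_id", "date"])
        parts = {}
        for uid, g in sub.groupby("unit_id", sort=False):
            w = segment_weights(g["date"], window=window)
            parts[uid] = float(np.dot(w, g["value"].to_numpy(float)))
        per_imp.append(pd.Series(parts))
    M = pd.concat(per_imp, axis=1)
    return pd.DataFrame({
        "unit_id": M.index,
        "mean": M.mean(axis=1).to_numpy(),
        "sd": M.std(axis=1, ddof=1).to_numpy() if M.shape[1] > 1 else 0.0,
    }).reset_index(drop=True)


def municipality_concentration(
    unit_means: pd.DataFrame, network: pd.DataFrame
) -> pd.DataFrame:
    """Population-served weighted municipal concentrations.

    ``unit_means`` columns: unit_id, mean[, sd].  Output columns:
    municipality_id, value, sd, missing.  Municipalities whose links all
    carry zero served population are flagged missing rather than filled.
    """
    validate_network(network)
    um = unit_means.set_index("unit_id")
    for uid in network["unit_id"].unique():
        if uid not in um.index:
            raise KeyError(f"no mean available for serving unit {uid!r}")
    rows = []
    for mid, g in network.groupby("municipality_id"):
        pop = g["served_population"].to_numpy(float)
        tot = pop.sum()
        if tot <= 0:
            rows.append({"municipality_id": mid, "value": np.nan, "sd": np.nan,
                         "missing": True})
            continue
        w = pop / tot
        mu = um.loc[g["unit_id"], "mean"].to_numpy(float)
        val = float(np.dot(w, mu))
        if "sd" in um.columns:
            sd = float(np.sqrt(np.dot(w**2, um.loc[g["unit_id"], "sd"].to_numpy(float) ** 2)))
        else:
            sd = np.nan
        rows.append({"municipality_id": mid, "value": val, "sd": sd, "missing": False})
    return pd.DataFrame(rows)


def municipality_cell_map(
    seeds: pd.DataFrame, template: RasterField
) -> np.ndarray:
    """Assign every grid cell to its nearest municipality seed (Voronoi).

    ``seeds`` columns: municipality_id, x_km, y_km.  Returns an object array
    of municipality ids with the raster's shape.
    """
    tree = cKDTree(seeds[["x_km", "y_km"]].to_numpy(float))
    cx, cy = template.cell_centers()
    _, idx = tree.query(np.column_stack([cx, cy]))
    ids = seeds["municipality_id"].to_numpy()[idx]
    return ids.reshape(template.shape)


def rasterize_municipalities(
    muni_values: pd.DataFrame, cell_map: np.ndarray, template: RasterField,
    value_col: str = "value",
) -> RasterField:
    """Paint each cell with its municipality's value, exactly (no smoothing).

    Cells of municipalities flagged missing (or absent from the table) get
    ``mask_missing`` — downstream this drives the grey-border overlay on the
    risk map.  Cells mapped to an unknown municipality id raise.
    """
    lut = muni_values.set_index("municipality_id")
    vals = np.zeros(template.shape, float)
    missing = np.zeros(template.shape, bool)
    known = set(lut.index)
    for mid in np.unique(cell_map):
        sel = cell_map == mid
        if mid not in known:
            raise KeyError(f"grid cell mapped to unknown municipality {mid!r}")
        row = lut.loc[mid]
        if bool(row.get("missing", False)) or not np.isfinite(row[value_col]):
            missing[sel] = True
        else:
            vals[sel] = float(row[value_col])
    return RasterField(
        vals, cell_size_km=template.cell_size_km, origin=template.origin,
        mask_missing=missing,
    )
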