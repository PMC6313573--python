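"""Multiple imputation of left-censored concentration panels.

A monitoring panel records, per distribution unit, date and substance, a
concentration or — very often — only the fact that it fell below a detection
limit (DL).  Substitution of censored values by a constant (DL/2, DL/sqrt 2,
0) is known to bias summaries badly once censoring exceeds a few percent.
This module instead treats censored cells as missing within a multivariate
normal model of the log-concentrations of all substances jointly, augmented
by a cubic polynomial in time, estimates the model by EM on bootstrap
resamples (one resample per imputation, in the style of bootstrap-EM
multiple imputation for cross-sectional time series), and draws each
censored cell from its conditional distribution given the observed cells in
the same (unit, date) row — truncated above at the cell's own DL so that
every imputed concentration lies in (0, DL].

The module also ships the naive substitution baselines and the artificial
censoring harness used to measure the bias of each approach on a panel whose
true values are known.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

PANEL_COLUMNS = ["unit_id", "date", "substance", "value", "censored", "dl"]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the CensoredPanel schema; returns the frame untouched."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns {missing}")
    if (panel["dl"] <= 0).any():
        raise ValueError("detection limits must be positive")
    cens = panel["censored"].astype(bool)
    if not np.allclose(panel.loc[cens, "value"], panel.loc[cens, "dl"]):
        raise ValueError("censored records must store the DL as their value")
    return panel


@dataclasses.dataclass
class ImputedPanelSet:
    """m completed panels plus across-imputation spread diagnostics.

    Uncensored records are bit-identical across all m panels; ``diagnostics``
    holds, per originally-censored record, the across-imputation mean and
    standard deviation — the uncertainty the imputation attaches to the cell.
    """

    panels: list[pd.DataFrame]
    diagnostics: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.panels)

    def pooled(self) -> pd.DataFrame:
        """Complete panel with censored cells replaced by the across-imputation mean."""
        out = self.panels[0].copy()
        vals = np.mean([p["value"].to_numpy() for p in self.panels], axis=0)
        out["value"] = vals
        return out


# ---------------------------------------------------------------------------
# EM for a multivariate normal with missing and left-censored cells
# ---------------------------------------------------------------------------

def _upper_trunc_moments(m, s, b):
    """Mean and variance of N(m, s^2) truncated to y <= b, vectorized.

    Stable for bounds far in the lower tail (inverse Mills ratio via its
    asymptote when the standardized bound alpha is very negative); b = +inf
    reduces to the untruncated moments.
    """
    alpha = (b - m) / s
    h = np.empty_like(alpha)
    lo = alpha < -8.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h[~lo] = norm.pdf(alpha[~lo]) / np.maximum(norm.cdf(alpha[~lo]), 1e-300)
    h[lo] = -alpha[lo] - 1.0 / alpha[lo]
    h = np.where(np.isinf(alpha), 0.0, h)
    mean = m - s * h
    var_factor = np.clip(1.0 - alpha * h - h**2, 1e-10, 1.0)
    var_factor = np.where(np.isinf(alpha), 1.0, var_factor)
    return mean, (s**2) * var_factor


def _em_mvn(X: np.ndarray, miss: np.ndarray, bounds: np.ndarray,
            max_iter: int = 100, tol: float = 1e-5,
            ridge: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """EM estimate of (mu, Sigma) with missing and left-censored cells.

    ``miss`` flags cells whose value is unknown; ``bounds`` holds, for each
    such cell, the upper bound implied by its detection limit (+inf for a
    plainly missing cell).  The E-step conditions each unknown cell on the
    observed cells of its row and — this is what removes the selection bias
    of treating censored cells as missing-at-random — replaces the
    conditional normal by its truncation below the bound.  Rows with a
    single unknown cell (the dominant case: one target substance censored,
    helpers observed) are handled exactly; when several cells of a row are
    censored jointly, truncated moments are applied per cell and the
    conditional cross-covariances are scaled accordingly (a standard
    componentwise approximation).  A ridge guards against singular Sigma.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely unknown; model not identifiable")

    X0 = np.where(miss, np.where(np.isfinite(bounds), bounds, np.nan), X)
    mu = np.nanmean(X0, axis=0)
    Sigma = np.cov(np.where(np.isnan(X0), mu, X0), rowvar=False) + np.eye(p) * ridge

    patterns: dict[int, np.ndarray] = {}
    keys = miss @ (1 << np.arange(p))
    for k in np.unique(keys):
        patterns[k] = np.where(keys == k)[0]

    for _ in range(max_iter):
        EX = np.where(miss, 0.0, X)
        S_extra = np.zeros((p, p))
        for k, rows in patterns.items():
            mis = miss[rows[0]]
            if not mis.any():
                continue
            o = ~mis
            midx = np.where(mis)[0]
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(mis, o)]
            Smm = Sigma[np.ix_(mis, mis)]
            if o.any():
                try:
                    K = np.linalg.solve(Soo, Smo.T).T
                except np.linalg.LinAlgError:
                    K = np.linalg.solve(Soo + np.eye(int(o.sum())) * 1e-8, Smo.T).T
                cond_mean = mu[mis] + (X[np.ix_(rows, np.where(o)[0])] - mu[o]) @ K.T
                cond_cov = Smm - K @ Smo.T
            else:
                cond_mean = np.tile(mu[mis], (rows.size, 1))
                cond_cov = Smm.copy()
            s = np.sqrt(np.clip(np.diag(cond_cov), 1e-12, None))
            b = bounds[np.ix_(rows, midx)]
            tmean, tvar = _upper_trunc_moments(cond_mean, s[None, :], b)
            EX[np.ix_(rows, midx)] = tmean
            # per-row second-moment correction: truncated variances on the
            # diagonal, cross terms scaled by the variance shrinkage
            shrink = np.sqrt(tvar / (s[None, :] ** 2))
            q = len(midx)
            corr = cond_cov / np.outer(s, s)
            avg_outer = np.einsum("ri,rj->ij", shrink, shrink) / rows.size
            cc = corr * avg_outer * np.outer(s, s)
            cc[np.diag_indices(q)] = tvar.mean(axis=0)
            S_extra[np.ix_(midx, midx)] += rows.size * cc
        mu_new = EX.mean(axis=0)
        D = EX - mu_new
        Sigma_new = (D.T @ D + S_extra) / n + np.eye(p) * ridge
        shift = np.max(np.abs(mu_new - mu)) + np.max(np.abs(Sigma_new - Sigma))
        mu, Sigma = mu_new, Sigma_new
        if shift < tol:
            break
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance in EM; ridge-regularized")
        w, V = np.linalg.eigh(Sigma)
        Sigma = (V * np.clip(w, 1e-8, None)) @ V.T
    return mu, Sigma


def _time_covariates(dates: pd.Series, window: tuple | None = None, degree: int = 3) -> np.ndarray:
    """Cubic polynomial in scaled time, shared across units."""
    t = pd.to_datetime(dates)
    if window is None:
        t0, t1 = t.min(), t.max()
    else:
        t0, t1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    span = max((t1 - t0).days, 1)
    u = (t - t0).dt.days.to_numpy() / span
    return np.column_stack([u**k for k in range(1, degree + 1)])


def _wide(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reshape the long panel to one row per (unit, date), cols per substance."""
    val = panel.pivot_table(index=["unit_id", "date"], columns="substance",
                            values="value", aggfunc="mean")
    cen = panel.assign(c=panel["censored"].astype(float)).pivot_table(
        index=["unit_id", "date"], columns="substance", values="c", aggfunc="max")
    dl = panel.pivot_table(index=["unit_id", "date"], columns="substance",
                           values="dl", aggfunc="mean")
    return val, cen, dl


def em_bootstrap_impute(
    panel: pd.DataFrame,
    m: int = 8,
    seed: int | None = None,
    max_iter: int = 100,
    time_degree: int = 3,
) -> ImputedPanelSet:
    """Bootstrap-EM multiple imputation of a left-censored panel.

    For each of the m imputations: resample (unit, date) rows with
    replacement, run EM on the resample's log-values + time polynomial to get
    (mu, Sigma), then draw every censored cell of the *original* panel from
    the conditional normal given the observed cells of its row, truncated
    above at log(DL).  Each bootstrap replicate gets an independent RNG
    substream.  m defaults to 8 (enough under very heavy censoring; 5 is a
    commonly sufficient minimum).
    """
    validate_panel(panel)
    if m < 2:
        raise ValueError("need at least two imputations")
    substances = sorted(panel["substance"].unique())
    if len(substances) < 2:
        cens_frac = panel["censored"].mean()
        if cens_frac > 0:
            raise ValueError(
                "panel has a single substance; cross-substance correlation "
                "cannot be exploited — imputation aborted"
            )
    if panel["censored"].astype(bool).all():
        raise ValueError("every record is censored; model not estimable")

    if not panel["censored"].any():
        panels = [panel.copy() for _ in range(m)]
        diag = panel.loc[[], PANEL_COLUMNS].assign(imp_mean=[], imp_sd=[])
        return ImputedPanelSet(panels, diag)

    val, cen, dl = _wide(panel)
    rows = val.index
    dates = rows.get_level_values("date")
    T = _time_covariates(pd.Series(dates), degree=time_degree)
    p_sub = len(substances)
    logv = np.log(val[substances].to_numpy())
    cmask = cen[substances].to_numpy() >= 0.5  # censored cells
    obs_nan = np.isnan(logv)  # substance never measured at this (unit, date)
    X_base = np.column_stack([logv, T])
    miss_template = np.column_stack([cmask | obs_nan, np.zeros_like(T, bool)])
    log_dl = np.log(dl[substances].to_numpy())
    bounds = np.full_like(X_base, np.inf)
    bounds[:, :p_sub] = np.where(cmask, log_dl, np.inf)

    rng_root = np.random.default_rng(seed)
    streams = rng_root.spawn(m)

    n = X_base.shape[0]
    draws = np.empty((m, n, p_sub))
    for b, rng in enumerate(streams):
        idx = rng.integers(0, n, size=n)
        mu, Sigma = _em_mvn(
            X_base[idx], miss_template[idx], bounds[idx], max_iter=max_iter
        )
        draws[b] = _conditional_draws(
            X_base, miss_template, cmask, log_dl, mu, Sigma, rng
        )

    panels = []
    key = panel.set_index(["unit_id", "date"]).index
    row_pos = {k: i for i, k in enumerate(rows)}
    ridx = np.array([row_pos[k] for k in key])
    sidx = np.array([substances.index(s) for s in panel["substance"]])
    cens_rec = panel["censored"].to_numpy(bool)
    for b in range(m):
        comp = panel.copy()
        newv = comp["value"].to_numpy(float).copy()
        newv[cens_rec] = np.exp(draws[b, ridx[cens_rec], sidx[cens_rec]])
        comp["value"] = newv
        comp["censored"] = False
        panels.append(comp)

    imp_stack = np.stack([p["value"].to_numpy()[cens_rec] for p in panels])
    diag = panel.loc[cens_rec, PANEL_COLUMNS].copy()
    diag["imp_mean"] = imp_stack.mean(axis=0)
    diag["imp_sd"] = imp_stack.std(axis=0, ddof=1)
    return ImputedPanelSet(panels, diag)


def _conditional_draws(X, miss, cmask, log_dl, mu, Sigma, rng,
                       max_reject: int = 50) -> np.ndarray:
    """Draw censored cells from N(cond_mean, cond_cov) truncated at log DL.

    Joint rejection sampling first (a row's censored cells are drawn together
    from their conditional MVN and accepted if all fall below their DLs),
    falling back to componentwise truncated normals for stubborn rows.
    """
    n, p_tot = X.shape
    p_sub = cmask.shape[1]
    out = X[:, :p_sub].copy()
    keys = miss @ (1 << np.arange(p_tot))
    for k in np.unique(keys):
        rows = np.where(keys == k)[0]
        mis = miss[rows[0]]
        if not mis.any():
            continue
        o = ~mis
        Soo = Sigma[np.ix_(o, o)]
        Smo = Sigma[np.ix_(mis, o)]
        Smm = Sigma[np.ix_(mis, mis)]
        K = np.linalg.solve(Soo + np.eye(int(o.sum())) * 1e-10, Smo.T).T
        cond_mean = mu[mis] + (X[np.ix_(rows, np.where(o)[0])] - mu[o]) @ K.T
        cond_cov = Smm - K @ Smo.T
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        w, V = np.linalg.eigh(cond_cov)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        q = int(mis.sum())
        mis_sub = np.where(mis[:p_sub])[0]  # only substance cells are drawn
        ub = log_dl[np.ix_(rows, mis_sub)]
        cen_here = cmask[np.ix_(rows, mis_sub)]
        ub_eff = np.where(cen_here, ub, np.inf)  # non-censored-missing: unbounded
        samp = np.full((rows.size, q), np.nan)
        todo = np.ones(rows.size, bool)
        for _ in range(max_reject):
            if not todo.any():
                break
            z = rng.standard_normal((int(todo.sum()), q))
            cand = cond_mean[todo] + z @ L.T
            ok = np.all(cand[:, :len(mis_sub)] <= ub_eff[todo], axis=1)
            pos = np.where(todo)[0][ok]
            samp[pos] = cand[ok]
            todo[pos] = False
        if todo.any():  # componentwise truncated-normal fallback
            sd = np.sqrt(np.clip(np.diag(cond_cov), 1e-12, None))
            for j in range(len(mis_sub)):
                mrows = np.where(todo)[0]
                a = -np.inf
                b = (ub_eff[mrows, j] - cond_mean[mrows, j]) / sd[j]
                b = np.clip(b, -8.0, np.inf)
                samp[mrows, j] = cond_mean[mrows, j] + sd[j] * truncnorm.rvs(
                    a, b, size=mrows.size, random_state=rng
                )
            if q > len(mis_sub):
                mrows = np.where(todo)[0]
                for j in range(len(mis_sub), q):
                    samp[mrows, j] = cond_mean[mrows, j] + sd[j] * rng.standard_normal(mrows.size)
        # write drawn substance cells back
        for jj, s in enumerate(mis_sub):
            sel = cen_here[:, jj]
            out[rows[sel], s] = samp[sel, jj]
    return out


# ---------------------------------------------------------------------------
# Baselines and the bias-evaluation harness
# ---------------------------------------------------------------------------

SUBSTITUTION_RULES = ("half_dl", "dl_over_sqrt2", "zero")


def substitute(panel: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Naive constant substitution of censored values (per-record DL based)."""
    validate_panel(panel)
    if rule not in SUBSTITUTION_RULES:
        raise ValueError(f"unknown substitution rule {rule!r}")
    out = panel.copy()
    cens = out["censored"].to_numpy(bool)
    dl = out["dl"].to_numpy(float)
    repl = {"half_dl": dl / 2.0, "dl_over_sqrt2": dl / np.sqrt(2.0), "zero": np.zeros_like(dl)}[rule]
    vals = out["value"].to_numpy(float).copy()
    vals[cens] = repl[cens]
    out["value"] = vals
    out["censored"] = False
    return out


def artificial_censor(panel: pd.DataFrame, threshold: float,
                      substances: list | None = None) -> tuple[pd.DataFrame, float]:
    """Flag values below ``threshold`` as censored (dl = threshold).

    Used to benchmark imputation on a panel whose true values are known.
    ``substances`` restricts censoring to the listed substances (the helper
    substances stay fully observed).  Returns (censored panel, realized
    censoring fraction over the targeted records).  Censoring everything is
    an error — no model could be estimated.
    """
    if panel["censored"].any():
        raise ValueError("panel must be complete before artificial censoring")
    out = panel.copy()
    target = np.ones(len(out), bool) if substances is None else out["substance"].isin(substances).to_numpy()
    below = (out["value"].to_numpy(float) < threshold) & target
    if below[target].all():
        raise ValueError("threshold censors 100% of the targeted records")
    vals = out["value"].to_numpy(float).copy()
    vals[below] = threshold
    out["value"] = vals
    out["censored"] = below
    out["dl"] = np.where(target, threshold, out["dl"].to_numpy(float))
    frac = float(below[target].mean())
    return out, frac


def evaluate_imputation(truth: pd.DataFrame, estimate, censored_mask=None) -> dict:
    """AME and RMSE of an estimate against truth, on originally-censored cells.

    ``estimate`` may be a complete panel (same record order as truth) or an
    ImputedPanelSet, in which case the across-imputation mean is scored.
    """
    if isinstance(estimate, ImputedPanelSet):
        est_vals = estimate.pooled()["value"].to_numpy(float)
        if censored_mask is None:
            censored_mask = estimate.panels[0].index.isin(estimate.diagnostics.index)
    else:
        est_vals = estimate["value"].to_numpy(float)
    if censored_mask is None:
        raise ValueError("censored_mask required when estimate is a plain panel")
    censored_mask = np.asarray(censored_mask, bool)
    if not censored_mask.any():
        raise ValueError("no censored cells to evaluate")
    err = est_vals[censored_mask] - truth["value"].to_numpy(float)[censored_mask]
    return {"AME": float(np.mean(np.abs(err))), "RMSE": float(np.sqrt(np.mean(err**2)))}


def bias_simulation(
    complete_panel: pd.DataFrame,
    thresholds: list[float],
    target_substance,
    m: int = 8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Artificially censor a known panel and score imputation vs substitution.

    Mirrors the validation design in which a nearly complete two-substance
    panel (e.g. arsenic helped by selenium) is censored at DL thresholds of
    3 and 5 ug/L and each completion method is scored by AME/RMSE on the
    censored cells.  Returns a tidy frame (threshold, method, AME, RMSE,
    censoring_fraction).
    """
    rows = []
    rng = np.random.default_rng(seed)
    for thr in thresholds:
        cens_panel, frac = artificial_censor(
            complete_panel, thr, substances=[target_substance]
        )
        mask = cens_panel["censored"].to_numpy(bool)
        imp = em_bootstrap_impute(cens_panel, m=m, seed=int(rng.integers(2**31)))
        for method, est in (
            ("imputation", imp),
            ("half_dl", substitute(cens_panel, "half_dl")),
            ("dl_over_sqrt2", substitute(cens_panel, "dl_over_sqrt2")),
        ):
            sc = evaluate_imputation(complete_panel, est, censored_mask=mask)
            rows.append({"threshold": thr, "method": method,
                         "censoring_fraction": frac, **sc})
    return pd.DataFrame(rows)
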