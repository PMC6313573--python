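"""Pipeline orchestration, run manifests, and the rendered risk map.

``run_pipeline`` executes the whole chain — scenario generation, censored
imputation, water aggregation, soil and air mapping, exposure — persisting
every intermediate as plain text (CSV, ESRI ASCII grid, YAML, JSON) under an
output directory, together with a JSON manifest recording the configuration,
seeds, per-stage diagnostics and output checksums.  Re-running with the same
configuration and intact outputs skips completed stages unless ``force``.

``render_risk_map`` draws the total-EIR choropleth with the two uncertainty
overlays: grey borders on cells where water data are missing, black
cross-hatch on cells outside the validity domain of the air model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import air as air_mod
from . import censoring, exposure, soil as soil_mod, water as water_mod
from .grids import RasterField, load_raster_bundle, save_raster_bundle
from .kriging import ObservationSet
from .scenario import (
    ScenarioConfig,
    make_receptors,
    simulate_air_year,
    simulate_soil_survey,
    simulate_water_panel,
)

log = logging.getLogger("geoexpose")


@dataclasses.dataclass
class PipelineConfig:
    scenario: ScenarioConfig = dataclasses.field(default_factory=ScenarioConfig)
    m_imputations: int = 8
    target_substance: str = "S0"
    candidate_radii: tuple = (1.0, 2.0, 3.0, 5.0, 10.0)
    rf_trees: int = 200
    soil_loocv: bool = False
    commercial_food_mg_kg: dict = dataclasses.field(
        default_factory=lambda: {"other_food": 2e-4})
    slope_ingestion: float = 7.3
    slope_inhalation: float = 3.9

    def key(self) -> str:
        d = dataclasses.asdict(self)
        d["scenario"].pop("soil_variogram", None)
        d["scenario"].pop("air_residual_variogram", None)
        d["scenario"]["soil_vgm"] = dataclasses.astuple(self.scenario.soil_variogram)
        d["scenario"]["air_vgm"] = dataclasses.astuple(self.scenario.air_residual_variogram)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    """Run manifest: config key, seeds, stage outputs with checksums."""

    def __init__(self, path: Path, config_key: str, seed: int):
        self.path = path
        self.data = {"config_key": config_key, "seed": seed, "stages": {}}
        if path.exists():
            try:
                prev = json.loads(path.read_text())
                if prev.get("config_key") == config_key and prev.get("seed") == seed:
                    self.data = prev
            except json.JSONDecodeError:
                pass

    def stage_complete(self, name: str) -> bool:
        st = self.data["stages"].get(name)
        if not st:
            return False
        for f, h in st.get("files", {}).items():
            p = self.path.parent / f
            if not p.exists() or _sha256(p) != h:
                return False
        return True

    def record(self, name: str, files: list[Path], diagnostics: dict) -> None:
        self.data["stages"][name] = {
            "files": {str(f.relative_to(self.path.parent)): _sha256(f) for f in files},
            "diagnostics": diagnostics,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int | None = None,
    force: bool = False,
) -> dict:
    """Execute scenario -> imputation -> water -> soil -> air -> exposure.

    Returns a dict of in-memory results; all intermediates and outputs are
    also persisted under ``out_dir``.  Stage failures raise with the stage
    name and seed in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.scenario.seed if seed is None else seed
    manifest = Manifest(out / "manifest.json", config.key(), seed)
    results: dict = {"manifest": manifest}
    cfg = config.scenario
    tmpl = cfg.template()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            if not force and manifest.stage_complete(name):
                log.info("stage %s: outputs intact, skipped", name)
                return None
            log.info("stage %s: running (seed=%s)", name, seed)
            try:
                files, diag = fn()
            except Exception:
                log.error("stage %s failed (seed=%s)", name, seed)
                raise
            manifest.record(name, files, diag)
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return None
        return deco

    # -- scenario ----------------------------------------------------------
    @stage("scenario")
    def _scenario():
        panel, network, seeds_df = simulate_water_panel(cfg, seed=seed)
        soil_obs, covs, sites, truth = simulate_soil_survey(cfg, seed=seed)
        st10, emission, altitude, population = simulate_air_year(cfg, 1.0, seed=seed)
        st11, *_ = simulate_air_year(cfg, 0.0, seed=seed + 1)
        receptors = make_receptors(cfg)
        panel.to_csv(out / "water_panel.csv", index=False)
        network.to_csv(out / "network.csv", index=False)
        seeds_df.to_csv(out / "municipalities.csv", index=False)
        soil_obs.to_csv(out / "soil_obs.csv", index=False)
        np.savetxt(out / "polluted_sites.csv", sites, delimiter=",",
                   header="x_km,y_km", comments="")
        files = [out / f for f in ("water_panel.csv", "network.csv",
                                   "municipalities.csv", "soil_obs.csv",
                                   "polluted_sites.csv")]
        for name, r in covs.items():
            files += save_raster_bundle(out / "covariates", name, r)
        for name, r in (("emission", emission), ("altitude", altitude),
                        ("population", population), ("soil_truth", truth)):
            files += save_raster_bundle(out, name, r)
        st10.to_csv(out / "stations_year1.csv", index=False)
        st11.to_csv(out / "stations_year2.csv", index=False)
        files += [out / "stations_year1.csv", out / "stations_year2.csv"]
        exposure.save_receptors(out / "receptors.yaml", receptors)
        files.append(out / "receptors.yaml")
        diag = {
            "water_censoring": float(panel["censored"].mean()),
            "soil_censoring": float(soil_obs["censored"].mean()),
            "n_stations": int(len(st10)),
        }
        return files, diag

    panel = pd.read_csv(out / "water_panel.csv")
    network = pd.read_csv(out / "network.csv")
    seeds_df = pd.read_csv(out / "municipalities.csv")
    soil_obs_df = pd.read_csv(out / "soil_obs.csv")
    sites = np.loadtxt(out / "polluted_sites.csv", delimiter=",", skiprows=1, ndmin=2)
    st10 = pd.read_csv(out / "stations_year1.csv")
    st11 = pd.read_csv(out / "stations_year2.csv")
    covs = {f"cov{k:02d}": load_raster_bundle(out / "covariates", f"cov{k:02d}")
            for k in range(14)}
    emission = load_raster_bundle(out, "emission")
    altitude = load_raster_bundle(out, "altitude")
    population = load_raster_bundle(out, "population")
    receptors = exposure.load_receptors(out / "receptors.yaml")

    # -- imputation + water ------------------------------------------------
    @stage("water")
    def _water():
        imp = censoring.em_bootstrap_impute(panel, m=config.m_imputations, seed=seed)
        means = water_mod.all_unit_means(imp, substance=config.target_substance,
                                        window=cfg.date_window)
        muni = water_mod.municipality_concentration(means, network)
        cell_map = water_mod.municipality_cell_map(seeds_df, tmpl)
        raster = water_mod.rasterize_municipalities(muni, cell_map, tmpl)
        sd_raster = water_mod.rasterize_municipalities(muni, cell_map, tmpl,
                                                       value_col="sd")
        means.to_csv(out / "unit_means.csv", index=False)
        muni.to_csv(out / "municipality_conc.csv", index=False)
        imp.diagnostics.to_csv(out / "imputation_diagnostics.csv", index=False)
        files = [out / "unit_means.csv", out / "municipality_conc.csv",
                 out / "imputation_diagnostics.csv"]
        files += save_raster_bundle(out, "water_conc", raster)
        files += save_raster_bundle(out, "water_conc_sd", sd_raster)
        diag = {"m": imp.m,
                "mean_imp_sd": float(imp.diagnostics["imp_sd"].mean()),
                "n_missing_municipalities": int(muni["missing"].sum())}
        return files, diag

    water_raster = load_raster_bundle(out, "water_conc")

    # -- soil --------------------------------------------------------------
    @stage("soil")
    def _soil():
        obs = ObservationSet.from_frame(soil_obs_df)
        res = soil_mod.map_soil(
            obs, covs, sites, tmpl, candidate_radii=config.candidate_radii,
            seed=seed, rf_trees=config.rf_trees, run_loocv=config.soil_loocv,
        )
        files = save_raster_bundle(out, "soil_conc", res.raster)
        files += save_raster_bundle(out, "soil_probability", res.probability)
        diag = {"buffer_radius_km": res.proxy_radius_km,
                "selected_covariates": res.selected_covariates}
        if res.loocv:
            diag["loocv_me"] = res.loocv["me"]
            diag["loocv_rmse"] = res.loocv["rmse"]
        return files, diag

    soil_raster = load_raster_bundle(out, "soil_conc")

    # -- air ---------------------------------------------------------------
    @stage("air")
    def _air():
        gx, gy = tmpl.cell_centers()
        maps, rmses = [], []
        year_diag = {}
        for label, st in (("year1", st10), ("year2", st11)):
            obs = ObservationSet.from_frame(st)
            proxy_o = air_mod.build_emission_proxy(emission, obs.x, obs.y)
            proxy_c = air_mod.build_emission_proxy(emission, gx, gy)
            cov_o = pd.DataFrame({
                "emission_proxy": proxy_o,
                "altitude": altitude.sample(obs.x, obs.y),
                "population": population.sample(obs.x, obs.y),
            })
            cov_c = pd.DataFrame({
                "emission_proxy": proxy_c,
                "altitude": altitude.values.ravel(),
                "population": population.values.ravel(),
            })
            drift = air_mod.fit_drift(obs, cov_o)
            res = air_mod.map_air_year(obs, drift, cov_c, cov_o, tmpl)
            maps.append(res.raster)
            rmses.append(res.loocv["rmse"])
            year_diag[label] = {"terms": list(drift.terms),
                                "loocv_me": drift.loocv["me"],
                                "loocv_rmse": drift.loocv["rmse"]}
        combined = air_mod.combine_years(maps, rmses)
        invalid = air_mod.validity_mask(altitude, population)
        combined.mask_invalid = invalid
        files = []
        for label, m in zip(("year1", "year2"), maps):
            files += save_raster_bundle(out, f"air_conc_{label}", m)
        files += save_raster_bundle(out, "air_conc_combined", combined)
        year_diag["combination_weights"] = list(
            (1 / np.array(rmses) ** 2) / np.sum(1 / np.array(rmses) ** 2))
        year_diag["n_invalid_cells"] = int(invalid.sum())
        return files, year_diag

    air_raster = load_raster_bundle(out, "air_conc_combined")

    # -- exposure ----------------------------------------------------------
    @stage("exposure")
    def _exposure():
        sf = exposure.SlopeFactors(config.slope_ingestion, config.slope_inhalation)
        maps = exposure.map_exposure(
            air_raster, soil_raster, water_raster, receptors,
            slope_factors=sf, commercial_food_mg_kg=config.commercial_food_mg_kg,
        )
        files = []
        contrib_rows = []
        for em in maps:
            tag = em.age_class
            files += save_raster_bundle(out, f"eir_total_{tag}", em.eir_total)
            files += save_raster_bundle(out, f"eir_ingestion_{tag}", em.eir_ingestion)
            files += save_raster_bundle(out, f"eir_inhalation_{tag}", em.eir_inhalation)
            for p, r in em.ladd.items():
                files += save_raster_bundle(out / "ladd", f"{p}_{tag}", r)
            for p, c in em.contributions.items():
                contrib_rows.append({"age_class": tag, "pathway": p, "fraction": c})
            fig_path = out / f"risk_map_{tag}.png"
            render_risk_map(em.eir_total, fig_path,
                            title=f"Total EIR (x1e6), {tag}")
            files.append(fig_path)
        pd.DataFrame(contrib_rows).to_csv(out / "pathway_contributions.csv", index=False)
        files.append(out / "pathway_contributions.csv")
        diag = {"n_receptors": len(maps)}
        return files, diag

    results["out_dir"] = out
    results["panel"] = panel
    results["water_raster"] = water_raster
    results["soil_raster"] = soil_raster
    results["air_raster"] = air_raster
    results["contributions"] = pd.read_csv(out / "pathway_contributions.csv")
    results["manifest_data"] = manifest.data
    return results


def render_risk_map(
    eir: RasterField,
    path: str | Path | None = None,
    title: str = "Total EIR (x1e6)",
):
    """Choropleth of total EIR with the two uncertainty overlays.

    Cells with ``mask_missing`` (no water data) are outlined in grey; cells
    with ``mask_invalid`` (outside the air model's validity domain) are
    hidden under a black cross-hatch.  The legend states the x10^6 scale.
    """
    fig, ax = plt.subplots(figsize=(7, 6))
    vals = np.ma.masked_where(eir.mask_missing, eir.values)
    ex = [eir.origin[0], eir.origin[0] + eir.nx * eir.cell_size_km,
          eir.origin[1], eir.origin[1] + eir.ny * eir.cell_size_km]
    im = ax.imshow(vals, origin="lower", extent=ex, cmap="YlOrRd")
    cb = fig.colorbar(im, ax=ax)
    cb.set_label("Excess Individual Risk (x10^6)")
    cs = eir.cell_size_km
    for j, i in zip(*np.where(eir.mask_missing)):
        ax.add_patch(plt.Rectangle(
            (ex[0] + i * cs, ex[2] + j * cs), cs, cs,
            facecolor="none", edgecolor="grey", linewidth=1.0))
    for j, i in zip(*np.where(eir.mask_invalid)):
        ax.add_patch(plt.Rectangle(
            (ex[0] + i * cs, ex[2] + j * cs), cs, cs,
            facecolor="none", edgecolor="black", hatch="xx", linewidth=0.0))
    ax.set_title(title)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig


def main(argv=None) -> None:
    """Thin shell entry: ``python -m geoexpose.pipeline CONFIG.yaml OUT_DIR``.

    The YAML config holds PipelineConfig fields, with scenario fields nested
    under ``scenario:``; omitted fields keep their defaults.
    """
    import argparse

    import yaml

    ap = argparse.ArgumentParser(description=main.__doc__)
    ap.add_argument("config", type=Path, help="YAML pipeline configuration")
    ap.add_argument("out_dir", type=Path)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--force", action="store_true")
    args = ap.parse_args(argv)

    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    raw = yaml.safe_load(args.config.read_text()) or {}
    scen = ScenarioConfig(**raw.pop("scenario", {}))
    cfg = PipelineConfig(scenario=scen, **raw)
    run_pipeline(cfg, args.out_dir, seed=args.seed, force=args.force)


if __name__ == "__main__":
    main()
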