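"""Source proxy, AIC buffer selection, OOB covariate selection, soil mapping."""

import warnings

import numpy as np
import pandas as pd
import pytest

from geoexpose.kriging import ObservationSet
from geoexpose.scenario import ScenarioConfig, simulate_soil_survey
from geoexpose.soil import (
    build_source_proxy,
    map_soil,
    select_buffer_radius,
    select_covariates_oob,
)


class TestSourceProxy:
    def test_inverse_distance_inside_buffer(self):
        p = build_source_proxy(np.array([[0.0, 0.0]]), [2.0], [0.0], 3.0, d_min_km=0.5)
        assert p[0] == pytest.approx(0.5)

    def test_zero_outside_buffer(self):
        p = build_source_proxy(np.array([[0.0, 0.0]]), [4.0], [0.0], 3.0)
        assert p[0] == 0.0

    def test_sums_over_sites(self):
        sites = np.array([[2.0, 0.0], [-4.0, 0.0]])
        p = build_source_proxy(sites, [0.0], [0.0], 5.0, d_min_km=0.5)
        assert p[0] == pytest.approx(0.5 + 0.25)

    def test_dmin_floors_colocation(self):
        p = build_source_proxy(np.array([[1.0, 1.0]]), [1.0], [1.0], 3.0, d_min_km=1.5)
        assert p[0] == pytest.approx(1.0 / 1.5)

    def test_no_sites_all_zero(self):
        p = build_source_proxy(np.empty((0, 2)), [1.0, 2.0], [0.0, 0.0], 3.0)
        assert np.allclose(p, 0.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            build_source_proxy(np.array([[0.0, 0.0]]), [1.0], [1.0], 0.0)


class TestBufferSelection:
    def test_single_candidate_returned(self, rng):
        obs = ObservationSet(rng.uniform(0, 20, 30), rng.uniform(0, 20, 30),
                             rng.normal(0, 1, 30))
        sites = np.array([[10.0, 10.0]])
        r, table = select_buffer_radius([5.0], obs, sites)
        assert r == 5.0 and len(table) == 1

    def test_true_decay_radius_recovered(self):
        # single-seed instance of the recovery experiment (majority-level
        # behaviour is asserted in the acceptance suite)
        cfg = ScenarioConfig(seed=3, grid_nx=60, grid_ny=60,
                             soil_spacing_cells=2, n_polluted_sites=40)
        obs_df, covs, sites, _ = simulate_soil_survey(cfg, site_amplitude=1.5)
        vals = obs_df["value"].to_numpy().copy()
        c = obs_df["censored"].to_numpy(bool)
        vals[c] /= 2
        obs = ObservationSet(obs_df.x_km, obs_df.y_km, np.log(vals))
        extra = np.column_stack(
            [covs[f"cov{k:02d}"].sample(obs.x, obs.y) for k in range(3)])
        r, _ = select_buffer_radius([1, 2, 3, 5, 10], obs, sites,
                                    extra_covariates=extra)
        assert r == 3.0

    def test_degenerate_proxy_skipped(self, rng):
        obs = ObservationSet(rng.uniform(50, 60, 20), rng.uniform(50, 60, 20),
                             rng.normal(0, 1, 20))
        sites = np.array([[0.0, 0.0]])  # far away from every observation
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError):
                select_buffer_radius([1.0, 2.0], obs, sites)


class TestOobSelection:
    def test_noise_covariate_eliminated(self, rng):
        n = 150
        x1 = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = 2.0 * x1 + 0.1 * rng.normal(size=n)
        sel, hist = select_covariates_oob(
            y, pd.DataFrame({"informative": x1, "noise": noise}),
            seed=0, n_estimators=200)
        assert sel == ["informative"]

    def test_orthogonal_informative_set_retained(self, rng):
        n = 200
        X = pd.DataFrame({f"c{i}": rng.normal(size=n) for i in range(3)})
        y = X["c0"] + X["c1"] + X["c2"] + 0.05 * rng.normal(size=n)
        sel, _ = select_covariates_oob(y, X, seed=0, n_estimators=200)
        assert set(sel) == {"c0", "c1", "c2"}

    def test_single_candidate_returned(self, rng):
        X = pd.DataFrame({"only": rng.normal(size=50)})
        sel, _ = select_covariates_oob(rng.normal(size=50), X, seed=0,
                                       n_estimators=50)
        assert sel == ["only"]

    def test_deterministic_under_seed(self, rng):
        n = 100
        X = pd.DataFrame({f"c{i}": rng.normal(size=n) for i in range(4)})
        y = X["c0"] - X["c2"] + 0.2 * rng.normal(size=n)
        a, _ = select_covariates_oob(y, X, seed=7, n_estimators=100)
        b, _ = select_covariates_oob(y, X, seed=7, n_estimators=100)
        assert a == b


class TestMapSoil:
    @pytest.fixture
    def small_soil(self, small_config):
        obs_df, covs, sites, truth = simulate_soil_survey(small_config)
        obs = ObservationSet.from_frame(obs_df)
        return obs, covs, sites, truth, small_config.template()

    def test_pipeline_outputs(self, small_soil):
        obs, covs, sites, truth, tmpl = small_soil
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = map_soil(obs, covs, sites, tmpl, seed=0, rf_trees=50,
                           run_loocv=False, candidate_radii=(2.0, 3.0, 5.0))
        assert res.raster.shape == tmpl.shape
        assert np.all(res.raster.values >= 0.0)
        assert np.all((res.probability.values >= 0) & (res.probability.values <= 1))
        assert res.proxy_radius_km in (2.0, 3.0, 5.0)
        assert len(res.selected_covariates) >= 1

    def test_deterministic_given_seed(self, small_soil):
        obs, covs, sites, truth, tmpl = small_soil
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = map_soil(obs, covs, sites, tmpl, seed=1, rf_trees=30,
                         run_loocv=False, candidate_radii=(3.0,),
                         select_covariates=False)
            b = map_soil(obs, covs, sites, tmpl, seed=1, rf_trees=30,
                         run_loocv=False, candidate_radii=(3.0,),
                         select_covariates=False)
        assert np.array_equal(a.raster.values, b.raster.values)

    def test_zero_variance_field_uniform_prediction(self, small_config):
        tmpl = small_config.template()
        n = 25
        r = np.random.default_rng(0)
        obs = ObservationSet(r.uniform(0, 40, n), r.uniform(0, 40, n),
                             np.full(n, 2.0))
        covs = {"c": tmpl.copy_with(r.normal(size=tmpl.shape))}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = map_soil(obs, covs, np.array([[20.0, 20.0]]), tmpl, seed=0,
                           rf_trees=30, run_loocv=False,
                           candidate_radii=(5.0,), select_covariates=False)
        assert np.allclose(res.raster.values, 2.0, atol=1e-6)
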