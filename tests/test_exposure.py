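"""Dose algebra: transfer model, LADD, EIR, contribution decomposition, maps."""

import numpy as np
import pytest

from geoexpose.exposure import (
    ALL_PATHWAYS,
    MediaConcentrations,
    ReceptorProfile,
    SlopeFactors,
    TransferParams,
    compute_eir,
    compute_ladd,
    default_receptors,
    load_receptors,
    map_exposure,
    save_receptors,
    veg_transfer,
)
from geoexpose.grids import RasterField


@pytest.fixture
def adult():
    return [r for r in default_receptors() if r.age_class == "adult_17_70"][0]


class TestReceptors:
    def test_two_classes_durations_partition_lifetime(self):
        rs = default_receptors()
        assert len(rs) == 2
        assert sum(r.exposure_duration_years for r in rs) == pytest.approx(70.0)
        assert {r.age_class for r in rs} == {"child_0_17", "adult_17_70"}

    def test_round_trip_serialization(self, tmp_path):
        rs = default_receptors()
        save_receptors(tmp_path / "r.yaml", rs)
        back = load_receptors(tmp_path / "r.yaml")
        assert [r.to_dict() for r in back] == [r.to_dict() for r in rs]

    def test_invalid_self_consumption_rejected(self, adult):
        d = adult.to_dict()
        d["self_consumption_fraction"] = 1.3
        with pytest.raises(ValueError):
            ReceptorProfile.from_dict(d)


class TestVegTransfer:
    def test_zero_media_zero_veg(self):
        out = veg_transfer(0.0, 0.0)
        assert all(v == 0.0 for v in out.values())

    def test_soil_doubling_affects_root_term_only(self):
        p = TransferParams()
        base = veg_transfer(1.0, 1.0, p)
        doubled = veg_transfer(1.0, 2.0, p)
        for cat in base:
            root = p.soil_to_plant.get(cat, 0.0)
            assert doubled[cat] - base[cat] == pytest.approx(root)

    def test_root_uptake_hand_product(self):
        p = TransferParams(soil_to_plant={"leaf": 0.01},
                           yield_kg_per_m2={"leaf": 2.0},
                           interception_weathering_days={"leaf": 0.0})
        out = veg_transfer(0.0, 1.0, p)
        assert out["leaf"] == pytest.approx(0.01)

    def test_nonpositive_yield_rejected(self):
        p = TransferParams(yield_kg_per_m2={"leaf": 0.0})
        with pytest.raises(ValueError):
            veg_transfer(1.0, 1.0, p)


class TestLadd:
    def test_all_zero_media(self, adult):
        doses = compute_ladd(MediaConcentrations(), adult)
        assert all(v == 0.0 for v in doses.ladd.values())

    def test_water_hand_value(self):
        # 0.001 mg/L x 2 L/d x (53/70) / 70 kg = 2.1633e-5 mg/kg/d
        rec = ReceptorProfile(
            age_class="adult_17_70", body_weight_kg=70.0,
            water_intake_l_per_day=2.0, soil_ingestion_mg_per_day=0.0,
            inhalation_m3_per_day=0.0, veg_intake_g_per_day={},
            commercial_intake_g_per_day={}, self_consumption_fraction=0.0,
            exposure_duration_years=53.0)
        doses = compute_ladd(MediaConcentrations(water_mg_l=0.001), rec)
        expected = 0.001 * 2.0 * (53.0 / 70.0) / 70.0
        assert doses.ladd["water"] == pytest.approx(expected, rel=1e-10)
        assert doses.ladd["water"] == pytest.approx(2.1632653e-5, rel=1e-6)

    def test_pathway_independence_under_doubling(self, adult):
        media = MediaConcentrations(air_ng_m3=0.5, soil_mg_kg=0.1, water_mg_l=1e-5,
                                    homegrown_veg_mg_kg={"leaf": 1e-4},
                                    commercial_food_mg_kg={"other_food": 2e-4})
        base = compute_ladd(media, adult)
        media2 = MediaConcentrations(air_ng_m3=0.5, soil_mg_kg=0.1, water_mg_l=2e-5,
                                     homegrown_veg_mg_kg={"leaf": 1e-4},
                                     commercial_food_mg_kg={"other_food": 2e-4})
        d2 = compute_ladd(media2, adult)
        assert d2.ladd["water"] == pytest.approx(2 * base.ladd["water"])
        for p in ALL_PATHWAYS:
            if p != "water":
                assert d2.ladd[p] == pytest.approx(base.ladd[p])

    def test_self_consumption_zero_kills_homegrown(self, adult):
        d = adult.to_dict()
        d["self_consumption_fraction"] = 0.0
        rec = ReceptorProfile.from_dict(d)
        media = MediaConcentrations(homegrown_veg_mg_kg={"leaf": 1.0, "root": 1.0,
                                                         "fruit": 1.0})
        doses = compute_ladd(media, rec)
        assert doses.ladd["homegrown_veg"] == 0.0


class TestEir:
    def test_unit_slope_identity(self, adult):
        doses = compute_ladd(MediaConcentrations(water_mg_l=0.001), adult)
        out = compute_eir(doses, SlopeFactors(1.0, 1.0))
        assert out.eir_ingestion == pytest.approx(sum(
            out.ladd[p] for p in ("water", "soil", "homegrown_veg", "commercial_food")))

    def test_zero_dose_zero_risk(self, adult):
        out = compute_eir(compute_ladd(MediaConcentrations(), adult))
        assert out.eir_total == 0.0

    def test_route_additivity(self, adult):
        media = MediaConcentrations(air_ng_m3=1.0, water_mg_l=1e-5,
                                    commercial_food_mg_kg={"other_food": 2e-4})
        out = compute_eir(compute_ladd(media, adult))
        assert out.eir_total == pytest.approx(out.eir_ingestion + out.eir_inhalation)

    def test_contributions_sum_to_one(self, adult):
        media = MediaConcentrations(air_ng_m3=1.0, soil_mg_kg=0.05, water_mg_l=1e-5,
                                    homegrown_veg_mg_kg={"leaf": 2e-4},
                                    commercial_food_mg_kg={"other_food": 2e-4})
        doses = compute_ladd(media, adult)
        assert sum(doses.contributions.values()) == pytest.approx(1.0)


class TestMapExposure:
    def make_rasters(self, missing=None, invalid=None):
        shape = (3, 3)
        air = RasterField(np.full(shape, 0.5), cell_size_km=3.0,
                          mask_invalid=invalid)
        soil = RasterField(np.full(shape, 0.05), cell_size_km=3.0)
        water = RasterField(np.full(shape, 1e-5), cell_size_km=3.0,
                            mask_missing=missing)
        return air, soil, water

    def test_uniform_media_uniform_risk(self):
        air, soil, water = self.make_rasters()
        maps = map_exposure(air, soil, water, default_receptors())
        for em in maps:
            v = em.eir_total.values
            assert np.allclose(v, v[0, 0])
            assert np.all(v > 0)

    def test_mask_propagation(self):
        missing = np.zeros((3, 3), bool)
        missing[1, 1] = True
        invalid = np.zeros((3, 3), bool)
        invalid[0, 2] = True
        air, soil, water = self.make_rasters(missing=missing, invalid=invalid)
        maps = map_exposure(air, soil, water, default_receptors())
        for em in maps:
            assert em.eir_total.mask_missing[1, 1]
            assert em.eir_total.mask_invalid[0, 2]
            assert em.eir_ingestion.mask_missing[1, 1]

    def test_contribution_fractions_sum_to_one(self):
        air, soil, water = self.make_rasters()
        maps = map_exposure(air, soil, water, default_receptors())
        for em in maps:
            assert sum(em.contributions.values()) == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        air, soil, water = self.make_rasters()
        bad_soil = RasterField(np.zeros((4, 4)), cell_size_km=3.0)
        with pytest.raises(ValueError):
            map_exposure(air, bad_soil, water, default_receptors())
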