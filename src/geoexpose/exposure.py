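"""Multimedia exposure: lifetime average daily doses and excess risk.

Pathways: inhalation of local air; ingestion of drinking water, soil,
home-grown vegetables (air deposition + root uptake transfer), and
commercial foodstuffs (spatially constant concentrations).  For each
pathway,

    LADD = C x intake_rate x ED / (BW x LT)        [mg kg^-1 day^-1]

with C the medium concentration, ED the age-class exposure duration in
years, LT the 70-year lifetime and BW the body weight.  Risk uses the
linear no-threshold model EIR = SF x LADD summed per route (ingestion,
inhalation); total EIR is their sum and maps are reported on a x10^6 scale.

The transfer and dose equations here are a simplified, clearly-labelled
stand-in for a full multimedia fate model: vegetable concentrations combine
an air-deposition term and a linear soil-to-plant term only.  Intake-rate
and slope-factor defaults are illustrative configuration values, not
recommendations from any toxicological authority.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml

from .grids import RasterField

LIFETIME_YEARS = 70.0
VEG_CATEGORIES = ("leaf", "root", "fruit")


@dataclasses.dataclass
class TransferParams:
    """Simplified air+soil -> vegetable transfer (per category).

    deposition_velocity_m_per_day: particle-bound deposition onto foliage;
    interception_weathering_days: foliage interception x effective residence
    time; yield_kg_per_m2: fresh crop yield; soil_to_plant: dimensionless
    linear root-uptake factor (mg/kg plant per mg/kg soil).
    """

    deposition_velocity_m_per_day: float = 100.0
    interception_weathering_days: dict = dataclasses.field(
        default_factory=lambda: {"leaf": 5.0, "root": 0.0, "fruit": 3.0})
    yield_kg_per_m2: dict = dataclasses.field(
        default_factory=lambda: {"leaf": 2.0, "root": 3.0, "fruit": 2.5})
    # hydrophobic PAH: root uptake is weak (log Kow ~ 6)
    soil_to_plant: dict = dataclasses.field(
        default_factory=lambda: {"leaf": 0.002, "root": 0.005, "fruit": 0.001})


@dataclasses.dataclass
class ReceptorProfile:
    """Age-class receptor: intake rates, body weight, exposure duration.

    Durations of the two classes partition the 70-year lifetime
    (0-17 -> 17 y, 17-70 -> 53 y).  Intake defaults are plausible
    round numbers for a national population, not survey values.
    """

    age_class: str
    body_weight_kg: float
    water_intake_l_per_day: float
    soil_ingestion_mg_per_day: float
    inhalation_m3_per_day: float
    veg_intake_g_per_day: dict
    commercial_intake_g_per_day: dict
    self_consumption_fraction: float
    exposure_duration_years: float
    lifetime_years: float = LIFETIME_YEARS

    def __post_init__(self) -> None:
        rates = [self.body_weight_kg, self.water_intake_l_per_day,
                 self.soil_ingestion_mg_per_day, self.inhalation_m3_per_day,
                 *self.veg_intake_g_per_day.values(),
                 *self.commercial_intake_g_per_day.values()]
        if any(r < 0 for r in rates) or self.body_weight_kg <= 0:
            raise ValueError("intake rates must be nonnegative, body weight positive")
        if not 0.0 <= self.self_consumption_fraction <= 1.0:
            raise ValueError("self-consumption fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReceptorProfile":
        return cls(**d)


def default_receptors() -> list[ReceptorProfile]:
    """Two age classes, children 0-17 and adults 17-70 (durations sum to 70 y)."""
    child = ReceptorProfile(
        age_class="child_0_17", body_weight_kg=30.0,
        water_intake_l_per_day=1.0, soil_ingestion_mg_per_day=100.0,
        inhalation_m3_per_day=10.0,
        veg_intake_g_per_day={"leaf": 40.0, "root": 60.0, "fruit": 50.0},
        commercial_intake_g_per_day={"other_food": 300.0},
        self_consumption_fraction=0.25, exposure_duration_years=17.0,
    )
    adult = ReceptorProfile(
        age_class="adult_17_70", body_weight_kg=70.0,
        water_intake_l_per_day=2.0, soil_ingestion_mg_per_day=50.0,
        inhalation_m3_per_day=15.0,
        veg_intake_g_per_day={"leaf": 80.0, "root": 100.0, "fruit": 70.0},
        commercial_intake_g_per_day={"other_food": 500.0},
        self_consumption_fraction=0.25, exposure_duration_years=53.0,
    )
    return [child, adult]


def save_receptors(path, receptors: list[ReceptorProfile]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([r.to_dict() for r in receptors], fh, sort_keys=False)


def load_receptors(path) -> list[ReceptorProfile]:
    with open(path) as fh:
        return [ReceptorProfile.from_dict(d) for d in yaml.safe_load(fh)]


@dataclasses.dataclass
class SlopeFactors:
    """Cancer slope factors per route, (mg kg^-1 day^-1)^-1. Config values."""

    ingestion: float = 7.3
    inhalation: float = 3.9

    def __post_init__(self) -> None:
        if self.ingestion <= 0 or self.inhalation <= 0:
            raise ValueError("slope factors must be positive")


@dataclasses.dataclass
class MediaConcentrations:
    """Concentrations the receptor contacts. Units enforced by field name.

    air ng/m^3; soil mg/kg; water mg/L; homegrown vegetables mg/kg fresh per
    category; commercial food mg/kg per category (spatially constant).
    """

    air_ng_m3: float = 0.0
    soil_mg_kg: float = 0.0
    water_mg_l: float = 0.0
    homegrown_veg_mg_kg: dict = dataclasses.field(default_factory=dict)
    commercial_food_mg_kg: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.air_ng_m3, self.soil_mg_kg, self.water_mg_l,
                *self.homegrown_veg_mg_kg.values(),
                *self.commercial_food_mg_kg.values()]
        if any(v < 0 for v in vals):
            raise ValueError("concentrations must be nonnegative")


INGESTION_PATHWAYS = ("water", "soil", "homegrown_veg", "commercial_food")
ALL_PATHWAYS = INGESTION_PATHWAYS + ("inhalation",)


@dataclasses.dataclass
class DoseResult:
    ladd: dict  # pathway -> mg kg^-1 day^-1
    eir_ingestion: float = np.nan
    eir_inhalation: float = np.nan

    @property
    def eir_total(self) -> float:
        return self.eir_ingestion + self.eir_inhalation

    @property
    def contributions(self) -> dict:
        tot = sum(self.ladd.values())
        if tot <= 0:
            return {k: 0.0 for k in self.ladd}
        return {k: v / tot for k, v in self.ladd.items()}


def veg_transfer(
    air_ng_m3: float,
    soil_mg_kg: float,
    params: TransferParams | None = None,
) -> dict:
    """Homegrown-vegetable concentrations (mg/kg fresh) per category.

    C_veg = air deposition term + root uptake term, both linear in their
    input:  (C_air x v_dep x interception / yield) + (C_soil x BCF).
    """
    params = params or TransferParams()
    if air_ng_m3 < 0 or soil_mg_kg < 0:
        raise ValueError("concentrations must be nonnegative")
    air_mg_m3 = air_ng_m3 * 1e-6
    out = {}
    for cat in params.yield_kg_per_m2:
        y = params.yield_kg_per_m2[cat]
        if y <= 0:
            raise ValueError(f"nonpositive yield for category {cat!r}")
        dep = (air_mg_m3 * params.deposition_velocity_m_per_day
               * params.interception_weathering_days.get(cat, 0.0) / y)
        root = soil_mg_kg * params.soil_to_plant.get(cat, 0.0)
        out[cat] = dep + root
    return out


def compute_ladd(media: MediaConcentrations, receptor: ReceptorProfile) -> DoseResult:
    """Per-pathway lifetime average daily doses for one receptor.

    Homegrown vegetable intake is the receptor's vegetable intake scaled by
    the self-consumption fraction; the remaining (1 - f) of vegetable intake
    is scored against the commercial concentration of the same category when
    one is provided.  Commercial non-vegetable categories are fully
    commercial.
    """
    r = receptor
    frac_lt = r.exposure_duration_years / r.lifetime_years
    bw = r.body_weight_kg

    ladd = {}
    ladd["water"] = media.water_mg_l * r.water_intake_l_per_day * frac_lt / bw
    ladd["soil"] = media.soil_mg_kg * r.soil_ingestion_mg_per_day * 1e-6 * frac_lt / bw

    home = 0.0
    comm = 0.0
    for cat, g_day in r.veg_intake_g_per_day.items():
        kg_day = g_day * 1e-3
        c_home = media.homegrown_veg_mg_kg.get(cat, 0.0)
        c_comm = media.commercial_food_mg_kg.get(cat, 0.0)
        home += c_home * kg_day * r.self_consumption_fraction
        comm += c_comm * kg_day * (1.0 - r.self_consumption_fraction)
    for cat, g_day in r.commercial_intake_g_per_day.items():
        comm += media.commercial_food_mg_kg.get(cat, 0.0) * g_day * 1e-3
    ladd["homegrown_veg"] = home * frac_lt / bw
    ladd["commercial_food"] = comm * frac_lt / bw

    ladd["inhalation"] = (media.air_ng_m3 * 1e-6 * r.inhalation_m3_per_day
                          * frac_lt / bw)
    return DoseResult(ladd=ladd)


def compute_eir(doses: DoseResult, slope_factors: SlopeFactors | None = None) -> DoseResult:
    """Fill in excess individual risk per route (linear no-threshold)."""
    sf = slope_factors or SlopeFactors()
    ing = sum(doses.ladd[p] for p in INGESTION_PATHWAYS)
    doses.eir_ingestion = sf.ingestion * ing
    doses.eir_inhalation = sf.inhalation * doses.ladd["inhalation"]
    return doses


@dataclasses.dataclass
class ExposureMaps:
    """Per-receptor grids of LADD (per pathway) and EIR (per route, x10^6)."""

    age_class: str
    ladd: dict  # pathway -> RasterField
    eir_ingestion: RasterField
    eir_inhalation: RasterField
    eir_total: RasterField
    contributions: dict  # pathway -> mean fraction over valid cells


def map_exposure(
    air: RasterField,
    soil: RasterField,
    water: RasterField,
    receptors: list[ReceptorProfile],
    slope_factors: SlopeFactors | None = None,
    commercial_food_mg_kg: dict | None = None,
    transfer: TransferParams | None = None,
) -> list[ExposureMaps]:
    """Cellwise exposure maps for every receptor.

    Water-missing cells propagate mask_missing into ingestion and total EIR;
    air-invalid cells propagate mask_invalid into inhalation and total EIR.
    EIR grids are on the x10^6 scale.  Contribution fractions are averaged
    over cells valid in every medium.
    """
    sf = slope_factors or SlopeFactors()
    transfer = transfer or TransferParams()
    commercial = commercial_food_mg_kg or {"other_food": 2e-4}
    for r in (soil, water):
        if r.shape != air.shape:
            raise ValueError("media rasters must share the reference grid")
    shape = air.shape
    missing = water.mask_missing | soil.mask_missing | air.mask_missing
    invalid = air.mask_invalid | soil.mask_invalid | water.mask_invalid
    frac = {
        "ingestion": sf.ingestion,
        "inhalation": sf.inhalation,
    }

    results = []
    veg = {
        cat: (air.values * 1e-6 * transfer.deposition_velocity_m_per_day
              * transfer.interception_weathering_days.get(cat, 0.0)
              / transfer.yield_kg_per_m2[cat])
        + soil.values * transfer.soil_to_plant.get(cat, 0.0)
        for cat in transfer.yield_kg_per_m2
    }
    for rec in receptors:
        frac_lt = rec.exposure_duration_years / rec.lifetime_years
        bw = rec.body_weight_kg
        ladd = {}
        ladd["water"] = water.values * rec.water_intake_l_per_day * frac_lt / bw
        ladd["soil"] = soil.values * rec.soil_ingestion_mg_per_day * 1e-6 * frac_lt / bw
        home = np.zeros(shape)
        comm = 0.0
        for cat, g_day in rec.veg_intake_g_per_day.items():
            kg_day = g_day * 1e-3
            home = home + veg.get(cat, 0.0) * kg_day * rec.self_consumption_fraction
            comm += commercial.get(cat, 0.0) * kg_day * (1 - rec.self_consumption_fraction)
        for cat, g_day in rec.commercial_intake_g_per_day.items():
            comm += commercial.get(cat, 0.0) * g_day * 1e-3
        ladd["homegrown_veg"] = home * frac_lt / bw
        ladd["commercial_food"] = np.full(shape, comm * frac_lt / bw)
        ladd["inhalation"] = air.values * 1e-6 * rec.inhalation_m3_per_day * frac_lt / bw

        eir_ing = frac["ingestion"] * sum(ladd[p] for p in INGESTION_PATHWAYS) * 1e6
        eir_inh = frac["inhalation"] * ladd["inhalation"] * 1e6
        eir_tot = eir_ing + eir_inh

        def _wrap(v, miss=missing, inv=invalid):
            return RasterField(v, cell_size_km=air.cell_size_km, origin=air.origin,
                               mask_missing=miss.copy(), mask_invalid=inv.copy())

        ok = ~(missing | invalid)
        tot_ladd = sum(ladd.values())
        contrib = {}
        for p in ALL_PATHWAYS:
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(tot_ladd > 0, ladd[p] / np.where(tot_ladd > 0, tot_ladd, 1.0), 0.0)
            contrib[p] = float(np.mean(c[ok])) if ok.any() else np.nan

        results.append(ExposureMaps(
            age_class=rec.age_class,
            ladd={p: _wrap(ladd[p]) for p in ALL_PATHWAYS},
            eir_ingestion=_wrap(eir_ing),
            eir_inhalation=_wrap(eir_inh),
            eir_total=_wrap(eir_tot),
            contributions=contrib,
        ))
    return results
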