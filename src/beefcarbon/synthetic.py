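"""Reproducible synthetic case-study farms.

Generates one-farm-year records emulating the structure of a 20-farm
Western-European case-study panel: five farms per country flavour, with
grass-based low-concentrate Irish systems, low-fertilizer French suckler
systems, and intensive Italian/Spanish fattening systems (the Spanish
fattening farms on under 5 ha of land).  Suckler-to-weaning progeny are sold
at 8 months of age.

Each archetype is a set of uniform sampling bounds over farm-scale knobs
(herd size, stocking, fertilizer rate, grazing season, concentrate use);
cohort-level biology (gross energy intake, N excretion, volatile solids) is
sampled within category-typical ranges.  Herds are in steady state (opening
mass = closing mass), so live-weight gain reduces to sales minus purchases.
Sampling is uniform and uncorrelated; the generator makes no claim to the
covariance structure of real farm panels.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .domain import AnimalCategory, AnimalCohort, FarmRecord, FarmSystem, ManureSystem

Bounds = Tuple[float, float]

SALE_AGE_WEANING_MONTHS = 8.0
CALF_PURCHASE_WEIGHT = 55.0  # kg, dairy-origin calf entering a rearing system

# Per-country flavour: grazing season, fertilizer intensity, storage mix, hedges.
_COUNTRY: Dict[str, Dict[str, Bounds]] = {
    "IE": {
        "grazing_days": (210, 260),
        "fert_n_per_ha": (70, 110),
        "hedgerow_m": (800, 2500),
        "slurry_share": (0.5, 0.8),
    },
    "FR": {
        "grazing_days": (180, 235),
        "fert_n_per_ha": (35, 70),
        "hedgerow_m": (1000, 3000),
        "slurry_share": (0.3, 0.6),
    },
    "IT": {
        "grazing_days": (150, 210),
        "fert_n_per_ha": (80, 140),
        "hedgerow_m": (0, 500),
        "slurry_share": (0.6, 0.9),
    },
    "ES": {
        "grazing_days": (220, 300),
        "fert_n_per_ha": (20, 50),
        "hedgerow_m": (0, 600),
        "slurry_share": (0.4, 0.7),
    },
}

# Category-typical cohort biology: (avg LW kg, daily gain kg/d, GEI MJ/d,
# Nex kg N/yr, VS kg/d), each sampled within +/-8% of the midpoint below
# except GEI/Nex/VS which use explicit ranges.
_BIOLOGY: Dict[AnimalCategory, Dict[str, Bounds]] = {
    AnimalCategory.SUCKLER_COW: {
        "alw": (600, 660), "gain": (0.0, 0.0), "gei": (165, 195),
        "nex": (75, 95), "vs": (3.0, 3.8),
    },
    AnimalCategory.BREEDING_BULL: {
        "alw": (850, 950), "gain": (0.0, 0.1), "gei": (185, 215),
        "nex": (85, 105), "vs": (3.5, 4.2),
    },
    AnimalCategory.WEANLING: {
        "alw": (200, 240), "gain": (0.8, 1.1), "gei": (55, 75),
        "nex": (25, 35), "vs": (1.0, 1.5),
    },
    AnimalCategory.STORE: {
        "alw": (390, 450), "gain": (0.6, 0.9), "gei": (100, 125),
        "nex": (40, 55), "vs": (1.8, 2.4),
    },
    AnimalCategory.FINISHING_BULL: {
        "alw": (520, 600), "gain": (1.0, 1.4), "gei": (130, 155),
        "nex": (45, 60), "vs": (2.2, 2.8),
    },
    AnimalCategory.FINISHING_STEER: {
        "alw": (520, 600), "gain": (0.8, 1.2), "gei": (125, 150),
        "nex": (45, 60), "vs": (2.2, 2.8),
    },
    AnimalCategory.FINISHING_HEIFER: {
        "alw": (460, 540), "gain": (0.7, 1.0), "gei": (115, 140),
        "nex": (40, 55), "vs": (2.0, 2.6),
    },
    AnimalCategory.DAIRY_ORIGIN_CALF: {
        "alw": (100, 140), "gain": (0.6, 0.8), "gei": (45, 60),
        "nex": (20, 30), "vs": (0.8, 1.2),
    },
}


class ArchetypeProfile(BaseModel):
    """Sampling bounds for one farm archetype (system x country flavour)."""

    model_config = ConfigDict(frozen=True)

    system: FarmSystem
    country: str
    bounds: Dict[str, Tuple[float, float]]
    purchases: bool = False
    sale_age_months: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ArchetypeProfile":
        if self.country not in _COUNTRY:
            raise ValueError(f"unknown country flavour {self.country!r}")
        for key, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"bad bounds for {key!r}: ({lo}, {hi})")
        if self.system is FarmSystem.SUCKLER_TO_WEANING and self.sale_age_months != 8.0:
            raise ValueError("suckler_to_weaning archetypes sell progeny at 8 months")
        return self


def archetype_profile(
    system: FarmSystem, country: str, purchases: bool = False
) -> ArchetypeProfile:
    """Packaged sampling bounds for one system under one country flavour."""
    c = _COUNTRY[country]
    bounds: Dict[str, Bounds] = {
        "grazing_days": c["grazing_days"],
        "fert_n_per_ha": c["fert_n_per_ha"],
        "hedgerow_m": c["hedgerow_m"],
        "slurry_share": c["slurry_share"],
        "lime_per_ha": (0, 120),
        "diesel_per_ha": (55, 90),
    }
    sale_age = None
    if system is FarmSystem.SUCKLER_TO_WEANING:
        bounds.update(
            cows=(40, 90), area_per_cow=(0.85, 1.2), weaning_rate=(0.88, 0.94),
            sale_weight=(280, 320), conc_per_cow=(250, 450), elec_per_head=(40, 60),
        )
        sale_age = SALE_AGE_WEANING_MONTHS
    elif system is FarmSystem.SUCKLER_TO_BEEF:
        if country == "ES":
            # extensive dehesa-style holdings, the largest farmland of the panel,
            # with purchased cattle finished intensively on concentrate
            bounds.update(cows=(50, 90), area_per_cow=(2.0, 3.0), conc_per_cow=(450, 750))
        else:
            bounds.update(cows=(35, 70), area_per_cow=(1.5, 2.1), conc_per_cow=(350, 650))
        sale_weight = (480, 540) if country == "IT" else (560, 620)
        bounds.update(
            weaning_rate=(0.88, 0.94), sale_weight=sale_weight, elec_per_head=(45, 70),
        )
        if purchases:
            bounds.update(
                purchase_ratio=(0.4, 0.6), purchase_weight=(280, 320),
                purchase_sale_weight=(620, 670),
            )
    elif system is FarmSystem.DAIRY_CALF_TO_BEEF:
        bounds.update(
            calves=(60, 120), area_per_head=(0.9, 1.2), sale_weight=(550, 600),
            conc_per_head=(350, 600), elec_per_head=(25, 40),
        )
    elif system is FarmSystem.DAIRY_CALF_TO_STORE:
        bounds.update(
            calves=(60, 120), area_per_head=(0.6, 0.85), sale_weight=(400, 440),
            conc_per_head=(200, 400), elec_per_head=(20, 35),
        )
    elif system is FarmSystem.BEEF_FATTENING:
        if country in ("IT", "ES"):
            bounds.update(
                places=(150, 400) if country == "IT" else (150, 350),
                cycles=(1.1, 1.4), buy_weight=(300, 360), sell_weight=(640, 700),
                conc_per_place_cycle=(1100, 1800), elec_per_head=(30, 50),
                grazing_days=(0, 0),
            )
            if country == "ES":
                # intensive dry-lot units on under 5 ha of land, feed purchased
                bounds.update(grassland_ha=(0.0, 0.8), cropland_ha=(1.0, 4.0))
                bounds["fert_n_per_ha"] = (80, 140)
            else:
                bounds.update(cropland_per_place=(0.15, 0.30))
                bounds["fert_n_per_ha"] = (150, 200)
        else:
            bounds.update(
                places=(80, 200) if country == "IE" else (100, 250),
                cycles=(1.0, 1.25), buy_weight=(300, 360), sell_weight=(640, 700),
                conc_per_place_cycle=(500, 1000) if country == "IE" else (900, 1400),
                elec_per_head=(30, 50),
                grazing_days=(60, 120) if country == "IE" else (0, 60),
            )
            if country == "IE":
                bounds.update(grassland_per_place=(0.35, 0.55))
                bounds["fert_n_per_ha"] = (60, 100)
            else:
                bounds.update(cropland_per_place=(0.15, 0.25))
                bounds["fert_n_per_ha"] = (100, 150)
    return ArchetypeProfile(
        system=system,
        country=country,
        bounds=bounds,
        purchases=purchases,
        sale_age_months=sale_age,
    )


def _sample(rng: np.random.Generator, bounds: Dict[str, Bounds]) -> Dict[str, float]:
    return {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in sorted(bounds.items())}


def _cohort(
    rng: np.random.Generator,
    category: AnimalCategory,
    headcount: float,
    days_grazing: float,
) -> AnimalCohort:
    b = _BIOLOGY[category]
    return AnimalCohort(
        category=category,
        headcount=headcount,
        avg_live_weight=float(rng.uniform(*b["alw"])),
        daily_gain=float(rng.uniform(*b["gain"])),
        gross_energy_intake=float(rng.uniform(*b["gei"])),
        n_excretion=float(rng.uniform(*b["nex"])),
        volatile_solids=float(rng.uniform(*b["vs"])),
        days_grazing=days_grazing,
        days_housed=365.0 - days_grazing,
    )


def _herd_mass(cohorts: List[AnimalCohort]) -> float:
    return sum(c.headcount * c.avg_live_weight for c in cohorts)


def generate_farm(profile: ArchetypeProfile, seed: int) -> FarmRecord:
    """Draw one farm from an archetype; identical (profile, seed) -> identical farm."""
    rng = np.random.default_rng(seed)
    p = _sample(rng, profile.bounds)
    graz = p["grazing_days"]
    sys_ = profile.system
    cohorts: List[AnimalCohort] = []
    concentrate: Dict[str, float] = {}
    lw_sold = lw_purchased = 0.0
    grassland = cropland = 0.0

    if sys_ is FarmSystem.SUCKLER_TO_WEANING:
        cows = round(p["cows"])
        progeny = p["weaning_rate"] * cows
        presence = profile.sale_age_months / 12.0
        cohorts = [
            _cohort(rng, AnimalCategory.SUCKLER_COW, cows, graz),
            _cohort(rng, AnimalCategory.WEANLING, progeny * presence, graz),
            _cohort(rng, AnimalCategory.BREEDING_BULL, max(1.0, 0.03 * cows), graz),
        ]
        lw_sold = progeny * p["sale_weight"]
        grassland = cows * p["area_per_cow"]
        concentrate = {"compound_ration": cows * p["conc_per_cow"]}
        n_head = cows
    elif sys_ is FarmSystem.SUCKLER_TO_BEEF:
        cows = round(p["cows"])
        progeny = p["weaning_rate"] * cows
        cohorts = [
            _cohort(rng, AnimalCategory.SUCKLER_COW, cows, graz),
            _cohort(rng, AnimalCategory.WEANLING, progeny * 0.67, graz),
            _cohort(rng, AnimalCategory.STORE, progeny * 0.95, graz),
            _cohort(rng, AnimalCategory.FINISHING_STEER, progeny * 0.25, min(graz, 120)),
            _cohort(rng, AnimalCategory.BREEDING_BULL, max(1.0, 0.03 * cows), graz),
        ]
        lw_sold = progeny * p["sale_weight"]
        grassland = cows * p["area_per_cow"]
        concentrate = {"compound_ration": cows * p["conc_per_cow"]}
        if profile.purchases:
            bought = p["purchase_ratio"] * cows
            cohorts.append(
                _cohort(rng, AnimalCategory.FINISHING_BULL, bought * 0.6, min(graz, 90))
            )
            lw_purchased = bought * p["purchase_weight"]
            lw_sold += bought * p["purchase_sale_weight"]
            concentrate["cereal_mix"] = bought * 900.0
        n_head = cows
    elif sys_ in (FarmSystem.DAIRY_CALF_TO_BEEF, FarmSystem.DAIRY_CALF_TO_STORE):
        calves = round(p["calves"])
        to_beef = sys_ is FarmSystem.DAIRY_CALF_TO_BEEF
        cohorts = [_cohort(rng, AnimalCategory.DAIRY_ORIGIN_CALF, 0.9 * calves, graz)]
        if to_beef:
            cohorts += [
                _cohort(rng, AnimalCategory.STORE, 0.85 * calves, graz),
                _cohort(rng, AnimalCategory.FINISHING_STEER, 0.2 * calves, min(graz, 120)),
            ]
        else:
            cohorts.append(_cohort(rng, AnimalCategory.STORE, 0.4 * calves, graz))
        lw_purchased = calves * CALF_PURCHASE_WEIGHT
        lw_sold = 0.93 * calves * p["sale_weight"]
        grassland = calves * p["area_per_head"]
        conc_total = calves * p["conc_per_head"]
        concentrate = {"compound_ration": 0.7 * conc_total, "cereal_mix": 0.3 * conc_total}
        n_head = calves
    elif sys_ is FarmSystem.BEEF_FATTENING:
        places = round(p["places"])
        throughput = places * p["cycles"]
        cohorts = [_cohort(rng, AnimalCategory.FINISHING_BULL, 0.92 * places, graz)]
        lw_purchased = throughput * p["buy_weight"]
        lw_sold = throughput * p["sell_weight"]
        if "grassland_per_place" in p:
            grassland = places * p["grassland_per_place"]
        if "cropland_per_place" in p:
            cropland = places * p["cropland_per_place"]
        if "grassland_ha" in p:
            grassland = p["grassland_ha"]
        if "cropland_ha" in p:
            cropland = p["cropland_ha"]
        conc_total = throughput * p["conc_per_place_cycle"]
        concentrate = {
            "compound_ration": 0.55 * conc_total,
            "cereal_mix": 0.30 * conc_total,
            "protein_mix": 0.15 * conc_total,
        }
        n_head = places
    else:  # pragma: no cover - enum is exhaustive
        raise AssertionError(sys_)

    herd_mass = _herd_mass(cohorts)
    fert_area = grassland + cropland
    slurry = p["slurry_share"]
    return FarmRecord(
        farm_id=f"{profile.country}_{sys_.value}",
        system=sys_,
        grassland_area=grassland,
        cropland_area=cropland,
        cohorts=cohorts,
        lw_sold=lw_sold,
        lw_purchased=lw_purchased,
        lw_opening=herd_mass,
        lw_closing=herd_mass,
        fert_n_applied=fert_area * p["fert_n_per_ha"],
        lime_applied=fert_area * p["lime_per_ha"],
        concentrate_fed=concentrate,
        diesel_used=max(fert_area, 0.02 * n_head) * p["diesel_per_ha"],
        electricity_used=n_head * p["elec_per_head"],
        manure_system_shares={
            ManureSystem.SLURRY_TANK: slurry,
            ManureSystem.SOLID_STORAGE: 1.0 - slurry,
        },
        hedgerow_length=p["hedgerow_m"],
    )


# The 20-farm panel: five farms per country, system mix per the case-study design.
SUITE_DESIGN: List[Tuple[str, FarmSystem, bool]] = [
    ("IE1", FarmSystem.SUCKLER_TO_BEEF, False),
    ("IE2", FarmSystem.SUCKLER_TO_WEANING, False),
    ("IE3", FarmSystem.DAIRY_CALF_TO_BEEF, False),
    ("IE4", FarmSystem.DAIRY_CALF_TO_STORE, False),
    ("IE5", FarmSystem.BEEF_FATTENING, False),
    ("FR1", FarmSystem.SUCKLER_TO_WEANING, False),
    ("FR2", FarmSystem.SUCKLER_TO_WEANING, False),
    ("FR3", FarmSystem.SUCKLER_TO_BEEF, True),
    ("FR4", FarmSystem.BEEF_FATTENING, False),
    ("FR5", FarmSystem.SUCKLER_TO_BEEF, False),
    ("IT1", FarmSystem.BEEF_FATTENING, False),
    ("IT2", FarmSystem.BEEF_FATTENING, False),
    ("IT3", FarmSystem.BEEF_FATTENING, False),
    ("IT4", FarmSystem.BEEF_FATTENING, False),
    ("IT5", FarmSystem.SUCKLER_TO_BEEF, False),
    ("ES1", FarmSystem.SUCKLER_TO_BEEF, True),
    ("ES2", FarmSystem.BEEF_FATTENING, False),
    ("ES3", FarmSystem.SUCKLER_TO_BEEF, True),
    ("ES4", FarmSystem.SUCKLER_TO_BEEF, True),
    ("ES5", FarmSystem.BEEF_FATTENING, False),
]


def generate_suite(seed: int) -> List[FarmRecord]:
    """Generate the packaged 20-farm synthetic panel (5 per country flavour)."""
    farms = []
    for i, (farm_id, system, purchases) in enumerate(SUITE_DESIGN):
        profile = archetype_profile(system, farm_id[:2], purchases)
        farm = generate_farm(profile, (seed * 1000 + i) % (2**31))
        farm = farm.model_copy(update={"farm_id": farm_id})
        farms.append(farm)
    return farms
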