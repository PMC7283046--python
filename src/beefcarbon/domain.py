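"""Domain types for whole-farm beef greenhouse-gas accounting.

The types here describe one farm-year of activity data (herd, land, inputs,
manure management), the emission-factor sets that turn activity data into gas
masses, and the containers the engine fills: a per-source/per-gas emission
inventory and a carbon-footprint result expressed per unit of live-weight
gain (LWG), live weight sold and carcass weight (CW).

Units are SI base units throughout: kg, ha, m, MJ, L, kWh, per year.
Percentages are carried on the 0-100 scale.
"""

from __future__ import annotations

import enum
import math
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ValidationError

DRESSING_PERCENTAGE = 0.55
"""Carcass weight as a fraction of live weight (55% dressing)."""

DAYS_PER_YEAR = 365


class AnimalCategory(str, enum.Enum):
    SUCKLER_COW = "suckler_cow"
    DAIRY_ORIGIN_CALF = "dairy_origin_calf"
    WEANLING = "weanling"
    STORE = "store"
    FINISHING_BULL = "finishing_bull"
    FINISHING_STEER = "finishing_steer"
    FINISHING_HEIFER = "finishing_heifer"
    BREEDING_BULL = "breeding_bull"


class FarmSystem(str, enum.Enum):
    SUCKLER_TO_WEANING = "suckler_to_weaning"
    SUCKLER_TO_BEEF = "suckler_to_beef"
    DAIRY_CALF_TO_BEEF = "dairy_calf_to_beef"
    DAIRY_CALF_TO_STORE = "dairy_calf_to_store"
    BEEF_FATTENING = "beef_fattening"


class ManureSystem(str, enum.Enum):
    SLURRY_TANK = "slurry_tank"
    SOLID_STORAGE = "solid_storage"
    PASTURE_DEPOSITION = "pasture_deposition"


class Source(str, enum.Enum):
    """Emission sources within the cradle-to-farm-gate boundary."""

    ENTERIC = "enteric"
    MANURE_STORAGE = "manure_storage"
    MANURE_SPREADING = "manure_spreading"
    GRAZING_RETURNS = "grazing_returns"
    SOIL_FERTILIZER = "soil_fertilizer"
    INDIRECT_N = "indirect_n"
    LIMING = "liming"
    FERT_MANUFACTURE = "fert_manufacture"
    CONCENTRATE = "concentrate"
    ENERGY = "energy"
    OTHER = "other"


class Gas(str, enum.Enum):
    CH4 = "CH4"
    N2O = "N2O"
    CO2 = "CO2"


class AnimalCohort(BaseModel):
    """An average-annual group of animals of one category.

    ``headcount`` is the average number of animals present over the year, so a
    calf crop present for eight months counts 8/12 of a head per calf.
    ``gross_energy_intake`` (GEI) drives tier-2 enteric methane; ``n_excretion``
    and ``volatile_solids`` drive the nitrogen and manure-methane pathways.
    """

    model_config = ConfigDict(validate_assignment=True)

    category: AnimalCategory
    headcount: float = Field(ge=0)
    avg_live_weight: float = Field(ge=0, description="kg")
    daily_gain: float = Field(ge=0, description="kg/day")
    gross_energy_intake: float = Field(ge=0, description="MJ/head/day")
    n_excretion: float = Field(ge=0, description="kg N/head/year")
    volatile_solids: float = Field(ge=0, description="kg VS/head/day")
    days_grazing: float = Field(ge=0, le=DAYS_PER_YEAR, description="days/year")
    days_housed: float = Field(ge=0, le=DAYS_PER_YEAR, description="days/year")

    @property
    def grazing_fraction(self) -> float:
        return self.days_grazing / DAYS_PER_YEAR

    @property
    def housed_fraction(self) -> float:
        return self.days_housed / DAYS_PER_YEAR


class FarmRecord(BaseModel):
    """One farm-year of activity data for a beef system.

    Weight flows follow the on-farm live-weight-gain convention: purchased
    animals enter with zero embedded burden (the boundary excludes emissions
    on the farm of origin) and their purchase weight is netted out of LWG.
    """

    model_config = ConfigDict(validate_assignment=True)

    farm_id: str
    system: FarmSystem
    grassland_area: float = Field(ge=0, description="ha")
    cropland_area: float = Field(default=0.0, ge=0, description="ha")
    cohorts: List[AnimalCohort] = Field(default_factory=list)
    lw_sold: float = Field(default=0.0, ge=0, description="kg LW/year")
    lw_purchased: float = Field(default=0.0, ge=0, description="kg LW/year")
    lw_opening: float = Field(default=0.0, ge=0, description="kg LW")
    lw_closing: float = Field(default=0.0, ge=0, description="kg LW")
    fert_n_applied: float = Field(default=0.0, ge=0, description="kg N/year")
    lime_applied: float = Field(default=0.0, ge=0, description="kg/year")
    concentrate_fed: Dict[str, float] = Field(default_factory=dict, description="type -> kg/year")
    diesel_used: float = Field(default=0.0, ge=0, description="L/year")
    electricity_used: float = Field(default=0.0, ge=0, description="kWh/year")
    manure_system_shares: Dict[ManureSystem, float] = Field(default_factory=dict)
    hedgerow_length: float = Field(default=0.0, ge=0, description="m")

    @property
    def total_area(self) -> float:
        return self.grassland_area + self.cropland_area


class EmissionFactorSet(BaseModel):
    """A named, region-flavoured collection of loss and embedded-emission factors.

    One set represents one regional carbon-footprint model flavour.  Sets
    differ mainly in how enteric methane is estimated (a tier-2 gross-energy
    equation with a methane conversion factor ``ym``, or a per-head table) and
    in the embedded factors for purchased concentrate — the two dimensions on
    which regional beef models diverge most.
    """

    model_config = ConfigDict(validate_assignment=True)

    name: str
    enteric_mode: str = Field(pattern="^(tier2|per_head_table)$")
    ym: float = Field(default=6.5, ge=0, description="% of GEI lost as enteric CH4")
    per_head_enteric: Dict[AnimalCategory, float] = Field(
        default_factory=dict, description="kg CH4/head/year"
    )
    b0: float = Field(ge=0, description="m3 CH4/kg VS (max CH4 producing capacity)")
    mcf: Dict[ManureSystem, float] = Field(description="methane conversion factor, %")
    ef3_storage: Dict[ManureSystem, float] = Field(description="kg N2O-N/kg N stored")
    ef3_prp: float = Field(ge=0, description="kg N2O-N/kg N deposited at pasture")
    ef1: float = Field(ge=0, description="kg N2O-N/kg N applied to soil")
    frac_gas_fert: float = Field(ge=0, le=1, description="fraction of fertilizer N volatilized")
    frac_gas_manure: float = Field(ge=0, le=1, description="fraction of manure N volatilized")
    frac_leach: float = Field(ge=0, le=1, description="fraction of N leached")
    ef4: float = Field(ge=0, description="kg N2O-N/kg N volatilized")
    ef5: float = Field(ge=0, description="kg N2O-N/kg N leached")
    ef_lime: float = Field(ge=0, description="kg CO2/kg lime")
    ef_fert_manufacture: float = Field(ge=0, description="kg CO2e/kg N")
    ef_concentrate: Dict[str, float] = Field(description="type -> kg CO2e/kg")
    ef_diesel: float = Field(ge=0, description="kg CO2e/L")
    ef_electricity: float = Field(ge=0, description="kg CO2e/kWh")
    seq_rate_grassland: float = Field(ge=0, description="kg CO2e/ha/year")
    seq_rate_hedgerow: float = Field(ge=0, description="kg CO2e/m/year")

    @model_validator(mode="after")
    def _check(self) -> "EmissionFactorSet":
        if self.enteric_mode == "tier2" and not (0 < self.ym < 15):
            raise ValueError(f"ym must lie in (0, 15) %% for tier2 mode, got {self.ym}")
        if self.enteric_mode == "per_head_table" and not self.per_head_enteric:
            raise ValueError("per_head_table mode requires a per_head_enteric table")
        for sys_, v in self.mcf.items():
            if not 0 <= v <= 100:
                raise ValueError(f"mcf[{sys_.value}] must lie in [0, 100] %%, got {v}")
        for sys_, v in self.ef3_storage.items():
            if v < 0:
                raise ValueError(f"ef3_storage[{sys_.value}] must be >= 0, got {v}")
        for typ, v in self.ef_concentrate.items():
            if v < 0:
                raise ValueError(f"ef_concentrate[{typ}] must be >= 0, got {v}")
        return self


class GWPSet(BaseModel):
    """Global warming potentials used to aggregate gas masses to CO2e.

    Defaults are the 100-year values the framework standardizes on:
    25 for CH4, 298 for N2O and 1 for CO2.
    """

    gwp_ch4: float = Field(default=25.0, gt=0)
    gwp_n2o: float = Field(default=298.0, gt=0)
    gwp_co2: float = Field(default=1.0, gt=0)
    horizon: float = Field(default=100.0, gt=0, description="years")

    def factor(self, gas: Gas) -> float:
        return {Gas.CH4: self.gwp_ch4, Gas.N2O: self.gwp_n2o, Gas.CO2: self.gwp_co2}[gas]


class EmissionInventory:
    """Per-source, per-gas annual gas masses (kg/year) for one farm.

    Off-farm sources whose factors are only available pre-aggregated in CO2e
    are stored under gas CO2 with the (source, gas) key added to
    ``co2e_preaggregated``; aggregation then weights them by exactly 1.
    """

    def __init__(self) -> None:
        self.entries: Dict[Tuple[Source, Gas], float] = {}
        self.co2e_preaggregated: set[Tuple[Source, Gas]] = set()

    def add(self, source: Source, gas: Gas, mass: float, *, preaggregated: bool = False) -> None:
        if mass < 0:
            raise ValidationError(f"negative mass for ({source.value}, {gas.value}): {mass}")
        key = (source, gas)
        self.entries[key] = self.entries.get(key, 0.0) + mass
        if preaggregated:
            self.co2e_preaggregated.add(key)

    def get(self, source: Source, gas: Gas) -> float:
        return self.entries.get((source, gas), 0.0)

    def scaled(self, factors: Mapping[Tuple[Source, Gas], float]) -> "EmissionInventory":
        """Return a copy with each (source, gas) mass multiplied by its factor."""
        out = EmissionInventory()
        for key, mass in self.entries.items():
            out.entries[key] = mass * factors.get(key, 1.0)
        out.co2e_preaggregated = set(self.co2e_preaggregated)
        return out

    def sources(self) -> Iterable[Source]:
        return sorted({s for s, _ in self.entries}, key=lambda s: s.value)

    def total_by_gas(self, gas: Gas) -> float:
        return sum(m for (s, g), m in self.entries.items() if g is gas)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmissionInventory):
            return NotImplemented
        keys = set(self.entries) | set(other.entries)
        return all(
            math.isclose(self.entries.get(k, 0.0), other.entries.get(k, 0.0), abs_tol=1e-9)
            for k in keys
        )


class FootprintResult(BaseModel):
    """Gross and net carbon footprints for one farm under one factor set.

    ``net_total`` is gross emissions less carbon sequestration; a negative net
    (sequestration exceeding gross) is permitted and flagged, never clamped.
    The carcass-weight footprint divides the per-LW-sold value by the 55%
    dressing percentage.
    """

    farm_id: str
    set_name: str
    gross_total: float = Field(description="kg CO2e/year")
    sequestration: float = Field(ge=0, description="kg CO2e/year")
    net_total: float = Field(description="kg CO2e/year")
    lwg: float = Field(description="kg LW/year")
    gross_per_lwg: float = Field(description="kg CO2e/kg LWG")
    net_per_lwg: float = Field(description="kg CO2e/kg LWG")
    per_lw_sold: float = Field(description="kg CO2e/kg LW sold (gross)")
    per_cw: float = Field(description="kg CO2e/kg CW (gross)")
    profile: Dict[Source, float] = Field(description="source -> % of gross_total")

    @property
    def negative_net(self) -> bool:
        return self.net_total < 0


class MitigationMeasure(BaseModel):
    """One catalogue entry of the mitigation plan.

    ``parameter_override`` measures re-run the engine with engine or farm
    parameters replaced (e.g. a methane-inhibiting feed additive capping
    ``ym``); ``intensity_delta`` measures scale named gas masses of the
    affected sources by a percentage (negative = reduction).  Measures whose
    reduction level is highly uncertain carry ``uncertainty_flag``.
    """

    name: str
    mechanism: str = Field(pattern="^(parameter_override|intensity_delta)$")
    category: str = "other"
    overrides: Optional[Dict[str, float]] = None
    deltas: Optional[Dict[Gas, float]] = None
    affected_sources: List[Source] = Field(default_factory=list)
    uncertainty_flag: bool = False
    applicable_systems: List[FarmSystem] = Field(default_factory=lambda: list(FarmSystem))

    @model_validator(mode="after")
    def _check(self) -> "MitigationMeasure":
        if (self.overrides is None) == (self.deltas is None):
            raise ValueError("exactly one of overrides/deltas must be populated")
        if self.mechanism == "parameter_override" and self.overrides is None:
            raise ValueError("parameter_override measures need overrides")
        if self.mechanism == "intensity_delta":
            if self.deltas is None:
                raise ValueError("intensity_delta measures need deltas")
            if not self.affected_sources:
                raise ValueError("intensity_delta measures need affected_sources")
            for gas, d in self.deltas.items():
                if not -100 <= d <= 100:
                    raise ValueError(f"delta for {gas.value} outside [-100, 100]: {d}")
        return self

    def applies_to(self, system: FarmSystem) -> bool:
        return system in self.applicable_systems


SHARE_TOL = 1e-9


def validate_farm(farm: FarmRecord) -> List[str]:
    """Check cross-field invariants of a farm record.

    Returns a list of human-readable findings, one per violated rule, each
    naming the offending field; an empty list means the record is internally
    consistent.  Scalar sign constraints are enforced at parse time by the
    model itself, so the checks here cover only relationships between fields.
    """
    findings: List[str] = []
    if farm.manure_system_shares:
        total = sum(farm.manure_system_shares.values())
        if abs(total - 1.0) > SHARE_TOL:
            findings.append(
                f"manure_system_shares: values must sum to 1, got {total:.6g}"
            )
        for sys_, share in farm.manure_system_shares.items():
            if share < 0:
                findings.append(f"manure_system_shares[{sys_.value}]: negative share {share}")
    for i, cohort in enumerate(farm.cohorts):
        label = f"cohorts[{i}] ({cohort.category.value})"
        if abs(cohort.days_grazing + cohort.days_housed - DAYS_PER_YEAR) > 1e-6:
            findings.append(
                f"{label}: days_grazing + days_housed must equal {DAYS_PER_YEAR}, "
                f"got {cohort.days_grazing + cohort.days_housed:.6g}"
            )
        if cohort.headcount > 0 and cohort.gross_energy_intake <= 0:
            findings.append(f"{label}: gross_energy_intake must be > 0 when headcount > 0")
    if farm.cohorts and not farm.manure_system_shares:
        findings.append("manure_system_shares: required when livestock are present")
    return findings
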