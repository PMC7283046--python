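"""Cradle-to-farm-gate emission computations.

Each public function computes one emission source of the whole-farm boundary
(enteric fermentation, manure storage and spreading, grazing returns, soil
and indirect nitrogen pathways, liming, energy, and embedded off-farm
emissions of purchased inputs), and :func:`build_inventory` assembles them all
into one :class:`~beefcarbon.domain.EmissionInventory`.  Carbon sequestration
by grassland and hedgerows is computed separately and never netted inside the
inventory, so both gross and net totals stay reportable.

Every source operation is linear (homogeneous of degree 1) in its activity
datum: headcount, kg N, L of fuel, kg of feed.  The IPCC constants used are
the gross energy density of methane (55.65 MJ/kg), the density of methane
(0.67 kg/m3) and the N2O-N to N2O mass ratio (44/28).

On manure-time apportionment: nitrogen and volatile solids excreted during
the grazing period (``days_grazing / 365``) are deposited at pasture and
attract the pasture emission factors; the housed remainder is split between
storage systems by the farm's ``manure_system_shares`` (renormalized over the
non-pasture systems).  Stored manure N is subsequently field-spread and
routed through the soil EF1 pathway under the ``manure_spreading`` source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

from .domain import (
    AnimalCohort,
    EmissionFactorSet,
    EmissionInventory,
    FarmRecord,
    Gas,
    ManureSystem,
    Source,
    validate_farm,
)
from .errors import DomainError, FactorLookupError, ValidationError

CH4_ENERGY_DENSITY = 55.65  # MJ per kg CH4
CH4_DENSITY = 0.67  # kg CH4 per m3
N2O_N_TO_N2O = 44.0 / 28.0
DAYS = 365.0
SHARE_TOL = 1e-9


@dataclass
class SourceResult:
    """Annual mass of one gas from one source, optionally detailed per cohort."""

    source: Source
    gas: Gas
    mass: float
    per_head_detail: Optional[Dict[str, float]] = None
    preaggregated: bool = False

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise DomainError(f"negative mass for {self.source.value}: {self.mass}")


def enteric_ch4_tier2(cohort: AnimalCohort, ym: float) -> SourceResult:
    """Tier-2 enteric methane: GEI x (Ym/100) x 365 / 55.65, per head.

    ``ym`` is the methane conversion factor, the percentage of gross energy
    intake lost as methane.
    """
    if cohort.gross_energy_intake < 0:
        raise DomainError(f"gross_energy_intake must be >= 0, got {cohort.gross_energy_intake}")
    if not 0 <= ym < 15:
        raise DomainError(f"ym must lie in [0, 15) %, got {ym}")
    per_head = cohort.gross_energy_intake * (ym / 100.0) * DAYS / CH4_ENERGY_DENSITY
    total = per_head * cohort.headcount
    return SourceResult(Source.ENTERIC, Gas.CH4, total, {cohort.category.value: total})


def enteric_ch4_per_head(cohort: AnimalCohort, table: Mapping[object, float]) -> SourceResult:
    """Per-head (tier-3 style) enteric methane from a category lookup table."""
    key = cohort.category
    if key not in table and key.value not in table:
        raise FactorLookupError(
            f"no per-head enteric factor for category {key.value!r}"
        )
    factor = table[key] if key in table else table[key.value]
    total = factor * cohort.headcount
    return SourceResult(Source.ENTERIC, Gas.CH4, total, {cohort.category.value: total})


def _effective_system_fractions(
    cohort: AnimalCohort, shares: Mapping[ManureSystem, float]
) -> Dict[ManureSystem, float]:
    """Time-apportioned manure-system fractions for one cohort.

    The grazing fraction of the year goes to pasture deposition; the housed
    fraction is distributed over the non-pasture storage shares, renormalized.
    A farm whose shares list only pasture deposition defaults housed manure to
    solid storage.
    """
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"manure_system_shares must sum to 1, got {total:.6g}")
    graz = cohort.grazing_fraction
    housed = cohort.housed_fraction
    stored = {
        s: v for s, v in shares.items() if s is not ManureSystem.PASTURE_DEPOSITION and v > 0
    }
    denom = sum(stored.values())
    out = {ManureSystem.PASTURE_DEPOSITION: graz}
    if housed > 0:
        if denom > 0:
            for s, v in stored.items():
                out[s] = housed * v / denom
        else:
            out[ManureSystem.SOLID_STORAGE] = housed
    return out


def manure_ch4(
    cohort: AnimalCohort,
    shares: Mapping[ManureSystem, float],
    efs: EmissionFactorSet,
) -> SourceResult:
    """Manure-management methane: VS x 365 x B0 x 0.67 x MCF/100 per system."""
    fractions = _effective_system_fractions(cohort, shares)
    capacity = cohort.volatile_solids * DAYS * efs.b0 * CH4_DENSITY  # kg CH4 at MCF=100%
    per_head = 0.0
    for system, frac in fractions.items():
        if system not in efs.mcf:
            raise FactorLookupError(f"no MCF for manure system {system.value!r}")
        per_head += capacity * frac * efs.mcf[system] / 100.0
    total = per_head * cohort.headcount
    return SourceResult(Source.MANURE_STORAGE, Gas.CH4, total, {cohort.category.value: total})


def manure_n2o(
    cohort: AnimalCohort,
    shares: Mapping[ManureSystem, float],
    efs: EmissionFactorSet,
) -> Tuple[SourceResult, SourceResult]:
    """Direct N2O from stored manure and from its subsequent field spreading.

    Only nitrogen excreted while housed enters storage; the same nitrogen is
    later spread on-farm and attracts the soil EF1 under ``manure_spreading``.
    Returns (storage, spreading) results.
    """
    if cohort.n_excretion < 0:
        raise DomainError(f"n_excretion must be >= 0, got {cohort.n_excretion}")
    fractions = _effective_system_fractions(cohort, shares)
    n_housed = cohort.n_excretion * cohort.housed_fraction
    storage_n2o = 0.0
    for system, frac in fractions.items():
        if system is ManureSystem.PASTURE_DEPOSITION:
            continue
        if system not in efs.ef3_storage:
            raise FactorLookupError(f"no EF3 for manure system {system.value!r}")
        storage_n2o += cohort.n_excretion * frac * efs.ef3_storage[system] * N2O_N_TO_N2O
    spreading_n2o = n_housed * efs.ef1 * N2O_N_TO_N2O
    c = cohort.category.value
    return (
        SourceResult(
            Source.MANURE_STORAGE,
            Gas.N2O,
            storage_n2o * cohort.headcount,
            {c: storage_n2o * cohort.headcount},
        ),
        SourceResult(
            Source.MANURE_SPREADING,
            Gas.N2O,
            spreading_n2o * cohort.headcount,
            {c: spreading_n2o * cohort.headcount},
        ),
    )


def grazing_n2o(cohort: AnimalCohort, efs: EmissionFactorSet) -> SourceResult:
    """N2O from excreta deposited by grazing cattle (pasture, range and paddock)."""
    if cohort.days_grazing < 0:
        raise DomainError(f"days_grazing must be >= 0, got {cohort.days_grazing}")
    per_head = cohort.n_excretion * cohort.grazing_fraction * efs.ef3_prp * N2O_N_TO_N2O
    total = per_head * cohort.headcount
    return SourceResult(Source.GRAZING_RETURNS, Gas.N2O, total, {cohort.category.value: total})


def soil_n2o_fertilizer(
    fert_n: float, spread_manure_n: float, efs: EmissionFactorSet
) -> SourceResult:
    """Direct soil N2O from applied nitrogen: (fertilizer N + spread manure N) x EF1."""
    if fert_n < 0 or spread_manure_n < 0:
        raise DomainError("applied N must be >= 0")
    mass = (fert_n + spread_manure_n) * efs.ef1 * N2O_N_TO_N2O
    return SourceResult(Source.SOIL_FERTILIZER, Gas.N2O, mass)


def indirect_n2o(
    n_by_pathway: Mapping[str, float], efs: EmissionFactorSet
) -> SourceResult:
    """Indirect N2O from ammonia volatilization and nitrate leaching.

    ``n_by_pathway`` carries ``fertilizer_n`` (synthetic N applied) and
    ``manure_n`` (total N excreted); each volatilizes at its own Frac_gas,
    both leach at Frac_leach.
    """
    fert_n = n_by_pathway.get("fertilizer_n", 0.0)
    manure_n = n_by_pathway.get("manure_n", 0.0)
    if fert_n < 0 or manure_n < 0:
        raise DomainError("pathway N must be >= 0")
    volatilized = fert_n * efs.frac_gas_fert + manure_n * efs.frac_gas_manure
    leached = (fert_n + manure_n) * efs.frac_leach
    mass = (volatilized * efs.ef4 + leached * efs.ef5) * N2O_N_TO_N2O
    return SourceResult(Source.INDIRECT_N, Gas.N2O, mass)


def liming_and_fuel_co2(
    lime: float, diesel: float, efs: EmissionFactorSet
) -> Tuple[SourceResult, SourceResult]:
    """On-farm CO2 from limestone application and diesel combustion."""
    if lime < 0 or diesel < 0:
        raise DomainError("lime and diesel must be >= 0")
    return (
        SourceResult(Source.LIMING, Gas.CO2, lime * efs.ef_lime),
        SourceResult(Source.ENERGY, Gas.CO2, diesel * efs.ef_diesel),
    )


def offfarm_co2e(farm: FarmRecord, efs: EmissionFactorSet) -> Tuple[SourceResult, ...]:
    """Embedded emissions of purchased inputs, pre-aggregated in CO2e.

    Fertilizer manufacture, concentrate production and electricity generation
    come from external databases in CO2e only; they are stored under gas CO2
    with the pre-aggregated flag so GWP weighting multiplies them by 1.
    """
    conc_total = 0.0
    for typ, mass in farm.concentrate_fed.items():
        if mass < 0:
            raise DomainError(f"concentrate_fed[{typ}] must be >= 0, got {mass}")
        if typ not in efs.ef_concentrate:
            raise FactorLookupError(
                f"no embedded factor for concentrate type {typ!r} in set {efs.name!r}"
            )
        conc_total += mass * efs.ef_concentrate[typ]
    return (
        SourceResult(
            Source.FERT_MANUFACTURE,
            Gas.CO2,
            farm.fert_n_applied * efs.ef_fert_manufacture,
            preaggregated=True,
        ),
        SourceResult(Source.CONCENTRATE, Gas.CO2, conc_total, preaggregated=True),
        SourceResult(
            Source.ENERGY,
            Gas.CO2,
            farm.electricity_used * efs.ef_electricity,
            preaggregated=True,
        ),
    )


def sequestration(farm: FarmRecord, efs: EmissionFactorSet) -> float:
    """Annual carbon removal (kg CO2e/yr) by grassland soils and hedgerows."""
    if farm.grassland_area < 0 or farm.hedgerow_length < 0:
        raise DomainError("areas and lengths must be >= 0")
    return (
        farm.grassland_area * efs.seq_rate_grassland
        + farm.hedgerow_length * efs.seq_rate_hedgerow
    )


def build_inventory(farm: FarmRecord, efs: EmissionFactorSet) -> EmissionInventory:
    """Assemble the full per-source, per-gas inventory for one farm-year.

    Purchased animals contribute only the emissions of their residence on
    this farm (they appear in the cohorts); no upstream burden is imported.
    Spread manure N is handled inside the manure pathway, so the soil
    fertilizer term here covers synthetic N only (no double counting).
    """
    findings = validate_farm(farm)
    if findings:
        raise ValidationError(
            f"farm {farm.farm_id!r} failed validation: " + "; ".join(findings)
        )
    inv = EmissionInventory()
    total_nex = 0.0
    for cohort in farm.cohorts:
        if cohort.headcount == 0:
            continue
        if efs.enteric_mode == "tier2":
            ent = enteric_ch4_tier2(cohort, efs.ym)
        else:
            ent = enteric_ch4_per_head(cohort, efs.per_head_enteric)
        inv.add(ent.source, ent.gas, ent.mass)
        mch4 = manure_ch4(cohort, farm.manure_system_shares, efs)
        inv.add(mch4.source, mch4.gas, mch4.mass)
        storage, spreading = manure_n2o(cohort, farm.manure_system_shares, efs)
        inv.add(storage.source, storage.gas, storage.mass)
        inv.add(spreading.source, spreading.gas, spreading.mass)
        graz = grazing_n2o(cohort, efs)
        inv.add(graz.source, graz.gas, graz.mass)
        total_nex += cohort.n_excretion * cohort.headcount
    soil = soil_n2o_fertilizer(farm.fert_n_applied, 0.0, efs)
    inv.add(soil.source, soil.gas, soil.mass)
    indirect = indirect_n2o(
        {"fertilizer_n": farm.fert_n_applied, "manure_n": total_nex}, efs
    )
    inv.add(indirect.source, indirect.gas, indirect.mass)
    lime, fuel = liming_and_fuel_co2(farm.lime_applied, farm.diesel_used, efs)
    inv.add(lime.source, lime.gas, lime.mass)
    inv.add(fuel.source, fuel.gas, fuel.mass)
    for res in offfarm_co2e(farm, efs):
        inv.add(res.source, res.gas, res.mass, preaggregated=res.preaggregated)
    return inv


def total_n2o_n(inv: EmissionInventory) -> float:
    """Total N2O-N (kg N/yr) emitted across all pathways of an inventory."""
    return inv.total_by_gas(Gas.N2O) / N2O_N_TO_N2O
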