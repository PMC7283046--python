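"""CO2e aggregation and carbon-footprint computation.

The functional unit is on-farm live-weight gain:

    LWG = (lw_sold + lw_closing) - (lw_purchased + lw_opening)

so purchased animals contribute no upstream burden and their purchase weight
is netted out.  The gross footprint relates GWP100-weighted gross emissions
to LWG; the net footprint subtracts grassland and hedgerow sequestration
first.  A carcass-weight basis divides the per-LW-sold footprint by the 55%
dressing percentage.
"""

from __future__ import annotations

import math
from typing import Dict, Optional

from .domain import (
    DRESSING_PERCENTAGE,
    EmissionFactorSet,
    EmissionInventory,
    FarmRecord,
    FootprintResult,
    Gas,
    GWPSet,
    Source,
)
from . import engine
from .errors import DomainError, FootprintUndefinedError

PROFILE_TOL = 1e-6


def co2e_aggregate(inv: EmissionInventory, gwp: Optional[GWPSet] = None) -> float:
    """Weight every inventory entry by its GWP and sum to kg CO2e/year.

    Entries flagged as pre-aggregated CO2e are multiplied by exactly 1
    regardless of the CO2 weight in force.
    """
    gwp = gwp or GWPSet()
    total = 0.0
    for (source, gas), mass in inv.entries.items():
        if (source, gas) in inv.co2e_preaggregated:
            total += mass
        else:
            total += mass * gwp.factor(gas)
    return total


def compute_lwg(farm: FarmRecord) -> float:
    """On-farm live-weight gain (kg/year); raises when non-positive."""
    lwg = (farm.lw_sold + farm.lw_closing) - (farm.lw_purchased + farm.lw_opening)
    if lwg <= 0:
        raise FootprintUndefinedError(
            f"farm {farm.farm_id!r}: live-weight gain is {lwg:.6g} kg/yr; "
            "a per-LWG footprint is undefined"
        )
    return lwg


def allocate(total_co2e: float, beef_fraction: float = 1.0) -> float:
    """Allocate farm emissions to the beef output.

    Beef-only farms allocate everything to live weight (fraction 1); a dairy
    enterprise sharing the holding would send most cow emissions to milk.
    """
    if not 0.0 <= beef_fraction <= 1.0:
        raise DomainError(f"beef_fraction must lie in [0, 1], got {beef_fraction}")
    return total_co2e * beef_fraction


def emission_profile(
    inv: EmissionInventory, gwp: Optional[GWPSet] = None
) -> Dict[Source, float]:
    """Percentage share of gross CO2e contributed by each source; sums to 100."""
    gwp = gwp or GWPSet()
    by_source: Dict[Source, float] = {}
    for (source, gas), mass in inv.entries.items():
        w = 1.0 if (source, gas) in inv.co2e_preaggregated else gwp.factor(gas)
        by_source[source] = by_source.get(source, 0.0) + mass * w
    gross = sum(by_source.values())
    if gross <= 0:
        raise DomainError("emission profile undefined for a zero-gross inventory")
    return {s: v / gross * 100.0 for s, v in by_source.items()}


def summarize(
    farm: FarmRecord,
    inv: EmissionInventory,
    seq: float,
    *,
    set_name: str,
    gwp: Optional[GWPSet] = None,
    beef_fraction: float = 1.0,
) -> FootprintResult:
    """Build a FootprintResult from a ready-made inventory and sequestration term.

    Factored out of :func:`footprint` so scenario engines can recompute the
    result after scaling inventory masses without re-running the engine.
    """
    gwp = gwp or GWPSet()
    lwg = compute_lwg(farm)
    gross = allocate(co2e_aggregate(inv, gwp), beef_fraction)
    seq_alloc = allocate(seq, beef_fraction)
    net = gross - seq_alloc
    per_lw_sold = gross / farm.lw_sold if farm.lw_sold > 0 else math.nan
    return FootprintResult(
        farm_id=farm.farm_id,
        set_name=set_name,
        gross_total=gross,
        sequestration=seq_alloc,
        net_total=net,
        lwg=lwg,
        gross_per_lwg=gross / lwg,
        net_per_lwg=net / lwg,
        per_lw_sold=per_lw_sold,
        per_cw=per_lw_sold / DRESSING_PERCENTAGE,
        profile=emission_profile(inv, gwp),
    )


def footprint(
    farm: FarmRecord,
    efs: EmissionFactorSet,
    gwp: Optional[GWPSet] = None,
    beef_fraction: float = 1.0,
) -> FootprintResult:
    """Gross and net carbon footprint of one farm under one factor set."""
    inv = engine.build_inventory(farm, efs)
    seq = engine.sequestration(farm, efs)
    return summarize(
        farm, inv, seq, set_name=efs.name, gwp=gwp, beef_fraction=beef_fraction
    )
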