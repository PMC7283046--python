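"""Mitigation measures, stacked plans, and evaluation against the reduction target.

A measure either overrides engine/farm parameters (e.g. a feed additive
capping the enteric methane conversion factor, or planting hedgerows) or
scales the gas masses of named sources by a percentage.  Stacking combines
overrides last-writer-wins and intensity deltas multiplicatively, so two
measures hitting the same source never remove more than 100% of it — stacked
mitigation on one source is deliberately sub-additive.

The headline statistic is the percentage reduction in the net footprint per
kg live-weight gain, compared against the project target of a 15% reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .domain import (
    EmissionFactorSet,
    FarmRecord,
    FootprintResult,
    Gas,
    GWPSet,
    MitigationMeasure,
    Source,
)
from . import engine
from .errors import ApplicabilityError, DomainError, ValidationError
from .footprint import footprint, summarize

log = logging.getLogger(__name__)

DEFAULT_TARGET_PCT = 15.0
"""Project target: % reduction in net footprint over the programme horizon."""


@dataclass
class MitigationPlan:
    """An ordered list of measures applied together."""

    measures: List[MitigationMeasure]
    combination_rule: str = "multiplicative"

    def __post_init__(self) -> None:
        names = [m.name for m in self.measures]
        if len(names) != len(set(names)):
            raise ValidationError("measure names within a plan must be unique")
        if self.combination_rule not in ("multiplicative", "additive_capped"):
            raise ValidationError(
                f"unknown combination rule {self.combination_rule!r}"
            )


@dataclass
class ScenarioResult:
    """Baseline vs mitigated footprints for one farm."""

    baseline: FootprintResult
    mitigated: FootprintResult
    per_measure_contributions: Dict[str, float] = field(default_factory=dict)

    @property
    def reduction_pct(self) -> float:
        """Percentage reduction in net footprint per kg LWG (positive = reduction)."""
        return (1.0 - self.mitigated.net_per_lwg / self.baseline.net_per_lwg) * 100.0


@dataclass
class TargetEvaluation:
    reduction_pct: float
    target_pct: float
    passed: bool
    margin: float


_FARM_PARAMS = {
    "grassland_area",
    "cropland_area",
    "hedgerow_length",
    "fert_n_applied",
    "lime_applied",
    "diesel_used",
    "electricity_used",
}
_EFS_PARAMS = set(EmissionFactorSet.model_fields) - {"name", "enteric_mode"}


def _apply_overrides(
    farm: FarmRecord,
    efs: EmissionFactorSet,
    overrides: Dict[str, float],
) -> Tuple[FarmRecord, EmissionFactorSet]:
    farm_updates, efs_updates = {}, {}
    for param, value in overrides.items():
        if param in _EFS_PARAMS:
            efs_updates[param] = value
        elif param in _FARM_PARAMS:
            farm_updates[param] = value
        else:
            raise DomainError(f"unknown override parameter {param!r}")
    if farm_updates:
        farm = farm.model_copy(update=farm_updates)
    if efs_updates:
        efs = efs.model_copy(update=efs_updates)
    return farm, efs


def _delta_factors(
    measures: Sequence[MitigationMeasure],
) -> Dict[Tuple[Source, Gas], float]:
    """Multiplicative scale factors per (source, gas) across a measure list."""
    factors: Dict[Tuple[Source, Gas], float] = {}
    for m in measures:
        if m.deltas is None:
            continue
        for source in m.affected_sources:
            for gas, delta in m.deltas.items():
                key = (source, gas)
                factors[key] = factors.get(key, 1.0) * (1.0 + delta / 100.0)
    return factors


def _run_scenario(
    farm: FarmRecord,
    efs: EmissionFactorSet,
    measures: Sequence[MitigationMeasure],
    gwp: Optional[GWPSet],
) -> FootprintResult:
    overrides: Dict[str, float] = {}
    for m in measures:
        if m.overrides:
            for param, value in m.overrides.items():
                if param in overrides and overrides[param] != value:
                    log.warning(
                        "override conflict on %r: %s replaces %s (measure %r wins)",
                        param, value, overrides[param], m.name,
                    )
                overrides[param] = value
    m_farm, m_efs = _apply_overrides(farm, efs, overrides) if overrides else (farm, efs)
    inv = engine.build_inventory(m_farm, m_efs)
    factors = _delta_factors(measures)
    if factors:
        inv = inv.scaled(factors)
    seq = engine.sequestration(m_farm, m_efs)
    return summarize(m_farm, inv, seq, set_name=efs.name, gwp=gwp)


def apply_measure(
    farm: FarmRecord,
    efs: EmissionFactorSet,
    measure: MitigationMeasure,
    gwp: Optional[GWPSet] = None,
) -> ScenarioResult:
    """Apply one measure to a farm and recompute its footprint.

    Live-weight gain is held fixed: mitigation here changes emission
    intensity, not output.
    """
    if not measure.applies_to(farm.system):
        raise ApplicabilityError(
            f"measure {measure.name!r} does not apply to system {farm.system.value!r}"
        )
    baseline = footprint(farm, efs, gwp)
    mitigated = _run_scenario(farm, efs, [measure], gwp)
    return ScenarioResult(
        baseline=baseline,
        mitigated=mitigated,
        per_measure_contributions={
            measure.name: (1.0 - mitigated.net_per_lwg / baseline.net_per_lwg) * 100.0
        },
    )


def stack_plan(
    farm: FarmRecord,
    efs: EmissionFactorSet,
    plan: MitigationPlan,
    gwp: Optional[GWPSet] = None,
) -> ScenarioResult:
    """Apply a whole plan jointly and report sequential marginal contributions.

    Contributions are the extra percentage points of net-footprint reduction
    each measure adds given the measures before it in plan order; they sum to
    the total reduction, but individually depend on the order (the total does
    not, under the multiplicative rule).
    """
    applicable = [m for m in plan.measures if m.applies_to(farm.system)]
    skipped = [m.name for m in plan.measures if not m.applies_to(farm.system)]
    if skipped:
        log.info("measures not applicable to %s skipped: %s", farm.system.value, skipped)
    baseline = footprint(farm, efs, gwp)
    contributions: Dict[str, float] = {}
    prev_reduction = 0.0
    mitigated = baseline
    for i in range(1, len(applicable) + 1):
        mitigated = _run_scenario(farm, efs, applicable[:i], gwp)
        reduction = (1.0 - mitigated.net_per_lwg / baseline.net_per_lwg) * 100.0
        contributions[applicable[i - 1].name] = reduction - prev_reduction
        prev_reduction = reduction
    return ScenarioResult(
        baseline=baseline,
        mitigated=mitigated,
        per_measure_contributions=contributions,
    )


def evaluate_target(
    result: ScenarioResult, target_pct: float = DEFAULT_TARGET_PCT
) -> TargetEvaluation:
    """Pass/fail of a scenario against the footprint-reduction target."""
    if result.baseline.net_per_lwg <= 0:
        raise DomainError("target evaluation needs a positive baseline net footprint")
    reduction = result.reduction_pct
    return TargetEvaluation(
        reduction_pct=reduction,
        target_pct=target_pct,
        passed=reduction >= target_pct,
        margin=reduction - target_pct,
    )
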