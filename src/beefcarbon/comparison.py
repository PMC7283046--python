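"""Multi-model comparison harness.

Runs several emission-factor sets over the same farms, tabulates gross
footprints per kg LWG, and computes the two comparison statistics of
interest: pairwise mean footprint differences between sets and the
concordance (Kendall tau-b) of the farm rankings each set induces.  A
deliberately mixed-model ranking — each farm scored by a different set — is
also evaluated, to quantify how mixing models destabilizes rankings within a
farm group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import kendalltau

from .domain import EmissionFactorSet, FarmRecord, GWPSet
from .errors import BeefCarbonError, DomainError
from .footprint import footprint

log = logging.getLogger(__name__)


@dataclass
class ComparisonTable:
    """Grid of gross footprints (kg CO2e/kg LWG) over farms x factor sets."""

    farms: List[str]
    sets: List[str]
    footprints: Dict[Tuple[str, str], float]
    failures: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def column(self, set_name: str) -> Dict[str, float]:
        return {
            f: self.footprints[(f, set_name)]
            for f in self.farms
            if (f, set_name) in self.footprints
        }

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = [
            {"farm_id": f, "set": s, "gross_per_lwg": self.footprints[(f, s)]}
            for f in self.farms
            for s in self.sets
            if (f, s) in self.footprints
        ]
        return pd.DataFrame(rows, columns=["farm_id", "set", "gross_per_lwg"])

    def to_wide_frame(self) -> pd.DataFrame:
        tidy = self.to_tidy_frame()
        if tidy.empty:
            return pd.DataFrame(index=pd.Index(self.farms, name="farm_id"))
        wide = tidy.pivot(index="farm_id", columns="set", values="gross_per_lwg")
        return wide.reindex(index=self.farms, columns=self.sets)


def run_sets(
    farms: Sequence[FarmRecord],
    sets: Sequence[EmissionFactorSet],
    gwp: Optional[GWPSet] = None,
) -> ComparisonTable:
    """Compute the full farm x set grid; per-cell failures are recorded, not fatal."""
    if not farms or not sets:
        raise DomainError("run_sets needs at least one farm and one factor set")
    table = ComparisonTable(
        farms=[f.farm_id for f in farms],
        sets=[s.name for s in sets],
        footprints={},
    )
    for farm in farms:
        for efs in sets:
            try:
                result = footprint(farm, efs, gwp)
                table.footprints[(farm.farm_id, efs.name)] = result.gross_per_lwg
            except BeefCarbonError as exc:
                log.warning("cell (%s, %s) failed: %s", farm.farm_id, efs.name, exc)
                table.failures[(farm.farm_id, efs.name)] = str(exc)
    return table


def pairwise_mean_diff(table: ComparisonTable, set_a: str, set_b: str) -> float:
    """Mean over common farms of (footprint_a - footprint_b); positive = a higher."""
    col_a, col_b = table.column(set_a), table.column(set_b)
    common = [f for f in table.farms if f in col_a and f in col_b]
    if not common:
        raise DomainError(f"no common farms between sets {set_a!r} and {set_b!r}")
    return sum(col_a[f] - col_b[f] for f in common) / len(common)


def _ranking(col: Dict[str, float], farms: Sequence[str]) -> List[str]:
    """Farms ordered by ascending footprint; ties broken by farm_id order."""
    present = [f for f in farms if f in col]
    return sorted(present, key=lambda f: (col[f], farms.index(f)))


@dataclass
class ConcordanceResult:
    """Within-set farm rankings and pairwise Kendall tau-b between sets."""

    rankings: Dict[str, List[str]]
    tau: Dict[Tuple[str, str], float]
    mixed_assignment: Dict[str, str]
    mixed_ranking: List[str]
    mixed_tau: Dict[str, float]


def ranking_concordance(table: ComparisonTable) -> ConcordanceResult:
    """Rank farms within each set and measure between-set rank agreement.

    Kendall tau-b (tie-corrected) is computed on the footprint columns over
    the farms common to each pair of sets.  The mixed-model ranking assigns
    set ``i mod k`` to farm ``i`` — one farm, one model — and its tau against
    each pure-set ranking shows how far mixing models perturbs the order.
    """
    if len(table.farms) < 2 or len(table.sets) < 2:
        raise DomainError("ranking concordance needs >= 2 farms and >= 2 sets")
    rankings = {s: _ranking(table.column(s), table.farms) for s in table.sets}
    tau: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(table.sets):
        for b in table.sets[i + 1 :]:
            col_a, col_b = table.column(a), table.column(b)
            common = [f for f in table.farms if f in col_a and f in col_b]
            if len(common) < 2:
                continue
            stat = kendalltau([col_a[f] for f in common], [col_b[f] for f in common])
            tau[(a, b)] = float(stat.statistic)
    mixed_assignment = {
        f: table.sets[i % len(table.sets)] for i, f in enumerate(table.farms)
    }
    mixed_col = {
        f: table.footprints[(f, s)]
        for f, s in mixed_assignment.items()
        if (f, s) in table.footprints
    }
    mixed_ranking = _ranking(mixed_col, table.farms)
    mixed_tau: Dict[str, float] = {}
    for s in table.sets:
        col = table.column(s)
        common = [f for f in table.farms if f in col and f in mixed_col]
        if len(common) < 2:
            continue
        stat = kendalltau([mixed_col[f] for f in common], [col[f] for f in common])
        mixed_tau[s] = float(stat.statistic)
    return ConcordanceResult(
        rankings=rankings,
        tau=tau,
        mixed_assignment=mixed_assignment,
        mixed_ranking=mixed_ranking,
        mixed_tau=mixed_tau,
    )
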