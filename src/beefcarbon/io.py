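"""File formats and report writers.

Farms travel either as nested JSON (one object per farm, cohorts inline) or
as a two-table CSV dialect: ``farms.csv`` with one row per farm and a
companion ``cohorts.csv`` keyed by ``farm_id`` (cohort counts vary per farm,
so a single wide table would not fit).  Mapping-valued farm fields
(concentrate by type, manure-system shares) are serialized in CSV cells as
``key=value`` pairs joined by ``;``.

Reports are deterministic CSV tables with numbers at four significant
digits; percentages are on the 0-100 scale and masses in kg.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd
import pydantic

from .comparison import ComparisonTable, ConcordanceResult, pairwise_mean_diff
from .domain import FarmRecord, FootprintResult, validate_farm
from .errors import ParseError, SchemaError, ValidationError
from .mitigation import ScenarioResult

log = logging.getLogger(__name__)

_FARM_SCALARS = [
    "farm_id", "system", "grassland_area", "cropland_area", "lw_sold",
    "lw_purchased", "lw_opening", "lw_closing", "fert_n_applied",
    "lime_applied", "diesel_used", "electricity_used", "hedgerow_length",
]
_FARM_MAPS = ["concentrate_fed", "manure_system_shares"]
_COHORT_COLS = [
    "farm_id", "category", "headcount", "avg_live_weight", "daily_gain",
    "gross_energy_intake", "n_excretion", "volatile_solids",
    "days_grazing", "days_housed",
]


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def _encode_map(d: Dict) -> str:
    return ";".join(f"{getattr(k, 'value', k)}={v:.10g}" for k, v in sorted(
        d.items(), key=lambda kv: str(getattr(kv[0], "value", kv[0]))
    ))


def _decode_map(cell: str, column: str, row: int) -> Dict[str, float]:
    if not cell or pd.isna(cell):
        return {}
    out: Dict[str, float] = {}
    for pair in str(cell).split(";"):
        if not pair.strip():
            continue
        try:
            key, value = pair.split("=", 1)
            out[key.strip()] = float(value)
        except ValueError as exc:
            raise ParseError(
                f"column {column!r}, row {row}: cannot parse map entry {pair!r}"
            ) from exc
    return out


def _validated(records: List[dict], origin: str) -> List[FarmRecord]:
    farms = []
    for i, rec in enumerate(records):
        try:
            farm = FarmRecord(**rec)
        except pydantic.ValidationError as exc:
            raise ParseError(f"{origin}, record {i}: {exc}") from exc
        findings = validate_farm(farm)
        if findings:
            raise ValidationError(
                f"{origin}, farm {farm.farm_id!r}: " + "; ".join(findings)
            )
        farms.append(farm)
    return farms


def read_farms(path: Union[str, Path]) -> List[FarmRecord]:
    """Read validated farm records from a JSON file or a farms/cohorts CSV pair.

    For CSV, ``path`` names the farm table; the cohort table is looked up as
    ``<stem>_cohorts.csv`` or ``cohorts.csv`` next to it.
    """
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"farm file not found: {p}")
    if p.suffix.lower() == ".json":
        data = json.loads(p.read_text())
        records = data["farms"] if isinstance(data, dict) else data
        return _validated(records, str(p))
    return _read_farms_csv(p)


def _read_farms_csv(p: Path) -> List[FarmRecord]:
    cohort_path = p.with_name(p.stem + "_cohorts.csv")
    if not cohort_path.exists():
        cohort_path = p.with_name("cohorts.csv")
    if not cohort_path.exists():
        raise SchemaError(f"companion cohort table not found next to {p}")
    farms_df = pd.read_csv(p, dtype={"farm_id": str})
    cohorts_df = pd.read_csv(cohort_path, dtype={"farm_id": str})
    for col in _FARM_SCALARS:
        if col not in farms_df.columns:
            raise SchemaError(f"{p}: missing mandatory column {col!r}")
    for col in _COHORT_COLS:
        if col not in cohorts_df.columns:
            raise SchemaError(f"{cohort_path}: missing mandatory column {col!r}")
    records = []
    for i, row in farms_df.iterrows():
        rec = {}
        for col in _FARM_SCALARS:
            value = row[col]
            if col in ("farm_id", "system"):
                rec[col] = str(value)
                continue
            try:
                rec[col] = float(value)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{p}: column {col!r}, row {i}: non-numeric value {value!r}"
                ) from exc
        for col in _FARM_MAPS:
            rec[col] = _decode_map(row.get(col, ""), col, int(i))
        mine = cohorts_df[cohorts_df["farm_id"] == rec["farm_id"]]
        rec["cohorts"] = [
            {c: (str(r[c]) if c == "category" else r[c]) for c in _COHORT_COLS[1:]}
            for _, r in mine.iterrows()
        ]
        records.append(rec)
    return _validated(records, str(p))


def write_farms(
    farms: Sequence[FarmRecord], path: Union[str, Path], fmt: str = "json"
) -> List[Path]:
    """Write farms as nested JSON or as the farms/cohorts CSV pair; returns paths."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = [json.loads(f.model_dump_json()) for f in farms]
        p.write_text(json.dumps({"farms": payload}, indent=2, sort_keys=True) + "\n")
        return [p]
    if fmt != "csv":
        raise ValueError(f"unknown farm format {fmt!r}")
    farm_rows, cohort_rows = [], []
    for f in farms:
        row = {c: getattr(f, c) for c in _FARM_SCALARS}
        row["system"] = f.system.value
        for c in _FARM_MAPS:
            row[c] = _encode_map(getattr(f, c))
        farm_rows.append(row)
        for c in f.cohorts:
            crow = {"farm_id": f.farm_id, "category": c.category.value}
            crow.update({k: getattr(c, k) for k in _COHORT_COLS[2:]})
            cohort_rows.append(crow)
    cohort_path = p.with_name(p.stem + "_cohorts.csv")
    pd.DataFrame(farm_rows, columns=_FARM_SCALARS + _FARM_MAPS).to_csv(p, index=False)
    pd.DataFrame(cohort_rows, columns=_COHORT_COLS).to_csv(cohort_path, index=False)
    return [p, cohort_path]


def write_report(
    results: Sequence[FootprintResult], outdir: Union[str, Path]
) -> List[Path]:
    """Per-farm footprint and source-profile tables; deterministic order."""
    if not results:
        raise ValueError("write_report needs at least one result")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fp_rows = [
        {
            "farm_id": r.farm_id,
            "set": r.set_name,
            "gross_total_kg": _fmt(r.gross_total),
            "sequestration_kg": _fmt(r.sequestration),
            "net_total_kg": _fmt(r.net_total),
            "lwg_kg": _fmt(r.lwg),
            "gross_per_lwg": _fmt(r.gross_per_lwg),
            "net_per_lwg": _fmt(r.net_per_lwg),
            "per_lw_sold": _fmt(r.per_lw_sold),
            "per_cw": _fmt(r.per_cw),
            "negative_net": r.negative_net,
        }
        for r in results
    ]
    prof_rows = [
        {"farm_id": r.farm_id, "set": r.set_name, "source": s.value, "share_pct": _fmt(v)}
        for r in results
        for s, v in sorted(r.profile.items(), key=lambda kv: kv[0].value)
    ]
    fp_path = out / "footprints.csv"
    prof_path = out / "profiles.csv"
    pd.DataFrame(fp_rows).to_csv(fp_path, index=False)
    pd.DataFrame(prof_rows).to_csv(prof_path, index=False)
    return [fp_path, prof_path]


def write_comparison(
    table: ComparisonTable,
    concordance: ConcordanceResult,
    outdir: Union[str, Path],
) -> List[Path]:
    """Comparison grid (tidy + wide), pairwise mean diffs and rank concordance."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tidy_path, wide_path = out / "comparison_tidy.csv", out / "comparison_wide.csv"
    table.to_tidy_frame().to_csv(tidy_path, index=False, float_format="%.4g")
    table.to_wide_frame().to_csv(wide_path, float_format="%.4g")
    diff_rows = [
        {"set_a": a, "set_b": b, "mean_diff_per_lwg": _fmt(pairwise_mean_diff(table, a, b))}
        for i, a in enumerate(table.sets)
        for b in table.sets[i + 1 :]
    ]
    diff_path = out / "pairwise_diffs.csv"
    pd.DataFrame(diff_rows, columns=["set_a", "set_b", "mean_diff_per_lwg"]).to_csv(
        diff_path, index=False
    )
    conc_path = out / "rank_concordance.json"
    conc_payload = {
        "rankings": concordance.rankings,
        "kendall_tau": {f"{a}|{b}": round(t, 6) for (a, b), t in concordance.tau.items()},
        "mixed_assignment": concordance.mixed_assignment,
        "mixed_ranking": concordance.mixed_ranking,
        "mixed_tau": {k: round(v, 6) for k, v in concordance.mixed_tau.items()},
    }
    conc_path.write_text(json.dumps(conc_payload, indent=2, sort_keys=True) + "\n")
    return [tidy_path, wide_path, diff_path, conc_path]


def write_scenarios(
    scenarios: Sequence[ScenarioResult], outdir: Union[str, Path]
) -> List[Path]:
    """Baseline vs mitigated footprints and per-measure contributions."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows, contrib_rows = [], []
    for s in scenarios:
        rows.append(
            {
                "farm_id": s.baseline.farm_id,
                "set": s.baseline.set_name,
                "baseline_net_per_lwg": _fmt(s.baseline.net_per_lwg),
                "mitigated_net_per_lwg": _fmt(s.mitigated.net_per_lwg),
                "reduction_pct": _fmt(s.reduction_pct),
            }
        )
        for name, pts in s.per_measure_contributions.items():
            contrib_rows.append(
                {
                    "farm_id": s.baseline.farm_id,
                    "measure": name,
                    "contribution_pct_points": _fmt(pts),
                }
            )
    s_path, c_path = out / "scenarios.csv", out / "scenario_contributions.csv"
    pd.DataFrame(rows).to_csv(s_path, index=False)
    pd.DataFrame(
        contrib_rows, columns=["farm_id", "measure", "contribution_pct_points"]
    ).to_csv(c_path, index=False)
    return [s_path, c_path]
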