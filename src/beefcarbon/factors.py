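"""Registry and loaders for emission-factor sets, GWP sets and measure catalogues.

Three region-flavoured factor sets ship with the package (``IE_style``,
``FR_style``, ``ES_style``); any other set can be supplied as a flat YAML or
JSON file with the same keys.  Loading always round-trips through the
validated pydantic models, so a malformed file fails fast with the offending
field named.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, List, Union

import pydantic
import yaml

from .domain import EmissionFactorSet, GWPSet, MitigationMeasure
from .errors import RegistryError, ValidationError

_DATA = resources.files("beefcarbon.data")

PACKAGED_EF_SETS = ("IE_style", "FR_style", "ES_style")


def _read_mapping(path: Union[str, Path]) -> dict:
    p = Path(path)
    if not p.exists():
        raise RegistryError(
            f"unknown emission-factor set {str(path)!r}; packaged sets: "
            + ", ".join(PACKAGED_EF_SETS)
        )
    text = p.read_text()
    data = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return data


def load_ef_set(name_or_path: Union[str, Path]) -> EmissionFactorSet:
    """Load a packaged factor set by name, or any set from a YAML/JSON file."""
    name = str(name_or_path)
    if name in PACKAGED_EF_SETS:
        data = yaml.safe_load(_DATA.joinpath(f"ef_sets/{name}.yaml").read_text())
    else:
        data = _read_mapping(name_or_path)
    try:
        return EmissionFactorSet(**data)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"invalid emission-factor set {name!r}: {exc}") from exc


def list_ef_sets() -> List[str]:
    return list(PACKAGED_EF_SETS)


def load_gwp_set(path: Union[str, Path, None] = None) -> GWPSet:
    """Load a GWP set from a file, or the packaged 100-year defaults."""
    if path is None:
        data = yaml.safe_load(_DATA.joinpath("gwp_gwp100.yaml").read_text())
    else:
        data = _read_mapping(path)
    try:
        return GWPSet(**data)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"invalid GWP set: {exc}") from exc


def load_measure_catalogue(path: Union[str, Path, None] = None) -> List[MitigationMeasure]:
    """Load a mitigation-measure catalogue (packaged one when ``path`` is None)."""
    if path is None:
        data = yaml.safe_load(_DATA.joinpath("measures.yaml").read_text())
    else:
        data = _read_mapping(path)
    records = data.get("measures", data) if isinstance(data, dict) else data
    measures = []
    for rec in records:
        try:
            measures.append(MitigationMeasure(**rec))
        except pydantic.ValidationError as exc:
            raise ValidationError(
                f"invalid measure {rec.get('name', '<unnamed>')!r}: {exc}"
            ) from exc
    names = [m.name for m in measures]
    if len(names) != len(set(names)):
        raise ValidationError("measure names in a catalogue must be unique")
    return measures


def catalogue_by_name(path: Union[str, Path, None] = None) -> Dict[str, MitigationMeasure]:
    return {m.name: m for m in load_measure_catalogue(path)}
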