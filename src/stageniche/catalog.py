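"""Registry of survey variables.

The abiotic covariates fall into four categories measured at different
spatial scales:

* COVER — percentage ground cover of 14 surface classes (bare soil,
  *Calluna*, dung, graminoids, herbs, lichen, litter, moss, roots,
  *Sedum*, shrubs, stone, *Vaccinium*, dead wood), each estimated in the
  25x25 cm, 50x50 cm and 1x1 m quadrats (suffixes ``_25``, ``_50``, ``_1``).
* RESISTANCE — vegetation penetrability around the 1x1 m quadrat
  (cardinal-direction cover and square counts on a vertical grid, mean
  heather height).
* SOIL — A-horizon particle-size fractions, humidity, organic matter, pH
  and litter depth of the 1x1 m quadrat.
* STRUCTURE — habitat configuration in 3 m and 6 m radii (bare-ground
  patch and tall-shrub counts, a six-class structure score, distances to
  the nearest open patch and shrub).

Biotic predictors are occurrences/abundances of the other life stage, of
the congeneric species, and of neighbouring larvae.  The registry is the
single source of truth for column names, categories, scales and units;
observation tables are validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

COVER_BASES = [
    "BARESOIL", "CALLUNA", "DUNG", "GRAMINOID", "HERB", "LICHEN", "LITTER",
    "MOSS", "ROOT", "SEDUM", "SHRUB", "STONE", "VACCINIUM", "WOOD",
]

COVER_SCALES = ("25", "50", "1")  # 25x25 cm, 50x50 cm, 1x1 m quadrat
STRUCTURE_SCALES = ("3", "6")  # 3 m and 6 m radius

RESISTANCE_VARS = [
    "COVER_N", "COVER_E", "COVER_S", "COVER_W",
    "HEIGHT",
    "SQUARE_N", "SQUARE_E", "SQUARE_S", "SQUARE_W",
]

SOIL_VARS = [
    "LITTER_DEPTH", "SOIL_0.063", "SOIL_0.125", "SOIL_0.25", "SOIL_0.50",
    "SOIL_1", "SOIL_2", "SOIL_HUMID", "SOIL_OM", "SOIL_PH",
]

STRUCTURE_VARS_SCALED = ["OPEN", "SHRUBTALL", "STRUCTURE"]
STRUCTURE_VARS_6ONLY = ["DIST_OPEN", "DIST_SHRUB"]

METADATA_COLUMNS = [
    "unit_id", "location", "point_id", "cell_id", "sampling_scale",
    "habitat_type", "x", "y",
]

RESPONSE_COLUMNS = [
    "adult_PA", "adult_AB", "male_PA", "female_PA",
    "larva_PA", "larva_AB", "larva1_AB", "larva2_AB", "larva3_AB",
]

BIOTIC_COLUMNS = [
    "larva_PA_1m", "larva_AB_1m", "larva1_AB_1m", "larva2_AB_1m",
    "larva3_AB_1m", "congener_adult_PA", "congener_adult_AB",
    "adult_PA_trap", "adult_AB_trap", "male_PA_trap", "female_PA_trap",
    "congener_larva_PA", "congener_larva_AB", "neighbour_larva_AB",
]


@dataclass(frozen=True)
class Variable:
    """One registered column: its category, scale and base name."""

    name: str
    category: str  # COVER | RESISTANCE | SOIL | STRUCTURE | BIOTIC | RESPONSE | META
    scale: str | None = None  # 25 | 50 | 1 | 3 | 6 | None
    base: str | None = None  # multiscale family, e.g. BARESOIL
    unit: str = ""


def _build_registry() -> dict[str, Variable]:
    reg: dict[str, Variable] = {}
    for b in COVER_BASES:
        for s in COVER_SCALES:
            name = f"{b}_{s}"
            reg[name] = Variable(name, "COVER", s, b, "%")
    for v in RESISTANCE_VARS:
        unit = "cm" if v == "HEIGHT" else ("%" if v.startswith("COVER") else "")
        reg[v] = Variable(v, "RESISTANCE", "1", None, unit)
    for v in SOIL_VARS:
        unit = "cm" if v == "LITTER_DEPTH" else ("" if v == "SOIL_PH" else "%")
        reg[v] = Variable(v, "SOIL", "1", None, unit)
    for b in STRUCTURE_VARS_SCALED:
        for s in STRUCTURE_SCALES:
            name = f"{b}_{s}"
            reg[name] = Variable(name, "STRUCTURE", s, b, "")
    for v in STRUCTURE_VARS_6ONLY:
        reg[v] = Variable(v, "STRUCTURE", "6", None, "cm")
    for v in BIOTIC_COLUMNS:
        reg[v] = Variable(v, "BIOTIC")
    for v in RESPONSE_COLUMNS:
        reg[v] = Variable(v, "RESPONSE")
    for v in METADATA_COLUMNS:
        reg[v] = Variable(v, "META")
    return reg


REGISTRY: dict[str, Variable] = _build_registry()

ABIOTIC_NAMES = [v.name for v in REGISTRY.values()
                 if v.category in ("COVER", "RESISTANCE", "SOIL", "STRUCTURE")]


def abiotic_names(categories: tuple[str, ...] | None = None,
                  cover_scales: tuple[str, ...] = COVER_SCALES) -> list[str]:
    """Abiotic column names, optionally restricted by category and, for the
    multiscale COVER family, by measurement scale."""
    out = []
    for name in ABIOTIC_NAMES:
        v = REGISTRY[name]
        if categories is not None and v.category not in categories:
            continue
        if v.category == "COVER" and v.scale not in cover_scales:
            continue
        out.append(name)
    return out


def scale_family(name: str) -> str | None:
    """Base name of a multiscale variable (e.g. BARESOIL_50 -> BARESOIL),
    or None for single-scale variables."""
    v = REGISTRY.get(name)
    return v.base if v is not None else None


def category_of(name: str) -> str:
    v = REGISTRY.get(name)
    if v is None:
        raise KeyError(f"column {name!r} is not in the variable catalog")
    return v.category


def validate_columns(columns, allow_extra: bool = False) -> None:
    """Raise ValueError naming every column not present in the catalog."""
    unknown = [c for c in columns if c not in REGISTRY]
    if unknown and not allow_extra:
        raise ValueError(f"unregistered columns: {', '.join(sorted(unknown))}")


def write_catalog_json(path: str | Path) -> None:
    """Serialize the registry (name, category, scale, unit) to JSON."""
    payload = {
        name: {"category": v.category, "scale": v.scale, "base": v.base,
               "unit": v.unit}
        for name, v in REGISTRY.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
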