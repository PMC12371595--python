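"""Anticoagulant and additive-solution recipes with ideal osmolarity.

The packaged registry holds the citrate–phosphate–dextrose anticoagulants
(CPD and its normoglycemic variant CPD-N) and the additive solutions (AS-1
and normoglycemic AS-1N).  Osmolarity is the ideal-dissociation sum
Σ concentration × osmotic-particle count, with integer particle counts
calibrated once against the CPD row (trisodium citrate → 4 particles, citric
acid → 1, monosodium phosphate → 2, sugars and adenine → 1, NaCl → 2) and
then frozen.  Computed values are compared against the declared ones and any
disagreement is reported, never silently reconciled (AS-1's declared
465 mOsm/L exceeds the ideal sum of 462 by 3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Recipe",
    "load_registry",
    "default_dissociation_table",
    "osmolarity",
    "compare_to_declared",
]


@dataclass(frozen=True)
class Recipe:
    """One solution: named component concentrations (mM) and declared figures."""

    name: str
    components: dict[str, float]
    kind: str = ""
    ph: float | None = None
    declared_osmolarity_mosm_l: float | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.components.values()):
            raise ValueError("component concentrations must be >= 0")


def _raw_registry() -> dict:
    with resources.files("storemetrics.data").joinpath("solutions.json").open() as f:
        return json.load(f)


def load_registry() -> dict[str, Recipe]:
    """The packaged recipes, keyed by name."""
    raw = _raw_registry()
    out: dict[str, Recipe] = {}
    for entry in raw["solutions"]:
        if entry["name"] in out:
            raise ValueError(f"duplicate recipe name: {entry['name']}")
        out[entry["name"]] = Recipe(
            name=entry["name"],
            components=dict(entry["components"]),
            kind=entry.get("kind", ""),
            ph=entry.get("pH"),
            declared_osmolarity_mosm_l=entry.get("declared_osmolarity_mosm_l"),
        )
    return out


def default_dissociation_table() -> dict[str, int]:
    """Osmotic particle counts per formula unit (ideal full dissociation)."""
    return {k: int(v) for k, v in _raw_registry()["dissociation"].items()}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def osmolarity(
    recipe: Recipe,
    table: dict[str, int] | None = None,
    round_to_int: bool = True,
) -> float:
    """Ideal-dissociation osmolarity (mOsm/L): Σ concentration × particles.

    Rounded half-away-from-zero to a whole number unless ``round_to_int`` is
    false.  Additive over components and homogeneous of degree one in the
    concentrations (before rounding).

    Raises
    ------
    KeyError
        If a component species has no dissociation entry.
    """
    if table is None:
        table = default_dissociation_table()
    total = 0.0
    for species, conc in recipe.components.items():
        if species not in table:
            raise KeyError(f"no dissociation entry for species '{species}'")
        total += conc * table[species]
    return float(_round_half_away(total)) if round_to_int else total


def compare_to_declared(
    recipe: Recipe, table: dict[str, int] | None = None
) -> tuple[float, float, float]:
    """(computed, declared, computed − declared); disagreements are reported as-is.

    Raises
    ------
    ValueError
        If the recipe declares no osmolarity.
    """
    if recipe.declared_osmolarity_mosm_l is None:
        raise ValueError(f"recipe '{recipe.name}' declares no osmolarity")
    computed = osmolarity(recipe, table)
    declared = float(recipe.declared_osmolarity_mosm_l)
    return (computed, declared, computed - declared)
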