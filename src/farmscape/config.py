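"""Default study configuration: land-cover categories, variable sets, transforms.

The analysis vocabulary is a categorical land-cover map with 11 codes (10 cover
categories plus 0 = outside buffer), split into a *natural* component
(seminatural habitats) and a *production* component (agricultural covers).
From each buffer 24 variables are derived, organised into six sets used as the
building blocks of candidate models:

=====================  =========================================================
set name               member variables
=====================  =========================================================
nat_comp               % cover of the 5 natural categories
prod_comp              % cover of the 5 production categories
nat_compos_het         land-cover richness / Shannon diversity / evenness
                       within the natural component
prod_compos_het        same, production component
nat_config_het         largest patch index, mean patch size, edge density,
                       mean shape index of the natural component
prod_config_het        same, production component
=====================  =========================================================

Everything here is a *default*: callers may supply their own category map,
period windows, variable sets and transform assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "Category",
    "NATURAL",
    "PRODUCTION",
    "DEFAULT_CATEGORY_MAP",
    "DEFAULT_PERIOD_WINDOWS",
    "COVER_VARIABLES",
    "HETEROGENEITY_VARIABLES",
    "ALL_VARIABLES",
    "DEFAULT_VARIABLE_SETS",
    "DEFAULT_TRANSFORMS",
    "component_codes",
]

NATURAL = "natural"
PRODUCTION = "production"


@dataclass(frozen=True)
class Category:
    """One land-cover category: a display name and its landscape component."""

    name: str
    component: str

    def __post_init__(self) -> None:
        if self.component not in (NATURAL, PRODUCTION):
            raise ValueError(f"component must be 'natural' or 'production', got {self.component!r}")


#: Code 0 is reserved for outside-buffer cells (NODATA in the ASCII grids).
DEFAULT_CATEGORY_MAP: dict[int, Category] = {
    1: Category("woodland", NATURAL),
    2: Category("open_woodland", NATURAL),
    3: Category("shrubland", NATURAL),
    4: Category("streams", NATURAL),
    5: Category("water_bodies", NATURAL),
    6: Category("arable_scattered_trees", PRODUCTION),
    7: Category("annual_dry_crops", PRODUCTION),
    8: Category("permanent_pastures", PRODUCTION),
    9: Category("annual_irrigated_crops", PRODUCTION),
    10: Category("permanent_crops", PRODUCTION),
}

#: Survey years pooled into each period: T0 before and T1 after the 2003 CAP reform.
DEFAULT_PERIOD_WINDOWS: dict[str, tuple[int, int]] = {
    "T0": (1995, 1997),
    "T1": (2010, 2012),
}

RESPONSE_GROUPS = ("all", "woodland", "farmland", "steppe")

COVER_VARIABLES = tuple(c.name for c in DEFAULT_CATEGORY_MAP.values())

_COMPOS = ("cover_richness", "cover_diversity", "cover_evenness")
_CONFIG = ("lpi", "mean_patch_size", "edge_density", "shape_index")

HETEROGENEITY_VARIABLES = tuple(
    f"{prefix}_{v}" for prefix in ("nat", "prod") for v in _COMPOS + _CONFIG
)

ALL_VARIABLES = COVER_VARIABLES + HETEROGENEITY_VARIABLES  # 10 + 14 = 24

DEFAULT_VARIABLE_SETS: dict[str, tuple[str, ...]] = {
    "nat_comp": tuple(c.name for c in DEFAULT_CATEGORY_MAP.values() if c.component == NATURAL),
    "prod_comp": tuple(c.name for c in DEFAULT_CATEGORY_MAP.values() if c.component == PRODUCTION),
    "nat_compos_het": tuple(f"nat_{v}" for v in _COMPOS),
    "prod_compos_het": tuple(f"prod_{v}" for v in _COMPOS),
    "nat_config_het": tuple(f"nat_{v}" for v in _CONFIG),
    "prod_config_het": tuple(f"prod_{v}" for v in _CONFIG),
}

#: Transform assignment used when building analysis matrices.  Percent covers
#: and the largest patch index are proportions (divided by 100 then
#: arcsin-sqrt); evenness is already in [0, 1]; the remaining variables are
#: strictly continuous and get ln(x + offset).
DEFAULT_TRANSFORMS: dict[str, str] = {
    **{v: "angular_pct" for v in COVER_VARIABLES},
    "nat_lpi": "angular_pct",
    "prod_lpi": "angular_pct",
    "nat_cover_evenness": "angular",
    "prod_cover_evenness": "angular",
    **{
        v: "log"
        for v in HETEROGENEITY_VARIABLES
        if not v.endswith(("lpi", "evenness"))
    },
}


def component_codes(category_map: Mapping[int, Category], component: str) -> tuple[int, ...]:
    """Integer codes belonging to one landscape component."""
    return tuple(code for code, cat in category_map.items() if cat.component == component)
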