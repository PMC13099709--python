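"""Objective-driven land-use allocation.

Five built-in scenarios allocate exactly one after-use per cell by a
first-feasible priority rule, each reflecting a planning objective:
climate regulation, ecological restoration, food production, timber
production, and peat-replacing biomass production. All scenarios place
open-water wetlands in the wettest depressions (the open-water-likely
cells), since those would need continuous pumping to stay dry.

Cells feasible for none of a scenario's listed uses fall back to
peatland restoration if they can be rewetted, else to the vegetated
surface — the permit-mandated minimum after-use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydrology import CONSTRAINED_WET, FLEXIBLE, HydroClassGrid
from .suitability import LandUseType, SuitabilityMaps

ALLOC_NODATA = -1
SCENARIO_NAMES = (
    "climate_regulation",
    "ecological_restoration",
    "food_production",
    "timber_production",
    "peat_replacing_biomass",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Priority-ordered land uses realizing one planning objective."""

    name: str
    priority_list: tuple[LandUseType, ...]
    wet_fallback: LandUseType = LandUseType.PEATLAND_RESTORATION
    dry_fallback: LandUseType = LandUseType.VEGETATED_SURFACE

    def __post_init__(self) -> None:
        if not self.priority_list:
            raise ValueError("priority_list must be non-empty")
        if len(set(self.priority_list)) != len(self.priority_list):
            raise ValueError("priority_list has duplicate uses")


def builtin_scenarios() -> list[ScenarioSpec]:
    """The five built-in objective scenarios.

    * climate_regulation — short-rotation downy birch wherever feasible;
      restoration on wet-constrained cells; open water in depressions.
      (Birch precedes restoration in the list so that flexible cells go
      to birch; restoration then covers only the wet-constrained rest.)
    * ecological_restoration — restoration wherever feasible, natural
      revegetation on dry-constrained land, open water in depressions.
    * food_production — forage grass first, conventional pine
      afforestation second.
    * timber_production — pine afforestation first, forage grass second.
    * peat_replacing_biomass — reed canary grass (drained) wherever
      feasible.
    """
    OW = LandUseType.OPEN_WATER_WETLAND
    return [
        ScenarioSpec(
            "climate_regulation",
            (OW, LandUseType.SHORT_ROTATION_BIRCH, LandUseType.PEATLAND_RESTORATION),
        ),
        ScenarioSpec(
            "ecological_restoration",
            (OW, LandUseType.PEATLAND_RESTORATION, LandUseType.VEGETATED_SURFACE),
        ),
        ScenarioSpec(
            "food_production",
            (OW, LandUseType.GRASS_AGRICULTURE, LandUseType.PINE_AFFORESTATION),
        ),
        ScenarioSpec(
            "timber_production",
            (OW, LandUseType.PINE_AFFORESTATION, LandUseType.GRASS_AGRICULTURE),
        ),
        ScenarioSpec(
            "peat_replacing_biomass",
            (OW, LandUseType.PHALARIS_DRAINED),
        ),
    ]


def get_scenario(name: str) -> ScenarioSpec:
    for spec in builtin_scenarios():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")


LAND_USE_ORDER = tuple(LandUseType)


@dataclass
class LandUseAllocation:
    """One land use per valid cell plus the resulting area bookkeeping."""

    scenario: str
    allocation_grid: np.ndarray  # indices into LAND_USE_ORDER, ALLOC_NODATA
    area_table: dict[LandUseType, float] = field(default_factory=dict)
    fallback_area_ha: float = 0.0

    def use_mask(self, use: LandUseType) -> np.ndarray:
        return self.allocation_grid == LAND_USE_ORDER.index(use)

    @property
    def total_area_ha(self) -> float:
        return float(sum(self.area_table.values()))


def allocate(
    suitability: SuitabilityMaps,
    spec: ScenarioSpec,
    hydro: HydroClassGrid,
    cell_area: float,
) -> LandUseAllocation:
    """Assign each valid cell the first feasible use in the priority list.

    Cells with no feasible listed use get the wet fallback where
    rewetting is possible (flexible or wet-constrained cells), else the
    dry fallback; a cell feasible for nothing at all is an error.
    """
    valid = suitability.valid_mask
    grid = np.full(valid.shape, ALLOC_NODATA, dtype=np.int8)
    unassigned = valid.copy()
    for use in spec.priority_list:
        take = unassigned & suitability[use]
        grid[take] = LAND_USE_ORDER.index(use)
        unassigned &= ~take

    fallback_cells = int(unassigned.sum())
    if fallback_cells:
        wet_capable = np.isin(hydro.class_grid, (FLEXIBLE, CONSTRAINED_WET))
        wet_fb = unassigned & wet_capable & suitability[spec.wet_fallback]
        grid[wet_fb] = LAND_USE_ORDER.index(spec.wet_fallback)
        unassigned &= ~wet_fb
        dry_fb = unassigned & suitability[spec.dry_fallback]
        grid[dry_fb] = LAND_USE_ORDER.index(spec.dry_fallback)
        unassigned &= ~dry_fb
        if unassigned.any():
            r, c = np.argwhere(unassigned)[0]
            raise ValueError(
                f"cell ({r}, {c}) is feasible for no land use under "
                f"scenario {spec.name!r}"
            )

    area_table = {
        use: float((grid == i).sum() * cell_area)
        for i, use in enumerate(LAND_USE_ORDER)
    }
    return LandUseAllocation(
        scenario=spec.name,
        allocation_grid=grid,
        area_table=area_table,
        fallback_area_ha=fallback_cells * cell_area,
    )


def area_summary(allocations: list[LandUseAllocation]) -> pd.DataFrame:
    """Long-format (scenario, land_use, hectares) table, unrounded."""
    rows = [
        {"scenario": a.scenario, "land_use": use.value, "hectares": ha}
        for a in allocations
        for use, ha in a.area_table.items()
    ]
    return pd.DataFrame(rows, columns=["scenario", "land_use", "hectares"])
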