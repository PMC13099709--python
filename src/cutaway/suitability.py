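"""Per-land-use feasibility mapping.

Combines three site properties into boolean feasibility masks per
after-use type:

* hydrological constraint class (wet uses excluded from constrained-dry
  cells, dry uses from constrained-wet cells);
* residual peat thickness class — thin (< 40 cm), medium (40–100 cm),
  thick (> 100 cm); thick peat makes afforestation suboptimal because
  tree roots cannot reach the mineral subsoil, and thin peat triggers a
  subsoil check for agriculture;
* mineral subsoil — coarse-textured tills (sandy or boulder-rich till)
  under thin peat exclude agriculture, as does the presence of stones.

The boundary values 40 and 100 cm belong to the middle class (closed
interval); the thresholds live in one constant table below.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .hydrology import CONSTRAINED_DRY, CONSTRAINED_WET, FLEXIBLE, HydroClassGrid
from .synthetic_site import COARSE_TILLS, SiteModel

#: Peat-thickness class boundaries in cm; both belong to the middle class.
PEAT_THIN_MAX_CM = 40.0
PEAT_THICK_MIN_CM = 100.0

PEAT_CLASSES = ("thin", "medium", "thick")
THIN, MEDIUM, THICK = 0, 1, 2
PEAT_NODATA = -1


class LandUseType(str, Enum):
    """After-use types allocatable in scenarios."""

    PINE_AFFORESTATION = "pine_afforestation"
    SHORT_ROTATION_BIRCH = "short_rotation_birch"
    VEGETATED_SURFACE = "vegetated_surface"
    PEATLAND_RESTORATION = "peatland_restoration"
    OPEN_WATER_WETLAND = "open_water_wetland"
    GRASS_AGRICULTURE = "grass_agriculture"
    PHALARIS_DRAINED = "phalaris_drained"


#: Uses requiring drained conditions vs a high water table.
DRY_USES = (
    LandUseType.PINE_AFFORESTATION,
    LandUseType.SHORT_ROTATION_BIRCH,
    LandUseType.VEGETATED_SURFACE,
    LandUseType.GRASS_AGRICULTURE,
    LandUseType.PHALARIS_DRAINED,
)
WET_USES = (LandUseType.PEATLAND_RESTORATION, LandUseType.OPEN_WATER_WETLAND)
AFFORESTATION_USES = (
    LandUseType.PINE_AFFORESTATION,
    LandUseType.SHORT_ROTATION_BIRCH,
)
AGRICULTURE_USES = (LandUseType.GRASS_AGRICULTURE, LandUseType.PHALARIS_DRAINED)


def classify_peat(peat_grid: np.ndarray) -> np.ndarray:
    """Classify peat thickness (cm) into thin/medium/thick codes.

    thin: < 40 cm; medium: 40–100 cm inclusive; thick: > 100 cm.
    NaN cells map to :data:`PEAT_NODATA`. Negative values are an input
    error.
    """
    peat = np.asarray(peat_grid, dtype=float)
    finite = np.isfinite(peat)
    if np.any(peat[finite] < 0):
        raise ValueError("peat thickness must be non-negative")
    classes = np.full(peat.shape, PEAT_NODATA, dtype=np.int8)
    classes[finite & (peat < PEAT_THIN_MAX_CM)] = THIN
    classes[finite & (peat >= PEAT_THIN_MAX_CM) & (peat <= PEAT_THICK_MIN_CM)] = MEDIUM
    classes[finite & (peat > PEAT_THICK_MIN_CM)] = THICK
    return classes


@dataclass
class SuitabilityMaps:
    """Boolean feasibility raster per land use."""

    masks: dict[LandUseType, np.ndarray]
    valid_mask: np.ndarray

    def __getitem__(self, use: LandUseType) -> np.ndarray:
        return self.masks[use]

    def feasible_area_ha(self, cell_area: float) -> dict[LandUseType, float]:
        return {
            use: float(mask.sum() * cell_area) for use, mask in self.masks.items()
        }


def suitability_maps(
    hydro: HydroClassGrid,
    peat_classes: np.ndarray,
    subsoil_names: np.ndarray,
    stone_mask: np.ndarray | None = None,
) -> SuitabilityMaps:
    """Build per-use feasibility masks from classified site properties.

    Rules:

    * dry uses are feasible on constrained-dry and flexible cells only;
    * wet uses on flexible and constrained-wet cells only, open-water
      wetland additionally restricted to the open-water-likely cells;
    * afforestation (pine, short-rotation birch) is excluded on thick
      (> 100 cm) peat;
    * grass and reed canary grass are excluded where thin (< 40 cm) peat
      overlies coarse-textured till, and wherever stones occur.
    """
    cls = hydro.class_grid
    if peat_classes.shape != cls.shape or subsoil_names.shape != cls.shape:
        raise ValueError("suitability inputs must share one shape")
    if stone_mask is None:
        stone_mask = np.zeros(cls.shape, dtype=bool)
    elif stone_mask.shape != cls.shape:
        raise ValueError("stone_mask shape mismatch")

    valid = hydro.valid_mask & (peat_classes != PEAT_NODATA)
    dry_capable = valid & np.isin(cls, (CONSTRAINED_DRY, FLEXIBLE))
    wet_capable = valid & np.isin(cls, (FLEXIBLE, CONSTRAINED_WET))
    thin = peat_classes == THIN
    thick = peat_classes == THICK
    coarse = np.isin(subsoil_names, sorted(COARSE_TILLS))

    masks: dict[LandUseType, np.ndarray] = {}
    for use in DRY_USES:
        masks[use] = dry_capable.copy()
    for use in AFFORESTATION_USES:
        masks[use] &= ~thick
    for use in AGRICULTURE_USES:
        masks[use] &= ~((thin & coarse) | stone_mask)
    masks[LandUseType.PEATLAND_RESTORATION] = wet_capable.copy()
    masks[LandUseType.OPEN_WATER_WETLAND] = wet_capable & hydro.open_water_mask
    return SuitabilityMaps(masks=masks, valid_mask=valid)


def site_suitability(
    site: SiteModel,
    hydro: HydroClassGrid,
    stone_mask: np.ndarray | None = None,
) -> SuitabilityMaps:
    """Convenience wrapper: classify peat and apply the rule table."""
    return suitability_maps(
        hydro,
        classify_peat(site.peat_grid),
        site.subsoil_names(),
        stone_mask=stone_mask,
    )
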