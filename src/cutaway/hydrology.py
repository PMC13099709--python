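"""Drainage/rewetting classification and D8 flow routing.

The central question for after-use planning is which parts of a cutaway
can be rewetted and which must stay dry. Two site levels decide it:

* the bottom level of the main outflowing drainage ditch — cells below
  or within ``wet_threshold`` (default 0.5 m) of it cannot be kept dry
  without pumping and are *constrained to wet* uses; they are also the
  cells likely to carry open water;
* the maximum water level tolerated by the border embankments — cells
  above it cannot be rewetted without flooding surrounding land and are
  *constrained to dry* uses.

Cells between the two levels are *flexible*: ditch management and dams
can make them either wet or dry.

Flow-accumulation and catchment utilities use single-direction D8
routing with deterministic tie-breaking, mirroring the standard GIS
procedure used to judge how much water is available for rewetting.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .synthetic_site import SiteModel

HYDRO_CLASSES = ("constrained_dry", "flexible", "constrained_wet")
CONSTRAINED_DRY, FLEXIBLE, CONSTRAINED_WET = 0, 1, 2
NODATA = -1

# D8 neighbour offsets in fixed tie-break order: N, NE, E, SE, S, SW, W, NW.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
)
_SQRT2 = float(np.sqrt(2.0))
D8_DISTANCES = tuple(_SQRT2 if dr and dc else 1.0 for dr, dc in D8_OFFSETS)

OFF_GRID = -1  # flow target for terminal cells


@dataclass(frozen=True)
class HydroRuleParams:
    """Thresholds of the wet/dry classification.

    ``wet_threshold`` is the height above the ditch bottom below which a
    cell is constrained to wet uses (0.5 m by default); ``freeboard``
    optionally lowers the usable maximum water level.
    """

    wet_threshold: float = 0.5
    freeboard: float = 0.0

    def __post_init__(self) -> None:
        if self.wet_threshold < 0:
            raise ValueError("wet_threshold must be >= 0")
        if self.freeboard < 0:
            raise ValueError("freeboard must be >= 0")


@dataclass
class HydroClassGrid:
    """Per-cell wet/dry constraint classes.

    ``class_grid`` holds integer codes (see :data:`HYDRO_CLASSES`,
    :data:`NODATA` for missing elevation); ``open_water_mask`` flags the
    cells likely to carry open water, a subset of ``constrained_wet``.
    """

    class_grid: np.ndarray
    open_water_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.class_grid.shape != self.open_water_mask.shape:
            raise ValueError("class grid and open-water mask shapes differ")
        if np.any(self.open_water_mask & (self.class_grid != CONSTRAINED_WET)):
            raise ValueError("open_water_mask must lie within constrained_wet")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.class_grid != NODATA

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.class_grid == code))
            for code, name in enumerate(HYDRO_CLASSES)
        }


def classify_hydro(site: SiteModel, params: HydroRuleParams | None = None) -> HydroClassGrid:
    """Partition the site into constrained-dry / flexible / constrained-wet.

    A cell of elevation ``z`` is constrained-wet (and open-water-likely)
    iff ``z <= ditch_bottom_level + wet_threshold``; flexible iff it is
    above that but at most ``max_water_level - freeboard``; constrained
    dry otherwise. Missing elevations propagate as no-data.
    """
    params = params or HydroRuleParams()
    z = site.elevation_grid
    wet_level = site.ditch_bottom_level + params.wet_threshold
    usable_max = site.max_water_level - params.freeboard

    classes = np.full(z.shape, NODATA, dtype=np.int8)
    valid = np.isfinite(z)
    wet = valid & (z <= wet_level)
    flexible = valid & ~wet & (z <= usable_max)
    dry = valid & ~wet & ~flexible
    classes[wet] = CONSTRAINED_WET
    classes[flexible] = FLEXIBLE
    classes[dry] = CONSTRAINED_DRY
    return HydroClassGrid(class_grid=classes, open_water_mask=wet)


def flow_directions(elevation_grid: np.ndarray) -> np.ndarray:
    """D8 steepest-descent neighbour index per cell.

    Returns an array of flat indices (``row * n_cols + col``) giving each
    cell's flow target, or :data:`OFF_GRID` for terminal cells (pits and
    cells whose flow leaves the grid). Ties between equally steep
    descents resolve to the first neighbour in N, NE, E, SE, S, SW, W,
    NW order. Flat areas drain toward their nearest strictly lower
    neighbourhood by breadth-first distance across the flat; flats with
    no lower outlet are terminal.
    """
    z = np.asarray(elevation_grid, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("flow routing requires a gap-free elevation grid")
    n_rows, n_cols = z.shape
    target = np.full(z.size, OFF_GRID, dtype=np.int64)
    flat_cells: list[tuple[int, int]] = []

    for r in range(n_rows):
        for c in range(n_cols):
            best_slope = 0.0
            best_idx = OFF_GRID
            has_equal = False
            for k, (dr, dc) in enumerate(D8_OFFSETS):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                    continue
                dz = z[r, c] - z[nr, nc]
                if dz == 0.0:
                    has_equal = True
                    continue
                slope = dz / D8_DISTANCES[k]
                if slope > best_slope:
                    best_slope = slope
                    best_idx = nr * n_cols + nc
            if best_idx != OFF_GRID:
                target[r * n_cols + c] = best_idx
            elif has_equal:
                flat_cells.append((r, c))
            # else: pit or edge cell draining off-grid -> terminal

    if flat_cells:
        _route_flats(z, target, flat_cells)
    return target


def _route_flats(
    z: np.ndarray, target: np.ndarray, flat_cells: list[tuple[int, int]]
) -> None:
    """Drain flat cells toward the nearest resolved cell by BFS.

    Seeds are flat cells adjacent (at equal elevation) to a cell that
    already has a flow target; BFS in fixed neighbour order makes the
    assignment deterministic. Unreached flat cells (closed plateaus)
    stay terminal.
    """
    n_rows, n_cols = z.shape
    unresolved = {r * n_cols + c for r, c in flat_cells}
    queue: deque[int] = deque()
    # Seed: flat cells with an equal-elevation neighbour that drains.
    for idx in sorted(unresolved):
        r, c = divmod(idx, n_cols)
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                continue
            nidx = nr * n_cols + nc
            if z[nr, nc] == z[r, c] and nidx not in unresolved:
                target[idx] = nidx
                queue.append(idx)
                unresolved.discard(idx)
                break
    while queue:
        idx = queue.popleft()
        r, c = divmod(idx, n_cols)
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                continue
            nidx = nr * n_cols + nc
            if nidx in unresolved and z[nr, nc] == z[r, c]:
                target[nidx] = idx
                unresolved.discard(nidx)
                queue.append(nidx)


def flow_accumulation(elevation_grid: np.ndarray) -> np.ndarray:
    """Number of cells (including itself) draining through each cell.

    D8 routing per :func:`flow_directions`; accumulation is propagated
    in topological order over the resulting flow forest.
    """
    z = np.asarray(elevation_grid, dtype=float)
    target = flow_directions(z)
    n = z.size
    acc = np.ones(n, dtype=np.int64)
    indegree = np.zeros(n, dtype=np.int64)
    for idx in range(n):
        t = target[idx]
        if t != OFF_GRID:
            indegree[t] += 1
    queue = deque(np.flatnonzero(indegree == 0).tolist())
    while queue:
        idx = queue.popleft()
        t = target[idx]
        if t == OFF_GRID:
            continue
        acc[t] += acc[idx]
        indegree[t] -= 1
        if indegree[t] == 0:
            queue.append(t)
    return acc.reshape(z.shape)


def catchment_mask(
    elevation_grid: np.ndarray, outlet_cell: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of all cells whose D8 path passes the outlet."""
    z = np.asarray(elevation_grid, dtype=float)
    n_rows, n_cols = z.shape
    r, c = outlet_cell
    if not (0 <= r < n_rows and 0 <= c < n_cols):
        raise ValueError(f"outlet {outlet_cell} outside grid {z.shape}")
    target = flow_directions(z)
    outlet = r * n_cols + c
    # Invert the flow forest and walk upstream from the outlet.
    upstream: dict[int, list[int]] = {}
    for idx in range(z.size):
        t = target[idx]
        if t != OFF_GRID:
            upstream.setdefault(int(t), []).append(idx)
    mask = np.zeros(z.size, dtype=bool)
    stack = [outlet]
    while stack:
        idx = stack.pop()
        if mask[idx]:
            continue
        mask[idx] = True
        stack.extend(upstream.get(idx, ()))
    return mask.reshape(z.shape)


def catchment_area(
    elevation_grid: np.ndarray,
    outlet_cell: tuple[int, int],
    cell_area: float,
) -> float:
    """Area (ha) draining to ``outlet_cell`` under D8 routing."""
    z = np.asarray(elevation_grid, dtype=float)
    r, c = outlet_cell
    if not (0 <= r < z.shape[0] and 0 <= c < z.shape[1]):
        raise ValueError(f"outlet {outlet_cell} outside grid {z.shape}")
    if not np.isfinite(z[r, c]):
        raise ValueError("outlet cell has no elevation data")
    return float(catchment_mask(z, outlet_cell).sum() * cell_area)
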