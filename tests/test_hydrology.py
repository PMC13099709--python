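"""Hydrological classification and D8 routing against brute-force oracles."""

import numpy as np
import pytest

from cutaway import HydroRuleParams, catchment_area, classify_hydro, flow_accumulation
from cutaway.hydrology import (
    CONSTRAINED_DRY,
    CONSTRAINED_WET,
    D8_OFFSETS,
    FLEXIBLE,
    flow_directions,
)
from cutaway.synthetic_site import SiteModel


def make_site(elevation, ditch_bottom, max_water):
    elevation = np.asarray(elevation, dtype=float)
    boundary = np.zeros(elevation.shape, dtype=bool)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    return SiteModel(
        elevation_grid=elevation,
        peat_grid=np.full(elevation.shape, 50.0),
        subsoil_grid=np.zeros(elevation.shape, dtype=np.int16),
        subsoil_legend=("sand",),
        ditch_bottom_level=ditch_bottom,
        max_water_level=max_water,
        boundary_mask=boundary,
        cell_area=0.01,
    )


# --- brute-force D8 oracle -------------------------------------------------

SQRT2 = np.sqrt(2.0)


def oracle_target(z, r, c):
    """Steepest-descent D8 neighbour with fixed tie-break order."""
    n_rows, n_cols = z.shape
    best, best_slope = None, 0.0
    for k, (dr, dc) in enumerate(D8_OFFSETS):
        nr, nc = r + dr, c + dc
        if not (0 <= nr < n_rows and 0 <= nc < n_cols):
            continue
        dz = z[r, c] - z[nr, nc]
        if dz <= 0:
            continue
        slope = dz / (SQRT2 if dr and dc else 1.0)
        if slope > best_slope:
            best, best_slope = (nr, nc), slope
    return best


def oracle_accumulation(z):
    """Follow each cell's descent path to termination, counting visits."""
    n_rows, n_cols = z.shape
    acc = np.zeros_like(z, dtype=int)
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            cell = (r0, c0)
            while cell is not None:
                acc[cell] += 1
                cell = oracle_target(z, *cell)
    return acc


# --- classification --------------------------------------------------------


def test_flat_low_site_all_open_water():
    """Cells within 0.5 m of the ditch bottom are wet-constrained."""
    site = make_site(np.full((4, 5), 10.3), ditch_bottom=10.0, max_water=11.0)
    hydro = classify_hydro(site)
    assert np.all(hydro.class_grid == CONSTRAINED_WET)
    assert np.all(hydro.open_water_mask)


def test_everything_above_max_water_is_dry():
    site = make_site(np.full((3, 3), 20.0), ditch_bottom=10.0, max_water=12.0)
    hydro = classify_hydro(site)
    assert np.all(hydro.class_grid == CONSTRAINED_DRY)
    assert not hydro.open_water_mask.any()


def test_three_terrace_site_one_class_each():
    """Terraces at ditch+0.2 / ditch+1.0 / max+1.0 hit one class apiece,
    as hand-enumeration of the 50-cm and embankment rules dictates."""
    ditch, maxwl = 10.0, 12.0
    z = np.array([[ditch + 0.2] * 3, [ditch + 1.0] * 3, [maxwl + 1.0] * 3])
    hydro = classify_hydro(make_site(z, ditch, maxwl))
    assert np.all(hydro.class_grid[0] == CONSTRAINED_WET)
    assert np.all(hydro.class_grid[1] == FLEXIBLE)
    assert np.all(hydro.class_grid[2] == CONSTRAINED_DRY)


def test_boundary_exactly_at_threshold_is_wet():
    site = make_site(np.full((2, 2), 10.5), ditch_bottom=10.0, max_water=12.0)
    assert np.all(classify_hydro(site).class_grid == CONSTRAINED_WET)


def test_missing_elevation_propagates_nodata():
    z = np.full((3, 3), 11.0)
    z[1, 1] = np.nan
    hydro = classify_hydro(make_site(z, 10.0, 12.0))
    assert hydro.class_grid[1, 1] == -1
    assert hydro.valid_mask.sum() == 8


def test_partition_and_monotonicity_on_random_terrain(rng):
    """Classes partition valid cells; widening either level band only
    grows the class it feeds."""
    z = 10.0 + rng.uniform(0, 3, size=(15, 15))
    site = make_site(z, 10.0, 12.0)
    base = classify_hydro(site, HydroRuleParams(wet_threshold=0.5))
    counts = base.counts()
    assert sum(counts.values()) == z.size

    wider_wet = classify_hydro(site, HydroRuleParams(wet_threshold=1.0))
    assert wider_wet.counts()["constrained_wet"] >= counts["constrained_wet"]

    higher_site = make_site(z, 10.0, 13.0)
    more_flex = classify_hydro(higher_site)
    assert (
        more_flex.counts()["flexible"] >= counts["flexible"]
    ), "raising max_water_level must not shrink the flexible class"
    # flexible cells of the lower level stay flexible
    assert np.all(more_flex.class_grid[base.class_grid == FLEXIBLE] == FLEXIBLE)


# --- flow routing ----------------------------------------------------------


def test_descending_ramp_accumulation():
    z = np.array([[5.0, 4.0, 3.0, 2.0, 1.0]])
    assert flow_accumulation(z).tolist() == [[1, 2, 3, 4, 5]]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_accumulation_matches_brute_force_on_random_grids(seed):
    rng = np.random.default_rng(seed)
    z = rng.uniform(0, 10, size=(6, 6)).round(2)
    assert np.array_equal(flow_accumulation(z), oracle_accumulation(z))


def test_valley_axis_concentrates_flow():
    """In a V-shaped valley the axis outcollects same-row slope cells."""
    cols = np.abs(np.arange(5) - 2).astype(float)
    z = cols[None, :] + 0.1 * np.arange(5)[:, None]
    acc = flow_accumulation(z)
    oracle = oracle_accumulation(z)
    assert np.array_equal(acc, oracle)
    for r in range(1, 5):
        assert acc[r, 2] > acc[r, 0]
        assert acc[r, 2] > acc[r, 4]


def test_flat_grid_documented_behaviour():
    """All-equal elevations: closed plateau, every cell terminal with
    accumulation 1."""
    acc = flow_accumulation(np.full((4, 4), 2.0))
    assert np.all(acc == 1)


def test_accumulation_conserves_cells(rng):
    """Sum of terminal-cell accumulations equals the number of cells."""
    z = rng.uniform(0, 5, size=(10, 12))
    target = flow_directions(z)
    acc = flow_accumulation(z).ravel()
    terminal = target == -1
    assert acc[terminal].sum() == z.size


def test_catchment_single_cell_and_ramp():
    assert catchment_area(np.array([[3.0]]), (0, 0), 0.01) == pytest.approx(0.01)
    z = np.array([[5.0, 4.0, 3.0, 2.0, 1.0]])
    assert catchment_area(z, (0, 4), 0.01) == pytest.approx(0.05)


def test_two_basin_catchments_match_oracle():
    """Two basins draining to opposite edges: per-basin catchment areas
    equal brute-force drainage counts."""
    ridge = np.abs(np.arange(6) - 2.5)
    z = 5.0 - ridge[None, :] + 0.1 * np.arange(6)[:, None]
    # outlets: lowest cells on each side of the ridge (row 0)
    for outlet in [(0, 0), (0, 5)]:
        n = 0
        for r in range(6):
            for c in range(6):
                cell = (r, c)
                visited = False
                while cell is not None:
                    if cell == outlet:
                        visited = True
                        break
                    cell = oracle_target(z, *cell)
                n += visited
        assert catchment_area(z, outlet, 0.01) == pytest.approx(n * 0.01)


def test_catchment_outlet_outside_grid_rejected():
    with pytest.raises(ValueError):
        catchment_area(np.zeros((3, 3)), (5, 5), 0.01)


# --- hypothesis properties -------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

_Z = np.random.default_rng(99).uniform(0, 3, size=(12, 12)) + 10.0


@given(
    thr=st.floats(0.0, 2.0, allow_nan=False),
    delta=st.floats(0.0, 1.0, allow_nan=False),
)
@settings(derandomize=True, max_examples=40, deadline=None)
def test_wet_class_monotone_in_threshold(thr, delta):
    """Raising wet_threshold never shrinks the constrained-wet class,
    and the partition always covers every cell."""
    site = make_site(_Z, 10.0, 12.0)
    a = classify_hydro(site, HydroRuleParams(wet_threshold=thr))
    b = classify_hydro(site, HydroRuleParams(wet_threshold=thr + delta))
    assert sum(a.counts().values()) == _Z.size
    assert np.all(b.open_water_mask[a.open_water_mask])
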