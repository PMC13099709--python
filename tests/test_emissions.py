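"""Emission-factor registry, annualization, depletion and trajectories."""

import math

import numpy as np
import pandas as pd
import pytest

from cutaway import (
    annualize_growing_season,
    build_trajectory,
    central_estimate,
    peat_carbon_stock,
    peat_depletion_time,
)
from cutaway.emissions import (
    C_TO_CH4,
    C_TO_CO2,
    N_TO_N2O,
    RegistryError,
    validate_registry,
)
from cutaway.suitability import LandUseType


# --- annualization ---------------------------------------------------------


@pytest.mark.parametrize(
    "balance,er,expected",
    [(0.0, 10.0, 1.5), (-2.0, 0.0, -2.0), (1.0, 4.0, 1.6)],
)
def test_winter_adjustment_is_15pct_of_respiration(balance, er, expected):
    assert annualize_growing_season(balance, er) == pytest.approx(expected)


def test_annualize_rejects_negative_respiration():
    with pytest.raises(ValueError):
        annualize_growing_season(0.0, -1.0)


def test_annualize_matches_arithmetic_oracle(rng):
    for _ in range(100):
        b, r = rng.normal(), abs(rng.normal())
        assert annualize_growing_season(b, r) == pytest.approx(
            b + 0.15 * r, abs=1e-12
        )


# --- central estimate ------------------------------------------------------


def test_central_estimate_median_vs_mean():
    assert central_estimate([1, 2, 100], "nonnormal") == 2
    assert central_estimate([1, 2, 3], "normal") == 2
    with pytest.raises(ValueError):
        central_estimate([])


def test_median_matches_sort_oracle(rng):
    for _ in range(50):
        vals = rng.normal(size=rng.integers(1, 20)).tolist()
        s = sorted(vals)
        n = len(s)
        oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
        assert central_estimate(vals, "nonnormal") == pytest.approx(oracle)


# --- peat depletion --------------------------------------------------------


def test_peat_stock_hand_checked():
    """20 cm at 0.18 g/cm3 and 0.523 C fraction: 20*0.18*0.523*100."""
    assert peat_carbon_stock(20.0) == pytest.approx(188.28)


def test_depletion_time_for_grass_loss_rate():
    """188.28 t C / 5.7 t C yr-1 ~ 33 years: depleted within decades."""
    years = peat_depletion_time(20.0, annual_c_loss=5.7)
    assert years == pytest.approx(188.28 / 5.7)
    assert 30 < years < 35


def test_zero_depth_depletes_immediately_and_bad_loss_raises():
    assert peat_depletion_time(0.0, annual_c_loss=1.0) == 0.0
    with pytest.raises(ValueError):
        peat_depletion_time(20.0, annual_c_loss=0.0)


# --- conversions -----------------------------------------------------------


def test_mass_basis_conversions_are_involutive(rng):
    c = rng.uniform(0.1, 10, size=20)
    assert np.allclose(c * C_TO_CO2 * (12.0 / 44.0), c, atol=1e-12)
    assert np.allclose(c * C_TO_CH4 * (12.0 / 16.0), c, atol=1e-12)
    assert np.allclose(c * N_TO_N2O * (28.0 / 44.0), c, atol=1e-12)


# --- trajectories ----------------------------------------------------------


def test_vegetated_surface_constant_series(registry):
    traj = build_trajectory(LandUseType.VEGETATED_SURFACE, 60.0, 100, registry)
    c = traj.net_c_series()
    assert np.allclose(c, 1.5)
    assert traj.series["CO2"] == pytest.approx(1.5 * C_TO_CO2)


def test_grass_truncates_at_depletion(registry):
    """On 20 cm peat the grass C flux runs ~33 years then stops; the
    emitted C equals the initial stock."""
    traj = build_trajectory(LandUseType.GRASS_AGRICULTURE, 20.0, 100, registry)
    loss = float(
        registry.loc[
            (registry.land_use == "grass_agriculture")
            & registry.gas.isin(["CO2", "CH4", "DOC"]),
            "value",
        ].sum()
    )
    t_dep = peat_carbon_stock(20.0) / loss
    assert traj.depletion_year == pytest.approx(t_dep)
    c = traj.net_c_series()
    n_full = math.floor(t_dep)
    assert np.all(c[:n_full] > 0)
    assert c[n_full] == pytest.approx((t_dep - n_full) * loss)
    assert np.all(c[n_full + 1 :] == 0)
    assert c.sum() == pytest.approx(peat_carbon_stock(20.0))
    # N2O is not peat-derived bookkeeping and continues
    assert traj.series["N2O"][-1] > 0


def test_open_water_methane_onset_year_10(registry):
    traj = build_trajectory(LandUseType.OPEN_WATER_WETLAND, 60.0, 100, registry)
    ch4 = traj.series["CH4"]
    assert np.all(ch4[:10] == 0)
    assert np.allclose(ch4[10:], 0.14 * C_TO_CH4)


def test_restoration_pulse_then_sink(registry):
    traj = build_trajectory(LandUseType.PEATLAND_RESTORATION, 60.0, 100, registry)
    co2c = traj.carbon_series["CO2"]
    assert co2c[0] > 1.0  # straw-decomposition pulse
    assert np.all(co2c[15:] < 0)  # developing moss sink
    assert traj.mean_annual_c_balance() == pytest.approx(-0.5, abs=0.05)


def test_trajectory_mean_equals_phase_weighted_mean(registry):
    """Piecewise-constant integration check for a chronosequence."""
    horizon = 100
    traj = build_trajectory(LandUseType.PEATLAND_RESTORATION, 60.0, horizon, registry)
    rows = registry[
        (registry.land_use == "peatland_restoration") & (registry.gas == "CO2")
    ]
    expected = 0.0
    for _, row in rows.iterrows():
        end = horizon if pd.isna(row.phase_end) else min(row.phase_end, horizon)
        expected += row.value * (end - row.phase_start)
    assert traj.carbon_series["CO2"].sum() == pytest.approx(expected)


def test_cumulative_emission_monotone_in_peat_depth(registry):
    """Truncation monotonicity: more peat, no less cumulative C."""
    totals = [
        build_trajectory(LandUseType.GRASS_AGRICULTURE, d, 100, registry)
        .net_c_series()
        .sum()
        for d in (5, 10, 20, 40, 80, 160, 330)
    ]
    assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))


def test_endpoint_runs_bracket_central(registry):
    for lu in LandUseType:
        lo = build_trajectory(lu, 60.0, 100, registry, "low").net_c_series().sum()
        mid = build_trajectory(lu, 60.0, 100, registry, "value").net_c_series().sum()
        hi = build_trajectory(lu, 60.0, 100, registry, "high").net_c_series().sum()
        assert lo <= mid + 1e-9
        assert mid <= hi + 1e-9


# --- registry validation ---------------------------------------------------


def _row(**kw):
    base = dict(
        land_use="x", gas="CO2", phase_start=0, phase_end=np.nan,
        value=1.0, low=0.5, high=1.5, uncertainty_kind="range", source_tag="t",
    )
    base.update(kw)
    return base


def test_registry_rejects_low_above_value():
    table = pd.DataFrame([_row(low=2.0)])
    with pytest.raises(RegistryError, match="low <= value <= high"):
        validate_registry(table)


def test_registry_rejects_phase_gap():
    table = pd.DataFrame(
        [_row(phase_start=0, phase_end=5), _row(phase_start=7, phase_end=np.nan)]
    )
    with pytest.raises(RegistryError, match="contiguous"):
        validate_registry(table)


def test_registry_rejects_unknown_gas():
    with pytest.raises(RegistryError, match="unknown gas"):
        validate_registry(pd.DataFrame([_row(gas="SF6")]))


def test_horizon_must_be_positive(registry):
    with pytest.raises(ValueError):
        build_trajectory(LandUseType.GRASS_AGRICULTURE, 20.0, 0, registry)
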