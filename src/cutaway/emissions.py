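"""Emission-factor registry and per-land-use flux trajectories.

The registry is a CSV of piecewise-constant annual fluxes per land use
and gas. Carbon species (CO2, CH4, DOC) are stored on a carbon basis in
t C ha⁻¹ yr⁻¹ and N2O on a nitrogen basis in t N2O-N ha⁻¹ yr⁻¹, with a
central value plus a low/high band (range across studies or a 95% CI,
per ``uncertainty_kind``). Phases are years since land-use conversion,
``[phase_start, phase_end)``, an empty ``phase_end`` meaning open-ended.

:func:`build_trajectory` assembles the per-gas annual mass series for a
horizon starting in 2020, applying two substantive rules:

* agricultural uses (forage grass, drained reed canary grass) mine the
  residual peat; their peat-derived carbon fluxes stop once the peat
  carbon stock is exhausted (:func:`peat_depletion_time`);
* DOC export is counted in the carbon balance and depletion, and is
  booked as CO2 released in the year of loss for forcing purposes.

Reference-only registry categories (``reference_*``, fluxes from former
agricultural peatlands kept for comparison) are never allocatable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .suitability import LandUseType

# Mass-basis conversions (molar-mass ratios).
C_TO_CO2 = 44.0 / 12.0
C_TO_CH4 = 16.0 / 12.0
N_TO_N2O = 44.0 / 28.0

#: Median dry bulk density of residual peat, g cm^-3.
DEFAULT_BULK_DENSITY = 0.18
#: Average carbon fraction of Finnish geological peat.
DEFAULT_C_FRACTION = 0.523

START_YEAR = 2020

GASES = ("CO2", "CH4", "DOC", "N2O")
CARBON_GASES = ("CO2", "CH4", "DOC")

#: Uses whose carbon fluxes derive from peat mining and truncate at depletion.
PEAT_MINING_USES = frozenset(
    {LandUseType.GRASS_AGRICULTURE.value, LandUseType.PHALARIS_DRAINED.value}
)

_REGISTRY_COLUMNS = [
    "land_use",
    "gas",
    "phase_start",
    "phase_end",
    "value",
    "low",
    "high",
    "uncertainty_kind",
    "source_tag",
]


class RegistryError(ValueError):
    """Raised for malformed emission-factor tables."""


def load_registry(path=None) -> pd.DataFrame:
    """Load and validate an emission-factor table (bundled by default)."""
    if path is None:
        with resources.files("cutaway.data").joinpath(
            "emission_factors.csv"
        ).open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return validate_registry(table)


def validate_registry(table: pd.DataFrame) -> pd.DataFrame:
    """Check header, value ordering and phase contiguity; return the table."""
    missing = set(_REGISTRY_COLUMNS) - set(table.columns)
    if missing:
        raise RegistryError(f"registry missing columns: {sorted(missing)}")
    table = table.copy()
    table["phase_end"] = pd.to_numeric(table["phase_end"], errors="coerce")
    for i, row in table.iterrows():
        if row["gas"] not in GASES:
            raise RegistryError(f"row {i}: unknown gas {row['gas']!r}")
        if not (row["low"] <= row["value"] <= row["high"]):
            raise RegistryError(
                f"row {i}: require low <= value <= high, got "
                f"{row['low']} / {row['value']} / {row['high']}"
            )
        end = row["phase_end"]
        if not math.isnan(end) and not row["phase_start"] < end:
            raise RegistryError(f"row {i}: phase_start must be < phase_end")
    for (lu, gas), grp in table.groupby(["land_use", "gas"], sort=False):
        grp = grp.sort_values("phase_start")
        ends = grp["phase_end"].to_numpy()
        if np.isnan(ends[:-1]).any():
            raise RegistryError(
                f"{lu}/{gas}: only the last phase may be open-ended"
            )
        starts = grp["phase_start"].to_numpy()
        if not np.allclose(starts[1:], ends[:-1], atol=1e-9):
            raise RegistryError(f"{lu}/{gas}: phases are not contiguous")
    return table


def annualize_growing_season(
    gs_balance: float, gs_ecosystem_respiration: float
) -> float:
    """Annual C flux from a growing-season balance.

    Adds an assumed winter CO2 emission of 15% of growing-season
    ecosystem respiration (positive = emission to atmosphere), the
    convention used when compiling growing-season-only flux studies.
    """
    if gs_ecosystem_respiration < 0:
        raise ValueError("ecosystem respiration must be >= 0")
    return gs_balance + 0.15 * gs_ecosystem_respiration


def central_estimate(values, distribution_flag: str = "normal") -> float:
    """Mean for normally distributed study values, median otherwise."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("central_estimate requires a non-empty list")
    if distribution_flag == "normal":
        return float(arr.mean())
    return float(np.median(arr))


def peat_carbon_stock(
    depth_cm: float,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    c_fraction: float = DEFAULT_C_FRACTION,
) -> float:
    """Peat carbon stock in t C ha⁻¹ for a layer of ``depth_cm``.

    1 cm of material over 1 ha at 1 g cm⁻³ weighs 100 t, so
    stock = depth × ρ × carbon fraction × 100.
    """
    if depth_cm < 0:
        raise ValueError("depth must be >= 0")
    if bulk_density <= 0 or not 0 < c_fraction <= 1:
        raise ValueError("bulk_density > 0 and 0 < c_fraction <= 1 required")
    return depth_cm * bulk_density * c_fraction * 100.0


def peat_depletion_time(
    depth_cm: float,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    c_fraction: float = DEFAULT_C_FRACTION,
    annual_c_loss: float = 1.0,
) -> float:
    """Years until the peat C stock is exhausted at ``annual_c_loss``."""
    if annual_c_loss <= 0:
        raise ValueError("annual_c_loss must be > 0")
    return peat_carbon_stock(depth_cm, bulk_density, c_fraction) / annual_c_loss


@dataclass
class EmissionTrajectory:
    """Annual per-gas emission series for one land use.

    ``series`` maps gas name to a mass series in t gas ha⁻¹ yr⁻¹ (CO2
    includes the DOC-derived component); ``carbon_series`` keeps the
    carbon-basis bookkeeping (t C ha⁻¹ yr⁻¹ for CO2/CH4/DOC, t N ha⁻¹
    yr⁻¹ for N2O) used for balance and depletion accounting.
    """

    land_use: str
    start_year: int
    horizon: int
    series: dict[str, np.ndarray]
    carbon_series: dict[str, np.ndarray]
    depletion_year: float | None = None

    def net_c_series(self) -> np.ndarray:
        """Net carbon balance series, t C ha⁻¹ yr⁻¹ (positive = loss)."""
        return sum(self.carbon_series[g] for g in CARBON_GASES)

    def mean_annual_c_balance(self) -> float:
        return float(self.net_c_series().mean())

    def to_frame(self) -> pd.DataFrame:
        years = self.start_year + np.arange(self.horizon)
        return pd.DataFrame({"year": years, **self.series})


def build_trajectory(
    land_use: str | LandUseType,
    peat_depth_cm: float,
    horizon: int,
    registry: pd.DataFrame,
    endpoint: str = "value",
    bulk_density: float = DEFAULT_BULK_DENSITY,
    c_fraction: float = DEFAULT_C_FRACTION,
) -> EmissionTrajectory:
    """Assemble the annual per-gas emission series for one land use.

    ``endpoint`` selects the registry column to run ('value', 'low' or
    'high'), so uncertainty propagates by re-running the model at the
    band endpoints. For peat-mining uses the carbon species are zeroed
    once the peat C stock is spent (the depletion year carries the
    fractional remainder so total emitted C equals the stock).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if endpoint not in ("value", "low", "high"):
        raise ValueError("endpoint must be 'value', 'low' or 'high'")
    lu = land_use.value if isinstance(land_use, LandUseType) else str(land_use)
    rows = registry[registry["land_use"] == lu]
    if rows.empty:
        raise RegistryError(f"no registry rows for land use {lu!r}")

    carbon = {g: np.zeros(horizon) for g in GASES}
    for _, row in rows.iterrows():
        start = int(row["phase_start"])
        end = row["phase_end"]
        stop = horizon if math.isnan(end) else min(int(end), horizon)
        if start < horizon:
            carbon[row["gas"]][start:stop] = row[endpoint]

    depletion: float | None = None
    if lu in PEAT_MINING_USES:
        loss = float(
            rows.loc[rows["gas"].isin(CARBON_GASES), endpoint].sum()
        )
        if loss > 0:
            depletion = peat_depletion_time(
                peat_depth_cm, bulk_density, c_fraction, loss
            )
            n_full = int(math.floor(depletion))
            for g in CARBON_GASES:
                if n_full < horizon:
                    carbon[g][n_full] *= depletion - n_full
                    carbon[g][n_full + 1 :] = 0.0

    series = {
        "CO2": (carbon["CO2"] + carbon["DOC"]) * C_TO_CO2,
        "CH4": carbon["CH4"] * C_TO_CH4,
        "N2O": carbon["N2O"] * N_TO_N2O,
    }
    return EmissionTrajectory(
        land_use=lu,
        start_year=START_YEAR,
        horizon=horizon,
        series=series,
        carbon_series=carbon,
        depletion_year=depletion,
    )
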