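"""Radiative forcing and constant CO2-equivalent emission metrics.

Converts multi-gas emission trajectories into the metric used for
comparing after-uses: the *constant CO2-equivalent emission* — the
steady CO2 emission rate that would produce the same time-integrated
radiative forcing over a chosen horizon (16 or 100 years from 2020) as
the trajectory itself.

The atmospheric model is the standard impulse-response formulation: a
multi-exponential decay with a permanent airborne fraction for CO2 and
single perturbation lifetimes for CH4 and N2O. Marginal radiative
efficiencies are evaluated against the SSP2-4.5 'middle-of-the-road'
background: for CO2 the logarithmic concentration-forcing relation is
linearized at each year's background concentration (so the efficiency
falls as the background rises); CH4 carries a multiplier for its
indirect effects (tropospheric ozone, stratospheric water vapour).
Feedbacks of the (hectare-scale) site emissions on the global
background are ignored. All constants live in provenance-tagged data
files, not in code.

Emissions are treated as mid-year pulses on an annual grid; the
integration window is half-open, ``[start, start + horizon)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .emissions import START_YEAR, EmissionTrajectory


@dataclass(frozen=True)
class GasParameters:
    """Impulse response and radiative efficiency of one gas.

    ``irf_fractions``/``irf_time_constants`` define a sum of
    exponentials (a ``None``/inf time constant marks a permanent
    fraction). ``radiative_efficiency`` is W m⁻² per ppb for CH4/N2O;
    for CO2 it is ``None`` and the efficiency comes from the log-linear
    relation at the background concentration.
    """

    gas: str
    molar_mass: float
    irf_fractions: tuple[float, ...]
    irf_time_constants: tuple[float, ...]  # inf = permanent
    radiative_efficiency: float | None
    indirect_factor: float

    def impulse_response(self, lags: np.ndarray) -> np.ndarray:
        """Airborne fraction of a unit pulse after ``lags`` years."""
        out = np.zeros_like(lags, dtype=float)
        for a, tau in zip(self.irf_fractions, self.irf_time_constants):
            if np.isinf(tau):
                out += a
            else:
                out += a * np.exp(-lags / tau)
        return out


@dataclass(frozen=True)
class ForcingConstants:
    """Bundle of gas parameters plus atmosphere bookkeeping constants."""

    gases: dict[str, GasParameters]
    atmosphere_mass_kg: float
    atmosphere_molar_mass: float
    co2_log_coefficient: float

    def tonnes_per_ppb(self, gas: str) -> float:
        g = self.gases[gas]
        kg = 1e-9 * (g.molar_mass / self.atmosphere_molar_mass) * (
            self.atmosphere_mass_kg
        )
        return kg / 1000.0


def load_constants(path=None) -> ForcingConstants:
    """Load the gas-parameter file (bundled assessment values by default)."""
    if path is None:
        raw = json.loads(
            resources.files("cutaway.data")
            .joinpath("gas_parameters.json")
            .read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)
    gases: dict[str, GasParameters] = {}
    for name, g in raw["gases"].items():
        if "impulse_response" in g:
            fractions = tuple(g["impulse_response"]["fractions"])
            taus = tuple(
                np.inf if t is None else float(t)
                for t in g["impulse_response"]["time_constants_years"]
            )
        else:
            fractions = (1.0,)
            taus = (float(g["lifetime_years"]),)
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"{name}: impulse-response fractions must sum to 1")
        gases[name] = GasParameters(
            gas=name,
            molar_mass=float(g["molar_mass"]),
            irf_fractions=fractions,
            irf_time_constants=taus,
            radiative_efficiency=g.get("radiative_efficiency_w_m2_ppb"),
            indirect_factor=float(g.get("indirect_factor", 1.0)),
        )
    atm = raw["atmosphere"]
    return ForcingConstants(
        gases=gases,
        atmosphere_mass_kg=float(atm["total_mass_kg"]),
        atmosphere_molar_mass=float(atm["mean_molar_mass"]),
        co2_log_coefficient=float(raw["co2_log_forcing_coefficient_w_m2"]),
    )


@dataclass
class BackgroundScenario:
    """Per-gas background concentration series by calendar year."""

    name: str
    years: np.ndarray
    co2_ppm: np.ndarray
    ch4_ppb: np.ndarray
    n2o_ppb: np.ndarray

    def concentration(self, gas: str, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        if years.min() < self.years.min() or years.max() > self.years.max():
            raise ValueError(
                f"years outside background coverage "
                f"[{self.years.min():.0f}, {self.years.max():.0f}]"
            )
        series = {"CO2": self.co2_ppm, "CH4": self.ch4_ppb, "N2O": self.n2o_ppb}
        return np.interp(years, self.years, series[gas])


def load_background(path=None, name: str = "SSP2-4.5") -> BackgroundScenario:
    if path is None:
        with resources.files("cutaway.data").joinpath(
            "ssp245_background.csv"
        ).open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return BackgroundScenario(
        name=name,
        years=table["year"].to_numpy(dtype=float),
        co2_ppm=table["co2_ppm"].to_numpy(dtype=float),
        ch4_ppb=table["ch4_ppb"].to_numpy(dtype=float),
        n2o_ppb=table["n2o_ppb"].to_numpy(dtype=float),
    )


def burden_series(
    emission_series: np.ndarray, gas_params: GasParameters
) -> np.ndarray:
    """Atmospheric mass increment (t) from an annual emission series (t/yr).

    Discrete annual convolution with the gas impulse response: the
    burden in year ``t`` superposes every earlier pulse decayed by its
    integer-year lag.
    """
    e = np.asarray(emission_series, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("emission series must be finite")
    n = e.size
    irf = gas_params.impulse_response(np.arange(n, dtype=float))
    return np.convolve(e, irf)[:n]


def marginal_efficiency(
    gas: str,
    constants: ForcingConstants,
    background: BackgroundScenario,
    years: np.ndarray,
) -> np.ndarray:
    """Forcing per tonne of airborne gas, W m⁻² t⁻¹, per calendar year."""
    g = constants.gases[gas]
    if gas == "CO2":
        conc_ppm = background.concentration("CO2", years)
        per_ppm = constants.co2_log_coefficient / conc_ppm  # d/dC of a*ln(C)
        tonnes_per_ppm = constants.tonnes_per_ppb("CO2") * 1000.0
        eff = per_ppm / tonnes_per_ppm
    else:
        if g.radiative_efficiency is None:
            raise ValueError(f"{gas}: no radiative efficiency configured")
        eff = np.full(
            len(years), g.radiative_efficiency / constants.tonnes_per_ppb(gas)
        )
    return eff * g.indirect_factor


def forcing_series(
    burden: np.ndarray,
    gas: str,
    constants: ForcingConstants,
    background: BackgroundScenario,
    start_year: int = START_YEAR,
) -> np.ndarray:
    """Marginal radiative forcing series (W m⁻²) of a burden series (t)."""
    years = start_year + np.arange(len(burden))
    return burden * marginal_efficiency(gas, constants, background, years)


def integrated_forcing(
    trajectory: EmissionTrajectory,
    horizon: int,
    constants: ForcingConstants,
    background: BackgroundScenario,
) -> float:
    """Time-integrated forcing (W m⁻² yr) over ``[start, start+horizon)``."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    total = 0.0
    for gas, series in trajectory.series.items():
        e = np.zeros(horizon)
        upto = min(horizon, len(series))
        e[:upto] = series[:upto]
        f = forcing_series(
            burden_series(e, constants.gases[gas]),
            gas,
            constants,
            background,
            trajectory.start_year,
        )
        total += float(f.sum())
    return total


def constant_co2_equivalent(
    trajectory: EmissionTrajectory,
    horizon: int,
    constants: ForcingConstants | None = None,
    background: BackgroundScenario | None = None,
) -> float:
    """Constant CO2-eq emission rate, t CO2-eq ha⁻¹ yr⁻¹.

    The rate E* such that a constant CO2 emission of E* over the window
    integrates to the same forcing as the trajectory; exact under
    marginal linearity, so a constant-CO2-only trajectory maps to its
    own rate identically.
    """
    constants = constants or load_constants()
    background = background or load_background()
    num = integrated_forcing(trajectory, horizon, constants, background)
    unit = EmissionTrajectory(
        land_use="_unit_co2",
        start_year=trajectory.start_year,
        horizon=horizon,
        series={"CO2": np.ones(horizon)},
        carbon_series={},
    )
    den = integrated_forcing(unit, horizon, constants, background)
    return num / den
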