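"""Synthetic cutaway-peatland site generator.

Generates :class:`SiteModel` bundles (surface elevation, residual peat
thickness, mineral subsoil category) with the statistical structure of
boreal peat-extraction fields: a gently sloping extraction surface with
local depressions, a thin residual peat layer (mostly < 100 cm, up to
330 cm), and spatially patchy subsoil dominated by sand, tills and
silt/clay. The generator exists so the downstream hydrology,
suitability, allocation and climate-impact stages can be exercised and
tested without survey data (drone DSMs, ground-penetrating radar).

Units follow field convention: elevation in metres above sea level,
peat thickness in centimetres, cell size in metres, cell area in
hectares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

SUBSOIL_CATEGORIES = (
    "sand",
    "sandy_till",
    "fine_till",
    "boulder_till",
    "silt",
    "silt_clay",
    "gyttja",
    "bedrock",
)

#: Coarse-textured till classes that exclude agriculture on thin peat.
COARSE_TILLS = frozenset({"sandy_till", "boulder_till"})


class SiteConfigError(ValueError):
    """Raised when a site-generation configuration is inconsistent."""


def _kampinneva_fractions() -> dict[str, float]:
    # Subsoil composition of the 123-ha reference site: sand 22%,
    # sandy till 56%, silt/clay 15%, gyttja 4%, bedrock 1%, rest fine till.
    return {
        "sand": 0.22,
        "sandy_till": 0.56,
        "silt_clay": 0.15,
        "gyttja": 0.04,
        "bedrock": 0.01,
        "fine_till": 0.02,
    }


@dataclass(frozen=True)
class SiteGenConfig:
    """Parameters of the synthetic site generator.

    Attributes
    ----------
    n_rows, n_cols:
        Grid shape (cells).
    cell_size:
        Cell edge length in metres (10 m cells give 0.01 ha per cell).
    base_elevation:
        Mean surface level, m a.s.l.
    regional_slope:
        (per-row, per-column) elevation increment in metres per cell.
    noise_amplitude:
        Standard deviation (m) of the smoothed micro-topography field.
    noise_correlation:
        Gaussian smoothing length of terrain/peat/subsoil noise, in cells.
    depression_count, depression_depth, depression_radius:
        Number, depth (m) and radius (cells) of local depressions
        (Gaussian-shaped hollows left by deeper extraction).
    peat_mean, peat_sd, peat_max:
        Residual peat thickness distribution, cm; values are clipped to
        ``[0, peat_max]``.
    subsoil_fractions:
        Target areal fraction per subsoil category; must sum to 1.
    ditch_bottom_offset:
        Metres the main outflow-ditch bottom lies below the site's
        minimum surface level.
    rim_height, rim_width:
        Extraction digs the field below the surrounding land, leaving a
        raised border rim; the perimeter is raised by ``rim_height``
        metres, decaying inward over ``rim_width`` cells. The rim is
        what lets the interior be flooded without affecting the
        surroundings.
    embankment_margin:
        Freeboard (m) between the lowest perimeter surface level and the
        maximum water level that avoids flooding surrounding land.
    rng_seed:
        Seed for all randomness; identical configs generate identical sites.
    """

    n_rows: int = 120
    n_cols: int = 100
    cell_size: float = 10.0
    base_elevation: float = 77.5
    regional_slope: tuple[float, float] = (0.004, 0.002)
    noise_amplitude: float = 0.25
    noise_correlation: float = 6.0
    depression_count: int = 3
    depression_depth: float = 0.9
    depression_radius: int = 10
    peat_mean: float = 60.0
    peat_sd: float = 45.0
    peat_max: float = 330.0
    subsoil_fractions: Mapping[str, float] = field(
        default_factory=_kampinneva_fractions
    )
    rim_height: float = 0.6
    rim_width: int = 4
    ditch_bottom_offset: float = 0.2
    embankment_margin: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise SiteConfigError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise SiteConfigError("cell_size must be positive")
        if self.depression_count < 0:
            raise SiteConfigError("depression_count must be >= 0")
        if self.depression_count > 0 and self.depression_radius >= max(
            self.n_rows, self.n_cols
        ):
            raise SiteConfigError(
                "depression_radius too large for the grid"
            )
        if not 0 <= self.peat_mean <= self.peat_max:
            raise SiteConfigError("require 0 <= peat_mean <= peat_max")
        if self.peat_sd < 0:
            raise SiteConfigError("peat_sd must be >= 0")
        if self.rim_height < 0 or self.rim_width < 0:
            raise SiteConfigError("rim_height and rim_width must be >= 0")
        total = sum(self.subsoil_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SiteConfigError(
                f"subsoil fractions must sum to 1, got {total!r}"
            )
        unknown = set(self.subsoil_fractions) - set(SUBSOIL_CATEGORIES)
        if unknown:
            raise SiteConfigError(f"unknown subsoil categories: {sorted(unknown)}")
        if any(f < 0 for f in self.subsoil_fractions.values()):
            raise SiteConfigError("subsoil fractions must be non-negative")


@dataclass
class SiteModel:
    """Co-registered rasters and hydrological scalars for one site.

    ``elevation_grid`` is in m a.s.l., ``peat_grid`` in cm (NaN marks
    missing), ``subsoil_grid`` holds indices into ``subsoil_legend``.
    ``ditch_bottom_level`` is the bottom of the main outflowing drainage
    ditch and ``max_water_level`` the highest surface level that can be
    flooded without affecting surrounding land (border embankments).
    """

    elevation_grid: np.ndarray
    peat_grid: np.ndarray
    subsoil_grid: np.ndarray
    subsoil_legend: tuple[str, ...]
    ditch_bottom_level: float
    max_water_level: float
    boundary_mask: np.ndarray
    cell_area: float  # hectares per cell

    def __post_init__(self) -> None:
        shapes = {
            self.elevation_grid.shape,
            self.peat_grid.shape,
            self.subsoil_grid.shape,
            self.boundary_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("site rasters must share one shape")
        if self.max_water_level < self.ditch_bottom_level:
            raise ValueError("max_water_level must be >= ditch_bottom_level")
        finite = self.peat_grid[np.isfinite(self.peat_grid)]
        if finite.size and finite.min() < 0:
            raise ValueError("peat thickness must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation_grid.shape

    @property
    def total_area_ha(self) -> float:
        return float(self.elevation_grid.size * self.cell_area)

    def subsoil_names(self) -> np.ndarray:
        """Subsoil raster as an array of category names."""
        legend = np.asarray(self.subsoil_legend, dtype=object)
        return legend[self.subsoil_grid]


def _smooth_noise(rng: np.random.Generator, shape, correlation: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given smoothing length."""
    white = rng.standard_normal(shape)
    if correlation <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=correlation, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _boundary_mask(shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[0, :] = mask[-1, :] = True
    mask[:, 0] = mask[:, -1] = True
    if shape[0] == 1 or shape[1] == 1:
        mask[:] = True
    return mask


def generate_site(config: SiteGenConfig) -> SiteModel:
    """Generate a synthetic :class:`SiteModel` from ``config``.

    Elevation is base level + regional slope + smoothed noise minus
    Gaussian depressions; peat thickness is a clipped, spatially
    autocorrelated field; subsoil categories are obtained by quantile
    thresholding of a smoothed field so realized areal fractions match
    the configured ones in expectation. Deterministic for a fixed
    ``rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    shape = (config.n_rows, config.n_cols)
    rows, cols = np.indices(shape, dtype=float)

    elevation = (
        config.base_elevation
        + config.regional_slope[0] * rows
        + config.regional_slope[1] * cols
    )
    if config.noise_amplitude > 0:
        elevation = elevation + config.noise_amplitude * _smooth_noise(
            rng, shape, config.noise_correlation
        )
    else:
        rng.standard_normal(shape)  # keep the stream aligned across configs
    if config.rim_height > 0 and config.rim_width > 0:
        edge_dist = np.minimum.reduce(
            [rows, cols, config.n_rows - 1 - rows, config.n_cols - 1 - cols]
        )
        elevation = elevation + config.rim_height * np.exp(
            -edge_dist / config.rim_width
        )
    for _ in range(config.depression_count):
        cr = rng.uniform(0, config.n_rows - 1)
        cc = rng.uniform(0, config.n_cols - 1)
        r2 = (rows - cr) ** 2 + (cols - cc) ** 2
        elevation = elevation - config.depression_depth * np.exp(
            -r2 / (2.0 * config.depression_radius**2)
        )

    peat_field = _smooth_noise(rng, shape, config.noise_correlation)
    peat = np.clip(
        config.peat_mean + config.peat_sd * peat_field, 0.0, config.peat_max
    )

    subsoil_field = _smooth_noise(rng, shape, config.noise_correlation)
    legend = tuple(
        c for c in SUBSOIL_CATEGORIES if config.subsoil_fractions.get(c, 0) > 0
    )
    # Quantile thresholding: category i occupies the fraction_i band of the
    # field's empirical distribution, giving contiguous patches.
    fractions = np.array([config.subsoil_fractions[c] for c in legend])
    edges = np.concatenate([[0.0], np.cumsum(fractions)])
    edges[-1] = 1.0
    ranks = subsoil_field.ravel().argsort().argsort() / max(
        subsoil_field.size - 1, 1
    )
    subsoil = np.searchsorted(edges[1:-1], ranks.reshape(shape), side="right")

    ditch_bottom = float(elevation.min()) - config.ditch_bottom_offset
    boundary = _boundary_mask(shape)
    max_water = float(elevation[boundary].min()) - config.embankment_margin
    max_water = max(max_water, ditch_bottom)

    cell_area = (config.cell_size**2) / 10_000.0  # m^2 -> ha
    return SiteModel(
        elevation_grid=elevation,
        peat_grid=peat,
        subsoil_grid=subsoil.astype(np.int16),
        subsoil_legend=legend,
        ditch_bottom_level=ditch_bottom,
        max_water_level=max_water,
        boundary_mask=boundary,
        cell_area=cell_area,
    )


def kampinneva_like_config(rng_seed: int = 0) -> SiteGenConfig:
    """Preset emulating the 123-ha reference site.

    123 rows x 100 cols of 10 m cells give exactly 123.00 ha. Subsoil
    fractions, peat-thickness range and the gently sloping topography
    with a few wet depressions follow the surveyed site statistics.
    """
    return SiteGenConfig(
        n_rows=123,
        n_cols=100,
        cell_size=10.0,
        base_elevation=78.3,
        regional_slope=(0.004, 0.002),
        noise_amplitude=0.25,
        noise_correlation=6.0,
        depression_count=3,
        depression_depth=1.1,
        depression_radius=10,
        rim_height=0.8,
        rim_width=4,
        peat_mean=60.0,
        peat_sd=45.0,
        peat_max=330.0,
        subsoil_fractions=_kampinneva_fractions(),
        ditch_bottom_offset=0.2,
        embankment_margin=0.0,
        rng_seed=rng_seed,
    )
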