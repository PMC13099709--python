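"""Raster and table I/O.

Rasters travel as plain TIFF files (one band, row-major, cell-centre
registration) with a JSON sidecar per site carrying everything a TIFF
tag cannot: hydrological levels, cell size, category legends, the
generator seed and the package version. ``write_site`` /``read_site``
round-trip a :class:`~cutaway.synthetic_site.SiteModel` losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .synthetic_site import SiteModel

_SIDECAR = "site.json"
_RASTERS = {
    "elevation": "elevation.tif",
    "peat": "peat_thickness.tif",
    "subsoil": "subsoil.tif",
}


class SiteIOError(OSError):
    """Raised for malformed or incomplete site directories."""


def write_raster(path: Path, array: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(array))


def read_raster(path: Path) -> np.ndarray:
    try:
        return tifffile.imread(str(path))
    except (FileNotFoundError, ValueError, tifffile.TiffFileError) as exc:
        raise SiteIOError(f"cannot read raster {path}: {exc}") from exc


def write_site(site: SiteModel, directory: str | Path, seed: int | None = None) -> Path:
    """Write a site as three TIFF rasters plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_raster(directory / _RASTERS["elevation"], site.elevation_grid.astype(np.float64))
    write_raster(directory / _RASTERS["peat"], site.peat_grid.astype(np.float64))
    write_raster(directory / _RASTERS["subsoil"], site.subsoil_grid.astype(np.int16))
    sidecar = {
        "format": "cutaway-site",
        "version": __version__,
        "ditch_bottom_level_m": site.ditch_bottom_level,
        "max_water_level_m": site.max_water_level,
        "cell_area_ha": site.cell_area,
        "subsoil_legend": list(site.subsoil_legend),
        "rng_seed": seed,
    }
    (directory / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return directory


def read_site(directory: str | Path) -> SiteModel:
    """Read a site directory written by :func:`write_site`."""
    directory = Path(directory)
    sidecar_path = directory / _SIDECAR
    if not sidecar_path.exists():
        raise SiteIOError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise SiteIOError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in ("ditch_bottom_level_m", "max_water_level_m", "cell_area_ha",
                "subsoil_legend"):
        if key not in sidecar:
            raise SiteIOError(f"sidecar {sidecar_path} lacks {key!r}")
    elevation = read_raster(directory / _RASTERS["elevation"])
    peat = read_raster(directory / _RASTERS["peat"])
    subsoil = read_raster(directory / _RASTERS["subsoil"])
    boundary = np.zeros(elevation.shape, dtype=bool)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    return SiteModel(
        elevation_grid=elevation,
        peat_grid=peat,
        subsoil_grid=subsoil,
        subsoil_legend=tuple(sidecar["subsoil_legend"]),
        ditch_bottom_level=float(sidecar["ditch_bottom_level_m"]),
        max_water_level=float(sidecar["max_water_level_m"]),
        boundary_mask=boundary,
        cell_area=float(sidecar["cell_area_ha"]),
    )


def write_labelled_raster(
    path: Path, array: np.ndarray, legend: dict[int, str]
) -> None:
    """Categorical raster plus a legend sidecar next to it."""
    path = Path(path)
    write_raster(path, np.asarray(array, dtype=np.int16))
    path.with_suffix(".json").write_text(
        json.dumps({"legend": {str(k): v for k, v in legend.items()}}, indent=2)
    )


def read_labelled_raster(path: Path) -> tuple[np.ndarray, dict[int, str]]:
    path = Path(path)
    array = read_raster(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    legend = {int(k): v for k, v in sidecar["legend"].items()}
    return array, legend
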