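"""Classified peatland grid: land use, climate, emission classes, areas.

The pipeline operates on any equal-area cell grid (each cell has the
same area in hectares); the map projection that guarantees this is not
part of the model. Rasters are 2-D NumPy arrays; a CSV cell-table
representation is provided in :mod:`peatghg.io` for on-disk exchange.

Land cover arrives as an ESA-GLC-style integer class raster and is
reclassified to the three IPCC land-use classes — cropland (CL),
grassland (GL), forest land (FL) — plus two mixed classes for cover
types that cannot be split (class 30 -> CL/GL/FL, class 180 -> GL/FL).
Water, bare soil, snow/ice and similar classes (200-230) carry no
peat-emission accounting and map to NONE.
"""
from __future__ import annotations

import enum
import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class LandUse(enum.IntEnum):
    """IPCC land-use class of a peat cell (NONE = not accountable)."""

    NONE = 0
    CL = 1
    GL = 2
    FL = 3
    MIX_CL_GL_FL = 4
    MIX_GL_FL = 5


class ClimateZone(enum.IntEnum):
    """Generic emission-factor climate zone.

    Polar and boreal climates share emission factors, hence a single
    BOREAL_POLAR zone; finer reporting subzones live in :class:`Subzone`.
    """

    UNSET = 0
    TROPICAL = 1
    TEMPERATE = 2
    BOREAL_POLAR = 3


class Subzone(enum.IntEnum):
    """Optional reporting subdivision (does not affect EF lookups)."""

    NONE = 0
    BOREAL = 1
    POLAR = 2
    OCEANIC = 3


#: Default ESA-GLC integer class -> land-use mapping.
DEFAULT_LANDCOVER_MAPPING: dict[int, LandUse] = {
    **{c: LandUse.CL for c in (11, 14, 20)},
    **{c: LandUse.FL for c in (40, 50, 60, 70, 90, 100, 110, 130, 160, 170)},
    **{c: LandUse.GL for c in (120, 140, 150, 190)},
    30: LandUse.MIX_CL_GL_FL,
    180: LandUse.MIX_GL_FL,
    **{c: LandUse.NONE for c in (200, 210, 220, 230)},
}

#: Default Köppen code -> (zone, subzone). Group B is split by aridity
#: temperature regime (hot arid with the tropics, cold arid temperate);
#: maritime west-coast classes are tagged OCEANIC for reporting only.
DEFAULT_KOPPEN_MAPPING: dict[str, tuple[ClimateZone, Subzone]] = {
    **{k: (ClimateZone.TROPICAL, Subzone.NONE) for k in ("Af", "Am", "Aw", "As")},
    **{k: (ClimateZone.TROPICAL, Subzone.NONE) for k in ("BWh", "BSh")},
    **{k: (ClimateZone.TEMPERATE, Subzone.NONE) for k in ("BWk", "BSk")},
    **{
        k: (ClimateZone.TEMPERATE, Subzone.NONE)
        for k in ("Csa", "Csb", "Csc", "Cwa", "Cwb", "Cwc", "Cfa")
    },
    **{k: (ClimateZone.TEMPERATE, Subzone.OCEANIC) for k in ("Cfb", "Cfc")},
    **{
        k: (ClimateZone.BOREAL_POLAR, Subzone.BOREAL)
        for k in ("Dfa", "Dfb", "Dfc", "Dfd", "Dwa", "Dwb", "Dwc", "Dwd",
                  "Dsa", "Dsb", "Dsc", "Dsd")
    },
    **{k: (ClimateZone.BOREAL_POLAR, Subzone.POLAR) for k in ("ET", "EF")},
}

ACCOUNTABLE_LANDUSES = (
    LandUse.CL,
    LandUse.GL,
    LandUse.FL,
    LandUse.MIX_CL_GL_FL,
    LandUse.MIX_GL_FL,
)
EF_CLIMATE_ZONES = (ClimateZone.TROPICAL, ClimateZone.TEMPERATE, ClimateZone.BOREAL_POLAR)


def reclassify_landcover(
    cover: np.ndarray,
    mapping: Mapping[int, LandUse] | None = None,
) -> np.ndarray:
    """Map an integer land-cover raster to a :class:`LandUse` raster.

    Unknown codes become NONE with a warning rather than failing, so
    rasters with dialectal class lists still run (their unknown area is
    simply excluded from accounting).
    """
    cover = np.asarray(cover)
    if not np.issubdtype(cover.dtype, np.integer):
        if np.issubdtype(cover.dtype, np.floating) and np.all(cover == np.floor(cover)):
            cover = cover.astype(np.int64)
        else:
            raise ValueError("land-cover raster must hold integer class codes")
    if mapping is None:
        mapping = DEFAULT_LANDCOVER_MAPPING
    out = np.full(cover.shape, LandUse.NONE, dtype=np.int8)
    present = np.unique(cover)
    unknown = [int(c) for c in present if int(c) not in mapping]
    if unknown:
        warnings.warn(f"unknown land-cover codes mapped to NONE: {unknown}", stacklevel=2)
        log.warning("unknown land-cover codes mapped to NONE: %s", unknown)
    for code in present:
        target = mapping.get(int(code), LandUse.NONE)
        out[cover == code] = target
    return out


def overlay_cropland(
    landuse: np.ndarray,
    cropland_probability: np.ndarray,
    threshold: float = 0.5,
) -> np.ndarray:
    """Superimpose cropland where its mapped probability exceeds ``threshold``.

    The comparison is strict (> threshold): a cell exactly at the
    threshold keeps its prior class. Cells already excluded (NONE —
    water, bare, ice) are never resurrected by the overlay.
    """
    p = np.asarray(cropland_probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("cropland probabilities must lie in [0, 1]")
    if landuse.shape != p.shape:
        raise ValueError("land-use and probability rasters are misaligned")
    out = np.array(landuse, copy=True)
    out[(p > threshold) & (out != LandUse.NONE)] = LandUse.CL
    return out


def reclassify_climate(
    koppen: np.ndarray,
    mapping: Mapping[str, tuple[ClimateZone, Subzone]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a Köppen class raster to the three generic EF zones.

    A purely per-cell lookup — zone boundaries follow the climate
    classes, not latitude. Returns ``(zone, subzone)`` integer rasters.

    Raises
    ------
    ValueError
        If any present Köppen code is missing from the mapping.
    """
    if mapping is None:
        mapping = DEFAULT_KOPPEN_MAPPING
    koppen = np.asarray(koppen)
    codes = np.unique(koppen)
    missing = [str(c) for c in codes if str(c) not in mapping]
    if missing:
        raise ValueError(f"unmapped Köppen classes: {missing}")
    zone = np.zeros(koppen.shape, dtype=np.int8)
    sub = np.zeros(koppen.shape, dtype=np.int8)
    for code in codes:
        z, s = mapping[str(code)]
        mask = koppen == code
        zone[mask] = z
        sub[mask] = s
    return zone, sub


def build_emission_classes(landuse: np.ndarray, climate: np.ndarray) -> np.ndarray:
    """Combine land use x climate into the 5 x 3 = 15 emission classes.

    Encoded as ``landuse * 10 + climate``; 0 where not accountable.
    """
    if landuse.shape != climate.shape:
        raise ValueError("land-use and climate rasters are misaligned")
    out = np.asarray(landuse, dtype=np.int16) * 10 + np.asarray(climate, dtype=np.int16)
    out[(landuse == LandUse.NONE) | (climate == ClimateZone.UNSET)] = 0
    return out


def emission_class_label(code: int) -> str:
    """Decode an emission-class code to e.g. ``'CL-tropical'``."""
    if code == 0:
        return "none"
    lu, cz = divmod(int(code), 10)
    return f"{LandUse(lu).name}-{ClimateZone(cz).name.lower()}"


def rescale_areas(stratum_areas: pd.Series, target_total: float) -> pd.Series:
    """Proportionally rescale stratum areas to a prescribed global total.

    Used to pin the mapped peatland area onto an independent global
    area estimate: every stratum is multiplied by
    ``target_total / sum(stratum_areas)``, so all pairwise proportions
    are preserved exactly.
    """
    areas = pd.Series(stratum_areas, dtype=float)
    if (areas < 0).any():
        raise ValueError("stratum areas must be nonnegative")
    if target_total <= 0:
        raise ValueError("target total must be positive")
    total = areas.sum()
    if total == 0:
        raise ValueError("cannot rescale: total input area is zero")
    return areas * (target_total / total)


def build_grid(
    peat: np.ndarray,
    landuse: np.ndarray,
    climate: np.ndarray,
    subzone: np.ndarray | None = None,
    country: np.ndarray | None = None,
    cell_area_ha: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-cell grid table from aligned rasters.

    Returns a DataFrame with one row per cell (row-major order) and
    columns ``cell_id, row, col, peat, landuse, climate, subzone,
    country, cell_area_ha, degradation``. ``degradation`` is initialised
    to NaN and filled by the degradation allocator.
    """
    peat = np.asarray(peat, dtype=bool)
    shapes = {peat.shape, landuse.shape, climate.shape}
    if subzone is not None:
        shapes.add(np.asarray(subzone).shape)
    if country is not None:
        shapes.add(np.asarray(country).shape)
    if len(shapes) != 1:
        raise ValueError("all rasters must share one grid shape")
    if cell_area_ha <= 0:
        raise ValueError("cell area must be positive")
    nrow, ncol = peat.shape
    rows, cols = np.divmod(np.arange(peat.size), ncol)
    grid = pd.DataFrame(
        {
            "cell_id": np.arange(peat.size),
            "row": rows,
            "col": cols,
            "peat": peat.ravel(),
            "landuse": np.asarray(landuse, dtype=np.int8).ravel(),
            "climate": np.asarray(climate, dtype=np.int8).ravel(),
            "subzone": (
                np.asarray(subzone, dtype=np.int8).ravel()
                if subzone is not None
                else np.zeros(peat.size, dtype=np.int8)
            ),
            "country": (
                np.asarray(country).ravel()
                if country is not None
                else np.zeros(peat.size, dtype=np.int32)
            ),
            "cell_area_ha": cell_area_ha,
            "degradation": np.nan,
        }
    )
    return grid


def accountable_mask(grid: pd.DataFrame) -> pd.Series:
    """Peat cells carrying a real land-use class (emission accounting)."""
    return grid["peat"] & (grid["landuse"] != LandUse.NONE)


def class_areas(grid: pd.DataFrame) -> pd.Series:
    """Per-emission-class area (ha) over accountable peat cells."""
    acc = grid[accountable_mask(grid)]
    codes = acc["landuse"].to_numpy(dtype=np.int16) * 10 + acc["climate"].to_numpy(np.int16)
    areas = pd.Series(acc["cell_area_ha"].to_numpy()).groupby(codes).sum()
    areas.index = [emission_class_label(c) for c in areas.index]
    return areas
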