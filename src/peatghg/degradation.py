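"""Country-level degradation statistics -> per-cell degradation fractions.

Drained-for-use peatland statistics exist per country, not per cell. The
allocation rule is: cropland on peat is always fully degrading (drainage
is a precondition for cropping), so CL carries degradation 1; whatever
degraded area the country statistic reports beyond its cropland area is
spread uniformly over the country's remaining (non-CL) accountable peat.
If the reported degraded area is smaller than the cropland-on-peat area,
the cropland area is taken as the better estimate and the non-CL
fraction is 0.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import LandUse, accountable_mask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountryRecord:
    """Per-country peatland statistics (areas in hectares)."""

    country: int | str
    peat_area: float
    cropland_on_peat_area: float
    degraded_area: float

    def __post_init__(self) -> None:
        if not (0 <= self.cropland_on_peat_area <= self.peat_area):
            raise ValueError(
                f"country {self.country}: cropland-on-peat area outside [0, peat area]"
            )
        if not (0 <= self.degraded_area <= self.peat_area):
            raise ValueError(f"country {self.country}: degraded area outside [0, peat area]")


@dataclass(frozen=True)
class DegradationAssignment:
    """Degradation fractions a country applies to its peat cells.

    ``fraction_cl`` is 1 by construction; ``fraction_other`` applies
    uniformly to GL, FL and the mixed classes.
    """

    country: int | str
    fraction_other: float
    fraction_cl: float = 1.0


def degradation_ratio(record: CountryRecord) -> float:
    """Degraded share of a country's peat area (0 intact .. 1 fully degraded)."""
    if record.peat_area <= 0:
        raise ValueError(f"country {record.country}: degradation ratio undefined (no peat area)")
    return min(max(record.degraded_area / record.peat_area, 0.0), 1.0)


def allocate(record: CountryRecord) -> DegradationAssignment:
    """Split a country's degraded area between its CL and non-CL peat.

    Let c = cropland/peat and d = degraded/peat. CL is fully degraded in
    both branches. If d <= c the country statistic is superseded by the
    cropland area and non-CL peat gets fraction 0; otherwise the residual
    degraded area (d - c) x peat_area is spread uniformly over the
    non-CL peat area.
    """
    c = record.cropland_on_peat_area / record.peat_area
    d = degradation_ratio(record)
    if d <= c:
        return DegradationAssignment(record.country, 0.0)
    non_cl_area = record.peat_area - record.cropland_on_peat_area
    if non_cl_area <= 0:
        raise ValueError(
            f"country {record.country}: degraded area exceeds cropland but no non-CL peat exists"
        )
    frac = (d - c) * record.peat_area / non_cl_area
    if frac > 1.0:
        warnings.warn(
            f"country {record.country}: residual degraded area exceeds non-CL peat; "
            "fraction clipped to 1",
            stacklevel=2,
        )
        frac = 1.0
    return DegradationAssignment(record.country, frac)


def build_degradation_map(
    grid: pd.DataFrame,
    assignments: Mapping[int | str, DegradationAssignment],
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Fill the grid's ``degradation`` column from country assignments.

    CL cells get 1; other accountable cells get their country's uniform
    fraction; NONE / non-peat cells get 0. With ``strict=False``,
    countries missing from ``assignments`` default to fraction 0 outside
    CL (the non-degraded end of the scale) with a warning.
    """
    out = grid.copy()
    out["degradation"] = 0.0
    acc = accountable_mask(out)
    missing = sorted(set(out.loc[acc, "country"].unique()) - set(assignments))
    if missing:
        if strict:
            raise ValueError(f"no degradation assignment for countries: {missing}")
        warnings.warn(
            f"countries without statistics default to non-CL degradation 0: {missing}",
            stacklevel=2,
        )
    frac_other = out.loc[acc, "country"].map(
        {k: a.fraction_other for k, a in assignments.items()}
    )
    out.loc[acc, "degradation"] = frac_other.fillna(0.0).to_numpy()
    out.loc[acc & (out["landuse"] == LandUse.CL), "degradation"] = 1.0
    return out


def allocate_table(records: pd.DataFrame) -> dict[int | str, DegradationAssignment]:
    """Vector convenience: allocate every row of a country CSV table.

    Expects columns ``country_id, peat_area_ha, cropland_on_peat_ha,
    degraded_area_ha``.
    """
    out: dict[int | str, DegradationAssignment] = {}
    for rec in records.itertuples(index=False):
        cr = CountryRecord(
            rec.country_id, rec.peat_area_ha, rec.cropland_on_peat_ha, rec.degraded_area_ha
        )
        out[cr.country] = allocate(cr)
    return out


def degraded_area_check(grid: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Book-keeping report: cell-level degraded area vs country statistic.

    For countries where the reported degraded area exceeds their
    cropland-on-peat area, the two must agree (conservation). Where the
    cropland override applied, the cell-level total equals the cropland
    area instead; both readings are reported.
    """
    acc = grid[accountable_mask(grid)]
    cell_level = (acc["degradation"] * acc["cell_area_ha"]).groupby(acc["country"]).sum()
    rep = records.set_index("country_id").copy()
    rep["cell_level_degraded_ha"] = cell_level.reindex(rep.index).fillna(0.0)
    rep["override_applied"] = (
        rep["degraded_area_ha"] <= rep["cropland_on_peat_ha"]
    )
    return rep.reset_index()
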