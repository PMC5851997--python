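"""Emission factors, CO2-equivalent aggregation, and emission maps.

Each (land use x climate) class carries per-gas annual fluxes — CO2,
CH4, N2O (gas-native mass per hectare) and leached dissolved organic
carbon DOC (as C mass, assumed fully oxidized to CO2 downstream). They
are collapsed to a single CO2-equivalent rate per class,

    co2eq = CO2 + GWP_CH4 * CH4 + GWP_N2O * N2O + (44/12) * DOC,

applied layer-by-layer to the (min, mean, max) uncertainty triple.
Potential emissions are what a cell would emit if drained (rate x
area); actual emissions scale that by the cell's degradation fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import (
    ClimateZone,
    LandUse,
    Subzone,
    accountable_mask,
)
from .uncertainty import Range, envelope

GASES = ("CO2", "CH4", "N2O", "DOC")
C_TO_CO2 = 44.0 / 12.0


@dataclass(frozen=True)
class GWPSet:
    """Global warming potentials used for CO2-equivalent aggregation."""

    gwp_ch4: float = 28.0
    gwp_n2o: float = 265.0
    horizon: str = "GWP100"

    def __post_init__(self) -> None:
        if self.gwp_ch4 <= 0 or self.gwp_n2o <= 0:
            raise ValueError("GWPs must be positive")


@dataclass(frozen=True)
class EmissionFactor:
    """Per-class annual flux rates with explicit min/mean/max ranges.

    Gas rates are t gas ha^-1 a^-1 (DOC as t C ha^-1 a^-1); the
    aggregated ``co2eq`` is t CO2-eq ha^-1 a^-1.
    """

    landuse: LandUse
    climate: ClimateZone
    co2: Range
    ch4: Range
    n2o: Range
    doc: Range
    co2eq: Range | None = None

    def __post_init__(self) -> None:
        for name in ("co2", "ch4", "n2o", "doc"):
            r: Range = getattr(self, name)
            r.validate()
            if r.min < 0:
                raise ValueError(f"{name} rate must be nonnegative (rewetting not modelled)")


def aggregate_ef(ef: EmissionFactor, gwp: GWPSet = GWPSet()) -> EmissionFactor:
    """Fill an EF's CO2-equivalent triple by interval arithmetic.

    Min combines with min and max with max across gases: the resulting
    range is the explicit extreme of the per-gas extremes.
    """
    co2eq = Range(
        *(
            getattr(ef.co2, layer)
            + gwp.gwp_ch4 * getattr(ef.ch4, layer)
            + gwp.gwp_n2o * getattr(ef.n2o, layer)
            + C_TO_CO2 * getattr(ef.doc, layer)
            for layer in ("min", "mean", "max")
        )
    ).validate()
    return replace(ef, co2eq=co2eq)


def mixed_class_ef(members: list[EmissionFactor], landuse: LandUse | None = None) -> EmissionFactor:
    """Combine pure-class EFs into a mixed-class EF (mean + envelope).

    Mean rates are unweighted means of the member means; the range is
    the envelope (min of mins, max of maxes), so the combined range
    contains every member's range. Members must share a climate zone.
    """
    if len(members) < 2:
        raise ValueError("a mixed class needs at least two member EFs")
    climates = {m.climate for m in members}
    if len(climates) != 1:
        raise ValueError("cannot mix EFs across climate zones")
    if landuse is None:
        landuse = LandUse.MIX_CL_GL_FL if len(members) >= 3 else LandUse.MIX_GL_FL
    kwargs = {
        name: envelope([getattr(m, name) for m in members])
        for name in ("co2", "ch4", "n2o", "doc")
    }
    ef = EmissionFactor(landuse=landuse, climate=next(iter(climates)), **kwargs)
    if all(m.co2eq is not None for m in members):
        ef = replace(ef, co2eq=envelope([m.co2eq for m in members]))  # type: ignore[misc]
    return ef


EFTable = dict[tuple[LandUse, ClimateZone], EmissionFactor]


def complete_ef_table(pure: list[EmissionFactor], gwp: GWPSet = GWPSet()) -> EFTable:
    """Aggregate pure-class EFs and derive the mixed-class entries.

    Input: CL/GL/FL EFs per climate zone. Output: all 15 emission
    classes keyed by (land use, climate), each with co2eq filled.
    """
    table: EFTable = {}
    for ef in pure:
        table[(ef.landuse, ef.climate)] = aggregate_ef(ef, gwp)
    for zone in {ef.climate for ef in pure}:
        trio = [table.get((lu, zone)) for lu in (LandUse.CL, LandUse.GL, LandUse.FL)]
        if None in trio:
            missing = [lu.name for lu, t in zip((LandUse.CL, LandUse.GL, LandUse.FL), trio) if t is None]
            raise ValueError(f"zone {zone.name}: missing pure-class EFs {missing}")
        table[(LandUse.MIX_CL_GL_FL, zone)] = mixed_class_ef(list(trio), LandUse.MIX_CL_GL_FL)
        table[(LandUse.MIX_GL_FL, zone)] = mixed_class_ef(trio[1:], LandUse.MIX_GL_FL)
    return table


def potential_emission_map(grid: pd.DataFrame, ef_table: EFTable) -> pd.DataFrame:
    """Per-cell potential emission (t CO2-eq a^-1) if the cell were drained.

    Returns the grid with columns ``potential_min/mean/max`` = co2eq
    rate x cell area; 0 on non-accountable cells.
    """
    out = grid.copy()
    for layer in ("min", "mean", "max"):
        out[f"potential_{layer}"] = 0.0
    acc = accountable_mask(out)
    keys = set(zip(out.loc[acc, "landuse"], out.loc[acc, "climate"]))
    missing = [
        f"{LandUse(lu).name}-{ClimateZone(cz).name.lower()}"
        for lu, cz in sorted(keys)
        if (LandUse(lu), ClimateZone(cz)) not in ef_table
        or ef_table[(LandUse(lu), ClimateZone(cz))].co2eq is None
    ]
    if missing:
        raise ValueError(f"no aggregated emission factor for classes: {missing}")
    for lu, cz in keys:
        ef = ef_table[(LandUse(lu), ClimateZone(cz))]
        mask = acc & (out["landuse"] == lu) & (out["climate"] == cz)
        area = out.loc[mask, "cell_area_ha"]
        for layer in ("min", "mean", "max"):
            out.loc[mask, f"potential_{layer}"] = getattr(ef.co2eq, layer) * area
    return out


def actual_emission_map(grid_with_potential: pd.DataFrame) -> pd.DataFrame:
    """Scale potential emissions by each cell's degradation fraction.

    Reported per area of *peatland*, not per area of disturbed peatland:
    a class half degraded reports half its potential rate.
    """
    out = grid_with_potential.copy()
    if out["degradation"].isna().any():
        raise ValueError("degradation map not filled; run the allocator first")
    for layer in ("min", "mean", "max"):
        out[f"actual_{layer}"] = out[f"potential_{layer}"] * out["degradation"]
    return out


_REPORT_ROWS = ("tropical", "temperate", "boreal", "polar", "oceanic")
_LU_COLS = {
    "area_cl_mha": LandUse.CL,
    "area_gl_mha": LandUse.GL,
    "area_fl_mha": LandUse.FL,
    "area_gl_fl_mha": LandUse.MIX_GL_FL,
    "area_cl_gl_fl_mha": LandUse.MIX_CL_GL_FL,
}


def _reporting_label(climate: int, subzone: int) -> str:
    if climate == ClimateZone.TROPICAL:
        return "tropical"
    if climate == ClimateZone.TEMPERATE:
        return "oceanic" if subzone == Subzone.OCEANIC else "temperate"
    return "polar" if subzone == Subzone.POLAR else "boreal"


def summarize(actual_grid: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell actual emissions to the per-climate overview.

    One row per reporting climate (tropical, temperate, boreal, polar,
    oceanic): peat area by land-use column (Mha), degrading area (Mha),
    and actual emissions min/mean/max (Gt CO2-eq a^-1). The totals row
    is computed on demand by :func:`summary_totals`, never stored.
    """
    acc = actual_grid[accountable_mask(actual_grid)].copy()
    rows = []
    labels = (
        acc.apply(lambda r: _reporting_label(r["climate"], r["subzone"]), axis=1)
        if len(acc)
        else pd.Series(dtype=object)
    )
    for name in _REPORT_ROWS:
        sub = acc[labels == name] if len(acc) else acc
        row: dict[str, float] = {"climate": name}
        row["area_mha"] = sub["cell_area_ha"].sum() / 1e6
        for col, lu in _LU_COLS.items():
            row[col] = sub.loc[sub["landuse"] == lu, "cell_area_ha"].sum() / 1e6
        row["degrading_mha"] = (sub["degradation"] * sub["cell_area_ha"]).sum() / 1e6
        for layer in ("min", "mean", "max"):
            row[f"emission_{layer}_gt"] = sub[f"actual_{layer}"].sum() / 1e9
        rows.append(row)
    return pd.DataFrame(rows).set_index("climate")


def summary_totals(summary: pd.DataFrame) -> pd.Series:
    """Column sums of a per-climate summary (the overview's totals row)."""
    return summary.sum(axis=0)


def co2eq_to_ceq(x: float) -> float:
    """Convert Gt CO2-eq to Gt CO2-C-eq (carbon mass), factor 12/44."""
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return x * 12.0 / 44.0
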