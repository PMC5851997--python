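"""Cell-table raster I/O, emission-factor tables, and run configuration.

Rasters travel on disk as CSV cell tables (``cell_id, row, col, value``)
on the equal-area grid contract; in memory they are 2-D NumPy arrays.
Emission factors and run settings are YAML.
"""
from __future__ import annotations

import hashlib
import importlib.resources as resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .emissions import EFTable, EmissionFactor, GWPSet, complete_ef_table
from .grid import ClimateZone, LandUse
from .uncertainty import Range

_GAS_FIELDS = {"CO2": "co2", "CH4": "ch4", "N2O": "n2o", "DOC": "doc"}


def raster_to_cell_table(arr: np.ndarray, value_name: str = "value") -> pd.DataFrame:
    """Flatten a 2-D raster to the CSV cell-table layout (row-major)."""
    arr = np.asarray(arr)
    nrow, ncol = arr.shape
    rows, cols = np.divmod(np.arange(arr.size), ncol)
    return pd.DataFrame(
        {"cell_id": np.arange(arr.size), "row": rows, "col": cols, value_name: arr.ravel()}
    )


def cell_table_to_raster(table: pd.DataFrame, value_name: str = "value") -> np.ndarray:
    """Rebuild the 2-D raster from a cell table."""
    nrow = int(table["row"].max()) + 1
    ncol = int(table["col"].max()) + 1
    if len(table) != nrow * ncol:
        raise ValueError("cell table does not cover a full rectangular grid")
    out = np.empty(nrow * ncol, dtype=table[value_name].dtype)
    out[table["cell_id"].to_numpy()] = table[value_name].to_numpy()
    return out.reshape(nrow, ncol)


def write_raster_csv(
    arr: np.ndarray, path: str | Path, value_name: str = "value", header: str | None = None
) -> None:
    """Write a raster as a CSV cell table, optionally with a provenance line."""
    path = Path(path)
    table = raster_to_cell_table(arr, value_name)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_csv(fh, index=False)


def read_raster_csv(path: str | Path, value_name: str = "value") -> np.ndarray:
    """Read a CSV cell table back into a 2-D raster (skips ``#`` lines)."""
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    return cell_table_to_raster(table, value_name)


def _packaged(name: str) -> Path:
    return Path(str(resources.files("peatghg").joinpath("data", name)))


def load_ef_table(path: str | Path | None = None, gwp: GWPSet = GWPSet()) -> EFTable:
    """Load per-gas emission factors from YAML and aggregate to CO2-eq.

    The YAML holds one record per (landuse, climate, gas) with
    ``min/mean/max`` and a unit tag; pure classes (CL, GL, FL) are
    required per climate zone and the mixed classes are derived. With
    no path, the packaged synthetic default table is used.
    """
    if path is None:
        path = _packaged("ef_synthetic.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    grouped: dict[tuple[LandUse, ClimateZone], dict[str, Range]] = {}
    for rec in raw["emission_factors"]:
        lu = LandUse[rec["landuse"]]
        cz = ClimateZone[rec["climate"].upper()]
        gas = rec["gas"]
        if gas not in _GAS_FIELDS:
            raise ValueError(f"unknown gas {gas!r}")
        grouped.setdefault((lu, cz), {})[_GAS_FIELDS[gas]] = Range(
            float(rec["min"]), float(rec["mean"]), float(rec["max"])
        )
    pure = []
    for (lu, cz), gases in grouped.items():
        missing = set(_GAS_FIELDS.values()) - set(gases)
        if missing:
            raise ValueError(f"{lu.name}-{cz.name}: missing gases {sorted(missing)}")
        pure.append(EmissionFactor(landuse=lu, climate=cz, **gases))
    return complete_ef_table(pure, gwp)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load run configuration, layering user YAML over packaged defaults."""
    with open(_packaged("default_config.yaml")) as fh:
        cfg: dict[str, Any] = yaml.safe_load(fh)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    """Short stable digest of a config for provenance headers."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
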