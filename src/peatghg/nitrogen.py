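"""Carbon and nitrogen stock budgets of degrading peat and mineral soil.

Peat and mineral-soil organic matter differ sharply in stoichiometry:
tropical peat has a median C/N near 29.7 and northern peat near 49.0,
while mineral-soil organic matter sits near 10.7. N stocks and releases
follow directly from C stocks via these medians (N = C / (C/N)), which
is what makes carbon storage in mineral soil nitrogen-costly compared
with avoiding peat emissions.

The mineral-soil C/N median comes from profile databases after removing
records that are organic soils in disguise or carry analytical errors:
Histosols, C/N outside [5, 100], or organic C concentration above
200 mg g^-1 (three independent OR-ed exclusion rules).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Configured zone medians (dimensionless C/N by mass).
TROPICAL_PEAT_CN = 29.7
NORTHERN_PEAT_CN = 49.0
MINERAL_CN = 10.7

FILTER_RULES = ("histosol", "cn_ratio", "concentration")


@dataclass(frozen=True)
class MineralSoilParams:
    """Mineral-soil sequestration scenario constants.

    ``agricultural_area_mha`` defaults to 4923 (1563 arable + 3360
    meadow/pasture); the saturating sink reaches ``seq_min_gt`` ..
    ``seq_max_gt`` additional C within ``horizon_years``.
    """

    agricultural_area_mha: float = 4923.0
    arable_area_mha: float = 1563.0
    pasture_area_mha: float = 3360.0
    soil_c_percent: float = 1.35
    mineral_cn: float = MINERAL_CN
    seq_min_gt: float = 24.0
    seq_max_gt: float = 64.0
    horizon_years: float = 63.0

    def __post_init__(self) -> None:
        vals = (
            self.agricultural_area_mha,
            self.soil_c_percent,
            self.mineral_cn,
            self.seq_min_gt,
            self.seq_max_gt,
            self.horizon_years,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all mineral-soil parameters must be positive")
        if self.seq_min_gt > self.seq_max_gt:
            raise ValueError("sequestration range inverted")


def filter_cn_samples(samples: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the mineral-soil exclusion rules to a C/N sample table.

    Removes Histosol-flagged records, records with C/N < 5 or > 100,
    and records with organic C concentration > 200 mg g^-1 (a record
    violating several rules counts in each). Expects columns
    ``histosol`` (bool), ``cn_ratio``, ``c_conc_mg_g``.

    Returns the retained table and per-rule exclusion counts.
    """
    histosol = samples["histosol"].astype(bool)
    bad_cn = (samples["cn_ratio"] < 5) | (samples["cn_ratio"] > 100)
    bad_conc = samples["c_conc_mg_g"] > 200
    counts = {
        "histosol": int(histosol.sum()),
        "cn_ratio": int(bad_cn.sum()),
        "concentration": int(bad_conc.sum()),
    }
    retained = samples[~(histosol | bad_cn | bad_conc)].copy()
    return retained, counts


def median_cn(samples: pd.DataFrame | pd.Series | np.ndarray) -> float:
    """Median C/N of a sample table (mean of the middle pair for even n)."""
    values = samples["cn_ratio"] if isinstance(samples, pd.DataFrame) else samples
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median of an empty sample set is undefined")
    return float(np.median(values))


def nitrogen_from_carbon(c_stock_gt: float, cn: float) -> float:
    """N stock (Gt N) bound in a C stock (Gt C) at mass ratio C/N = cn."""
    if cn <= 0:
        raise ValueError("C/N ratio must be positive")
    return c_stock_gt / cn


def total_n_release(budgets: pd.DataFrame) -> float:
    """Total avoidable N release (Gt N) from degrading peat, all zones.

    ``budgets`` needs columns ``degrading_c_gt`` and ``cn_median`` with
    one row per reporting climate; every zone with degrading stock must
    carry a median.
    """
    if budgets["cn_median"].isna().any() or (budgets["cn_median"] <= 0).any():
        bad = budgets.loc[
            budgets["cn_median"].isna() | (budgets["cn_median"] <= 0), "climate"
        ].tolist()
        raise ValueError(f"missing or invalid C/N median for zones: {bad}")
    return float((budgets["degrading_c_gt"] / budgets["cn_median"]).sum())


def mineral_n_requirement(
    seq_c_gt: float, params: MineralSoilParams = MineralSoilParams()
) -> tuple[float, float]:
    """N immobilized in mineral soil to store ``seq_c_gt`` Gt C.

    Returns ``(total Gt N, annual Mt N a^-1)`` with the annual rate
    averaged over the sequestration horizon.
    """
    if seq_c_gt < 0:
        raise ValueError("sequestered C must be nonnegative")
    total = seq_c_gt / params.mineral_cn
    annual = total / params.horizon_years * 1000.0
    return total, annual


def n_cost_ratio(
    budgets: pd.DataFrame, mineral_cn: float = MINERAL_CN
) -> float:
    """How many times more N mineral-soil storage costs than peat emits.

    Ratio of N per C immobilized in mineral soil (1 / mineral C/N) to
    the N released per C emitted from degrading peat (total N release /
    total degrading C).
    """
    total_c = float(budgets["degrading_c_gt"].sum())
    if total_c <= 0:
        raise ValueError("no degrading peat C in budgets")
    peat_n_per_c = total_n_release(budgets) / total_c
    return (1.0 / mineral_cn) / peat_n_per_c
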