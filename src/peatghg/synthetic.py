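"""Synthetic world and sample generators, plus the packaged overview fixture.

No deposited GIS sources ship with the package; instead a seeded
generator emits the full input stack the pipeline expects — peat
extent, ESA-GLC-style land cover, cropland probability, Köppen climate
codes, country blocks, and the matching per-country degradation
statistics — with configurable composition so every aggregate-level
computation can be exercised and checked against closed-form
expectations.

The generated world is deliberately simple spatially (climate bands,
country stripes, independent per-cell draws): it reproduces the
*statistical* structure the accounting assumes (areas by class,
per-country statistics consistent with the maps) but none of the
spatial autocorrelation of real peat basins.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import (
    ClimateZone,
    LandUse,
    build_grid,
    overlay_cropland,
    reclassify_climate,
    reclassify_landcover,
)
from .nitrogen import NORTHERN_PEAT_CN, TROPICAL_PEAT_CN

#: Representative land-cover codes per intended land use.
_LANDCOVER_CHOICES = {
    LandUse.CL: (11, 14, 20),
    LandUse.GL: (120, 140, 150, 190),
    LandUse.FL: (40, 50, 70, 100, 160),
    LandUse.MIX_CL_GL_FL: (30,),
    LandUse.MIX_GL_FL: (180,),
    LandUse.NONE: (200, 210, 220, 230),
}
_KOPPEN_BY_ZONE = {
    ClimateZone.TROPICAL: "Af",
    ClimateZone.TEMPERATE: "Cfa",
    ClimateZone.BOREAL_POLAR: "Dfc",
}


@dataclass(frozen=True)
class WorldSpec:
    """Composition targets for a synthetic peatland world.

    ``climate_shares`` split grid rows into latitudinal bands;
    ``peat_fraction`` is the per-band probability that a cell is peat;
    ``landuse_shares`` is the intended composition of peat cells (must
    sum to 1). Half of the intended cropland enters through land-cover
    codes and half through the cropland-probability overlay, so both
    classification routes are exercised. ``degradation_ratios`` are
    per-country targets, cycled over countries; values below the
    cropland share exercise the cropland-override branch.
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    n_countries: int = 6
    cell_area_ha: float = 100.0
    climate_shares: dict[ClimateZone, float] = field(
        default_factory=lambda: {
            ClimateZone.TROPICAL: 0.25,
            ClimateZone.TEMPERATE: 0.30,
            ClimateZone.BOREAL_POLAR: 0.45,
        }
    )
    polar_rows_share: float = 0.15  # share of the boreal band tagged ET
    peat_fraction: dict[ClimateZone, float] = field(
        default_factory=lambda: {
            ClimateZone.TROPICAL: 0.20,
            ClimateZone.TEMPERATE: 0.10,
            ClimateZone.BOREAL_POLAR: 0.40,
        }
    )
    landuse_shares: dict[LandUse, float] = field(
        default_factory=lambda: {
            LandUse.CL: 0.15,
            LandUse.GL: 0.25,
            LandUse.FL: 0.45,
            LandUse.MIX_CL_GL_FL: 0.05,
            LandUse.MIX_GL_FL: 0.05,
            LandUse.NONE: 0.05,
        }
    )
    degradation_ratios: tuple[float, ...] = (0.05, 0.5, 0.3, 0.0, 0.8, 0.2)
    cropland_noise: float = 0.45  # ceiling of probability noise on non-CL cells

    def validate(self) -> None:
        if abs(sum(self.climate_shares.values()) - 1.0) > 1e-9:
            raise ValueError("climate shares must sum to 1")
        if abs(sum(self.landuse_shares.values()) - 1.0) > 1e-9:
            raise ValueError("land-use shares must sum to 1")
        if any(not 0 <= f <= 1 for f in self.peat_fraction.values()):
            raise ValueError("peat fractions must lie in [0, 1]")
        if any(not 0 <= d <= 1 for d in self.degradation_ratios):
            raise ValueError("degradation ratios must lie in [0, 1]")
        if not 0 <= self.cropland_noise < 0.5:
            raise ValueError("cropland noise ceiling must lie in [0, 0.5)")


@dataclass
class World:
    """A generated input stack (all rasters share one grid)."""

    spec: WorldSpec
    peat: np.ndarray  # bool
    landcover: np.ndarray  # ESA-GLC-style integer codes
    cropland_p: np.ndarray  # float in [0, 1]
    koppen: np.ndarray  # Köppen code strings
    country: np.ndarray  # integer country ids
    country_table: pd.DataFrame  # country_id, peat_area_ha, cropland_on_peat_ha, degraded_area_ha


def generate_world(spec: WorldSpec) -> World:
    """Generate rasters and a consistent country statistics table.

    Deterministic given ``spec.seed``. The emitted country records are
    computed from the generated maps themselves (cropland-on-peat from
    the post-overlay land use), so the statistics and rasters can never
    disagree. ``peat_area_ha`` in the table counts accountable peat
    (peat cells with an assignable land use).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.shape

    # climate bands (rows), polar tail of the boreal band tagged ET
    zones = list(spec.climate_shares)
    bounds = np.cumsum([spec.climate_shares[z] for z in zones])
    row_edges = np.concatenate([[0], np.round(bounds * nrow).astype(int)])
    koppen = np.empty(spec.shape, dtype="U3")
    zone_of_row = np.empty(nrow, dtype=np.int8)
    for z, lo, hi in zip(zones, row_edges[:-1], row_edges[1:]):
        koppen[lo:hi, :] = _KOPPEN_BY_ZONE[z]
        zone_of_row[lo:hi] = z
        if z == ClimateZone.BOREAL_POLAR and hi > lo:
            n_polar = int(round(spec.polar_rows_share * (hi - lo)))
            if n_polar:
                koppen[hi - n_polar : hi, :] = "ET"

    # peat extent: per-band Bernoulli
    p_peat = np.array([spec.peat_fraction[ClimateZone(z)] for z in zone_of_row])
    peat = rng.random(spec.shape) < p_peat[:, None]

    # intended land use on peat cells; half of CL arrives via the overlay
    lus = list(spec.landuse_shares)
    probs = np.array([spec.landuse_shares[lu] for lu in lus])
    intended = rng.choice(len(lus), size=spec.shape, p=probs)
    landcover = np.full(spec.shape, 210, dtype=np.int64)  # water off peat
    cropland_p = rng.uniform(0.0, spec.cropland_noise, size=spec.shape)
    via_overlay = rng.random(spec.shape) < 0.5
    for i, lu in enumerate(lus):
        mask = peat & (intended == i)
        codes = _LANDCOVER_CHOICES[lu]
        landcover[mask] = rng.choice(codes, size=int(mask.sum()))
        if lu == LandUse.CL:
            ov = mask & via_overlay
            landcover[ov] = rng.choice(_LANDCOVER_CHOICES[LandUse.FL], size=int(ov.sum()))
            cropland_p[ov] = rng.uniform(0.55, 1.0, size=int(ov.sum()))

    country = np.repeat(
        np.floor(np.arange(ncol) * spec.n_countries / ncol).astype(np.int32)[None, :],
        nrow,
        axis=0,
    )

    # country statistics from the realized maps
    landuse = overlay_cropland(reclassify_landcover(landcover), cropland_p)
    acc = peat & (landuse != LandUse.NONE)
    records = []
    for cid in range(spec.n_countries):
        cmask = country == cid
        peat_ha = float(np.sum(acc & cmask)) * spec.cell_area_ha
        cl_ha = float(np.sum(acc & cmask & (landuse == LandUse.CL))) * spec.cell_area_ha
        d = spec.degradation_ratios[cid % len(spec.degradation_ratios)]
        records.append(
            {
                "country_id": cid,
                "peat_area_ha": peat_ha,
                "cropland_on_peat_ha": cl_ha,
                "degraded_area_ha": d * peat_ha,
            }
        )
    return World(
        spec=spec,
        peat=peat,
        landcover=landcover,
        cropland_p=cropland_p,
        koppen=koppen,
        country=country,
        country_table=pd.DataFrame(records),
    )


def world_to_grid(world: World) -> pd.DataFrame:
    """Run the classification pipeline on a world's rasters."""
    landuse = overlay_cropland(reclassify_landcover(world.landcover), world.cropland_p)
    climate, subzone = reclassify_climate(world.koppen)
    return build_grid(
        world.peat,
        landuse,
        climate,
        subzone=subzone,
        country=world.country,
        cell_area_ha=world.spec.cell_area_ha,
    )


def expected_potential_emission(spec: WorldSpec, ef_table, layer: str = "mean") -> float:
    """Closed-form expected potential emission (t CO2-eq a^-1).

    Sums, over climate zones and accountable land uses, the expected
    accountable area (cells x band share x peat fraction x land-use
    share x cell area) times the class's aggregated CO2-eq rate. The
    independent oracle for end-to-end pipeline checks.
    """
    nrow, ncol = spec.shape
    total = 0.0
    for zone, zshare in spec.climate_shares.items():
        n_cells = nrow * ncol * zshare * spec.peat_fraction[zone]
        for lu, lshare in spec.landuse_shares.items():
            if lu == LandUse.NONE:
                continue
            rate = getattr(ef_table[(lu, zone)].co2eq, layer)
            total += n_cells * lshare * spec.cell_area_ha * rate
    return total


@dataclass(frozen=True)
class CNGeneratorSpec:
    """Log-normal C/N sample population with planted filter violators.

    ``median`` is the target median of the clean subpopulation (the
    log-normal location is its log, so the population median equals the
    target exactly); ``contamination`` rates plant records violating
    each exclusion rule.
    """

    median: float
    sigma: float = 0.35
    contamination: dict[str, float] = field(default_factory=dict)
    # keys: histosol, cn_low, cn_high, concentration

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be positive")
        rates = self.contamination.values()
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) > 1 + 1e-12:
            raise ValueError("contamination rates must lie in [0,1] and sum to <= 1")


TROPICAL_PEAT_SPEC = CNGeneratorSpec(median=TROPICAL_PEAT_CN, sigma=0.4)
NORTHERN_PEAT_SPEC = CNGeneratorSpec(median=NORTHERN_PEAT_CN, sigma=0.5)
MINERAL_SPEC = CNGeneratorSpec(
    median=10.7,
    sigma=0.3,
    contamination={"histosol": 0.02, "cn_low": 0.01, "cn_high": 0.01, "concentration": 0.02},
)


def generate_cn_samples(spec: CNGeneratorSpec, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw a C/N sample table with the stated clean median and violators.

    Columns: ``sample_id, region, landuse, histosol, cn_ratio,
    c_conc_mg_g``. Contaminated records violate exactly one planted
    rule each; clean records pass every exclusion rule.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    cn = rng.lognormal(mean=np.log(spec.median), sigma=spec.sigma, size=n)
    cn = np.clip(cn, 5.0 + 1e-6, 100.0 - 1e-6)  # clean records must pass the filter
    conc = rng.uniform(5.0, 150.0, size=n)
    histosol = np.zeros(n, dtype=bool)

    kinds = ["clean", "histosol", "cn_low", "cn_high", "concentration"]
    rates = [spec.contamination.get(k, 0.0) for k in kinds[1:]]
    probs = np.array([max(1.0 - sum(rates), 0.0)] + rates)
    which = rng.choice(len(kinds), size=n, p=probs / probs.sum())
    histosol[which == 1] = True
    cn[which == 2] = rng.uniform(0.5, 4.99, size=int(np.sum(which == 2)))
    cn[which == 3] = rng.uniform(100.01, 300.0, size=int(np.sum(which == 3)))
    conc[which == 4] = rng.uniform(200.01, 600.0, size=int(np.sum(which == 4)))

    return pd.DataFrame(
        {
            "sample_id": np.arange(n),
            "region": "synthetic",
            "landuse": "unknown",
            "histosol": histosol,
            "cn_ratio": cn,
            "c_conc_mg_g": conc,
        }
    )


def table1_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged global peatland overview (areas, emissions, C stocks).

    Returns ``(summary, budgets)``: the per-climate area/emission
    overview in the same column layout :func:`peatghg.emissions.summarize`
    produces (areas in Mha, emissions in Gt CO2-eq a^-1), and the
    per-climate C budget (Gt C) with the configured C/N medians. Values
    are the published per-row figures; totals are always computed by
    summation, so component rounding shows up exactly as in the source
    (e.g. the minimum-emission total sums to 0.30 against a printed
    0.31). The sub-0.1 oceanic row is carried as 0.
    """
    summary = pd.DataFrame(
        {
            "area_mha": [58.7, 18.5, 360.9, 25.0, 0.0],
            "area_cl_mha": [8.5, 3.5, 6.8, 0.1, 0.0],
            "area_gl_mha": [11.3, 5.0, 85.6, 14.9, 0.0],
            "area_fl_mha": [34.6, 8.9, 249.5, 9.7, 0.0],
            "area_gl_fl_mha": [1.6, 0.7, 17.9, 0.1, 0.0],
            "area_cl_gl_fl_mha": [2.7, 0.6, 1.1, 0.3, 0.0],
            "degrading_mha": [24.2, 10.6, 15.5, 0.7, 0.0],
            "emission_min_gt": [0.04, 0.10, 0.16, 0.0, 0.0],
            "emission_mean_gt": [1.48, 0.16, 0.26, 0.01, 0.0],
            "emission_max_gt": [2.79, 0.21, 0.36, 0.02, 0.0],
        },
        index=pd.Index(["tropical", "temperate", "boreal", "polar", "oceanic"], name="climate"),
    )
    budgets = pd.DataFrame(
        {
            "climate": ["tropical", "temperate", "boreal", "polar", "oceanic"],
            "peat_c_gt": [119.2, 21.9, 427.0, 29.6, 0.0],
            "degrading_c_gt": [49.1, 12.5, 18.3, 0.8, 0.0],
            "cn_median": [
                TROPICAL_PEAT_CN,
                NORTHERN_PEAT_CN,
                NORTHERN_PEAT_CN,
                NORTHERN_PEAT_CN,
                NORTHERN_PEAT_CN,
            ],
        }
    )
    return summary, budgets
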