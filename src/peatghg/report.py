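"""Headline quantities of the global peatland accounting, recomputed.

Every number here is derived at call time from the packaged per-climate
overview fixture and the configured stoichiometric constants — nothing
is stored pre-computed. The functions are the single source for the
command-line report and the reproduction script.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .emissions import co2eq_to_ceq, summary_totals
from .nitrogen import (
    MINERAL_CN,
    MineralSoilParams,
    n_cost_ratio,
    nitrogen_from_carbon,
    total_n_release,
)
from .synthetic import table1_fixture
from .trajectory import (
    PoolState,
    Range,
    ScenarioConfig,
    equivalence_range,
    mineral_sink,
    peat_trajectory,
    scenario_asymptote,
    scenario_trajectory,
)


def fixture_pools(budgets: pd.DataFrame, summary: pd.DataFrame) -> list[PoolState]:
    """Per-climate degrading pools with C-eq emission rates.

    Pools are the degrading peat C stocks (Gt C); rates convert each
    climate's actual CO2-eq emission triple to C-equivalent mass.
    """
    pools = []
    for rec in budgets.itertuples(index=False):
        if rec.degrading_c_gt <= 0:
            continue
        row = summary.loc[rec.climate]
        rate = Range(
            co2eq_to_ceq(row["emission_min_gt"]),
            co2eq_to_ceq(row["emission_mean_gt"]),
            co2eq_to_ceq(row["emission_max_gt"]),
        )
        pools.append(PoolState(rec.climate, rec.degrading_c_gt, rate))
    return pools


@dataclass
class HeadlineReport:
    """Recomputed headline numbers with the units they are reported in."""

    total_emission_gt_co2eq: Range
    total_emission_gt_ceq: Range
    area_share_boreal_polar_pct: float
    area_share_tropical_pct: float
    area_share_temperate_pct: float
    degrading_share_tropical_pct: float
    degrading_share_temperate_pct: float
    degrading_share_boreal_polar_pct: float
    degrading_vs_agricultural_pct: float
    total_peat_area_mha: float
    total_degrading_area_mha: float
    tropical_n_stock_gt: float
    tropical_n_release_gt: float
    northern_n_release_gt: float
    total_n_release_gt: float
    mineral_n_per_c_kg_kg: float
    mineral_n_total_gt: tuple[float, float]
    mineral_n_annual_mt: tuple[float, float]
    n_cost_ratio: float
    scenario_asymptote_gt_c: float
    total_degrading_c_gt: float
    equivalence_years: Range = field(default=None)  # type: ignore[assignment]
    scenario_equivalence_years: Range = field(default=None)  # type: ignore[assignment]
    annualized_n_avoidance_mt: float = float("nan")


def compute_headlines(
    mineral: MineralSoilParams = MineralSoilParams(),
    dt: float = 0.5,
    horizon: float = 1200.0,
    scenario: ScenarioConfig = ScenarioConfig(),
    reference_equivalence_years: float | None = None,
) -> HeadlineReport:
    """Recompute every headline number from the packaged fixture.

    ``reference_equivalence_years`` optionally fixes the horizon used to
    annualize the avoidable N release (e.g. a published mean equivalence
    point); by default the recomputed mean equivalence point is used.
    """
    summary, budgets = table1_fixture()
    totals = summary_totals(summary)
    em = Range(
        totals["emission_min_gt"], totals["emission_mean_gt"], totals["emission_max_gt"]
    )
    area_total = totals["area_mha"]
    degr_total = totals["degrading_mha"]
    bp_area = summary.loc["boreal", "area_mha"] + summary.loc["polar", "area_mha"]
    bp_degr = summary.loc["boreal", "degrading_mha"] + summary.loc["polar", "degrading_mha"]

    b = budgets.set_index("climate")
    tropical_n_stock = nitrogen_from_carbon(
        b.loc["tropical", "peat_c_gt"], b.loc["tropical", "cn_median"]
    )
    tropical_n_release = nitrogen_from_carbon(
        b.loc["tropical", "degrading_c_gt"], b.loc["tropical", "cn_median"]
    )
    total_release = total_n_release(budgets)
    northern_release = total_release - tropical_n_release

    n_per_c = 1.0 / mineral.mineral_cn
    from .nitrogen import mineral_n_requirement

    lo_total, lo_annual = mineral_n_requirement(mineral.seq_min_gt, mineral)
    hi_total, hi_annual = mineral_n_requirement(mineral.seq_max_gt, mineral)

    pools = fixture_pools(budgets, summary)
    peat = peat_trajectory(pools, horizon, dt)
    sink = mineral_sink(
        Range(mineral.seq_min_gt, (mineral.seq_min_gt + mineral.seq_max_gt) / 2, mineral.seq_max_gt),
        horizon,
        dt,
        t_seq=mineral.horizon_years,
    )
    eq = equivalence_range(peat, sink)
    scen = scenario_trajectory(pools, horizon, dt, scenario)
    scen_eq = equivalence_range(scen, sink)

    eq_year = (
        reference_equivalence_years if reference_equivalence_years is not None else eq.mean
    )
    from .trajectory import annualized_n_avoidance

    return HeadlineReport(
        total_emission_gt_co2eq=em,
        total_emission_gt_ceq=Range(*(co2eq_to_ceq(x) for x in em)),
        area_share_boreal_polar_pct=100 * bp_area / area_total,
        area_share_tropical_pct=100 * summary.loc["tropical", "area_mha"] / area_total,
        area_share_temperate_pct=100 * summary.loc["temperate", "area_mha"] / area_total,
        degrading_share_tropical_pct=100 * summary.loc["tropical", "degrading_mha"] / degr_total,
        degrading_share_temperate_pct=100 * summary.loc["temperate", "degrading_mha"] / degr_total,
        degrading_share_boreal_polar_pct=100 * bp_degr / degr_total,
        degrading_vs_agricultural_pct=100 * degr_total / mineral.agricultural_area_mha,
        total_peat_area_mha=area_total,
        total_degrading_area_mha=degr_total,
        tropical_n_stock_gt=tropical_n_stock,
        tropical_n_release_gt=tropical_n_release,
        northern_n_release_gt=northern_release,
        total_n_release_gt=total_release,
        mineral_n_per_c_kg_kg=n_per_c,
        mineral_n_total_gt=(lo_total, hi_total),
        mineral_n_annual_mt=(lo_annual, hi_annual),
        n_cost_ratio=n_cost_ratio(budgets, mineral.mineral_cn),
        scenario_asymptote_gt_c=scenario_asymptote(pools, scenario),
        total_degrading_c_gt=float(budgets["degrading_c_gt"].sum()),
        equivalence_years=eq,
        scenario_equivalence_years=scen_eq,
        annualized_n_avoidance_mt=annualized_n_avoidance(total_release, eq_year),
    )


#: Published headline estimates the report compares against (for the
#: human-readable deviation column only; never used in computation).
PUBLISHED = {
    "total_emission_mean_gt_co2eq": 1.91,
    "total_emission_max_gt_co2eq": 3.38,
    "total_emission_mean_gt_ceq": 0.52,
    "area_share_boreal_polar_pct": 83.3,
    "area_share_tropical_pct": 12.7,
    "degrading_share_temperate_pct": 21.0,
    "tropical_n_stock_gt": 4.0,
    "tropical_n_release_gt": 1.7,
    "northern_n_release_gt": 0.6,
    "total_n_release_gt": 2.3,
    "mineral_n_per_c_kg_kg": 0.094,
    "mineral_n_total_lo_gt": 2.2,
    "mineral_n_total_hi_gt": 5.9,
    "mineral_n_annual_lo_mt": 35.2,
    "mineral_n_annual_hi_mt": 93.9,
    "n_cost_ratio": 3.4,
    "scenario_asymptote_gt_c": 161.6,
    "annualized_n_avoidance_mt": 9.7,
}


def format_report(rep: HeadlineReport) -> str:
    """Human-readable comparison of recomputed vs published estimates."""
    rows = [
        ("global actual emission, mean (Gt CO2-eq/a)", rep.total_emission_gt_co2eq.mean,
         PUBLISHED["total_emission_mean_gt_co2eq"]),
        ("global actual emission, max (Gt CO2-eq/a)", rep.total_emission_gt_co2eq.max,
         PUBLISHED["total_emission_max_gt_co2eq"]),
        ("global actual emission, mean (Gt CO2-C-eq/a)", rep.total_emission_gt_ceq.mean,
         PUBLISHED["total_emission_mean_gt_ceq"]),
        ("boreal+polar area share (%)", rep.area_share_boreal_polar_pct,
         PUBLISHED["area_share_boreal_polar_pct"]),
        ("tropical area share (%)", rep.area_share_tropical_pct,
         PUBLISHED["area_share_tropical_pct"]),
        ("temperate share of degrading area (%)", rep.degrading_share_temperate_pct,
         PUBLISHED["degrading_share_temperate_pct"]),
        ("tropical peat N stock (Gt N)", rep.tropical_n_stock_gt,
         PUBLISHED["tropical_n_stock_gt"]),
        ("tropical avoidable N release (Gt N)", rep.tropical_n_release_gt,
         PUBLISHED["tropical_n_release_gt"]),
        ("northern avoidable N release (Gt N)", rep.northern_n_release_gt,
         PUBLISHED["northern_n_release_gt"]),
        ("total avoidable N release (Gt N)", rep.total_n_release_gt,
         PUBLISHED["total_n_release_gt"]),
        ("mineral-soil N per C (kg/kg)", rep.mineral_n_per_c_kg_kg,
         PUBLISHED["mineral_n_per_c_kg_kg"]),
        ("mineral-soil N demand, low (Gt N)", rep.mineral_n_total_gt[0],
         PUBLISHED["mineral_n_total_lo_gt"]),
        ("mineral-soil N demand, high (Gt N)", rep.mineral_n_total_gt[1],
         PUBLISHED["mineral_n_total_hi_gt"]),
        ("N cost ratio (mineral vs peat)", rep.n_cost_ratio, PUBLISHED["n_cost_ratio"]),
        ("doubling-scenario max release (Gt C)", rep.scenario_asymptote_gt_c,
         PUBLISHED["scenario_asymptote_gt_c"]),
        ("annualized N avoidance (Mt N/a)", rep.annualized_n_avoidance_mt,
         PUBLISHED["annualized_n_avoidance_mt"]),
    ]
    lines = [f"{'quantity':<48}{'recomputed':>12}{'published':>12}{'dev %':>8}"]
    for name, got, ref in rows:
        dev = 100 * (got - ref) / ref if ref else float("nan")
        lines.append(f"{name:<48}{got:>12.3f}{ref:>12.3f}{dev:>8.1f}")
    lines.append("")
    lines.append(
        "equivalence point, current area (years, min/mean/max): "
        f"{rep.equivalence_years.min:.0f}/{rep.equivalence_years.mean:.0f}/"
        f"{rep.equivalence_years.max:.0f}"
    )
    lines.append(
        "equivalence point, doubling scenario (years, min/mean/max): "
        f"{rep.scenario_equivalence_years.min:.0f}/{rep.scenario_equivalence_years.mean:.0f}/"
        f"{rep.scenario_equivalence_years.max:.0f}"
    )
    lines.append(
        "(equivalence points — and the annualized N avoidance, which divides by the mean "
        "equivalence year — depend on the pluggable sink saturation form; published values "
        "used a source-specific equation and are not compared line-by-line)"
    )
    return "\n".join(lines)
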