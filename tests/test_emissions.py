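"""CO2-eq aggregation, emission maps, and the per-climate summary."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peatghg import (
    ClimateZone,
    EmissionFactor,
    GWPSet,
    LandUse,
    actual_emission_map,
    aggregate_ef,
    allocate_table,
    build_degradation_map,
    co2eq_to_ceq,
    mixed_class_ef,
    potential_emission_map,
    summarize,
    summary_totals,
)
from peatghg.emissions import C_TO_CO2
from peatghg.grid import accountable_mask
from peatghg.uncertainty import Range, envelope

ZERO = Range(0.0, 0.0, 0.0)


def _ef(co2=ZERO, ch4=ZERO, n2o=ZERO, doc=ZERO,
        lu=LandUse.CL, cz=ClimateZone.TROPICAL):
    return EmissionFactor(landuse=lu, climate=cz, co2=co2, ch4=ch4, n2o=n2o, doc=doc)


def ranges(min_val=0.0, max_val=50.0):
    """Strategy for an ordered nonnegative (min, mean, max) triple."""
    return st.tuples(
        st.floats(min_val, max_val), st.floats(min_val, max_val), st.floats(min_val, max_val)
    ).map(lambda t: Range(*sorted(t)))


class TestAggregateEF:
    def test_all_zero_rates_give_zero_co2eq(self):
        assert aggregate_ef(_ef()).co2eq == ZERO

    def test_carbon_mass_converts_with_44_over_12(self):
        # CO2 flux quoted as C mass must be converted to CO2 mass first
        as_c = Range(1.0, 2.0, 3.0)
        ef = _ef(co2=Range(*(x * C_TO_CO2 for x in as_c)))
        got = aggregate_ef(ef).co2eq
        assert got.min == pytest.approx(3.67, abs=0.005)
        assert got.mean == pytest.approx(7.33, abs=0.005)
        assert got.max == pytest.approx(11.0, abs=0.005)

    def test_gwp_weighting(self):
        ef = _ef(ch4=Range(0.0, 1.0, 2.0), n2o=Range(0.0, 0.1, 0.2), doc=Range(0.0, 1.2, 2.4))
        got = aggregate_ef(ef, GWPSet(28.0, 265.0)).co2eq
        assert got.mean == pytest.approx(28.0 + 26.5 + 1.2 * C_TO_CO2)
        assert got.min == 0.0
        assert got.max == pytest.approx(56.0 + 53.0 + 2.4 * C_TO_CO2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            _ef(co2=Range(-1.0, 0.0, 1.0))

    @settings(max_examples=100, derandomize=True)
    @given(co2=ranges(), ch4=ranges(0, 2), n2o=ranges(0, 0.5), doc=ranges(0, 3))
    def test_interval_order_preserved(self, co2, ch4, n2o, doc):
        got = aggregate_ef(_ef(co2=co2, ch4=ch4, n2o=n2o, doc=doc)).co2eq
        assert got.min <= got.mean <= got.max


class TestMixedClassEF:
    def test_identical_members_unchanged(self):
        ef = aggregate_ef(_ef(co2=Range(1.0, 2.0, 3.0)))
        mixed = mixed_class_ef([ef, ef])
        assert mixed.co2 == ef.co2 and mixed.co2eq == ef.co2eq

    def test_mean_is_unweighted_member_mean(self):
        a = aggregate_ef(_ef(co2=Range(1.0, 2.0, 3.0)))
        b = aggregate_ef(_ef(co2=Range(2.0, 4.0, 6.0), lu=LandUse.GL))
        assert mixed_class_ef([a, b]).co2.mean == pytest.approx(3.0)

    def test_mixed_climates_rejected(self):
        a = _ef()
        b = _ef(cz=ClimateZone.TEMPERATE)
        with pytest.raises(ValueError, match="climate"):
            mixed_class_ef([a, b])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(ranges(), min_size=2, max_size=4))
    def test_envelope_contains_every_member(self, members):
        efs = [_ef(co2=r) for r in members]
        mixed = mixed_class_ef(efs)
        for r in members:
            assert mixed.co2.min <= r.min and mixed.co2.max >= r.max


class TestEmissionMaps:
    def test_one_hectare_cell_reports_the_rate(self, toy_grid, ef_table):
        out = potential_emission_map(toy_grid, ef_table)
        cl = out[(out["landuse"] == LandUse.CL) & out["peat"]].iloc[0]
        rate = ef_table[(LandUse.CL, ClimateZone.TROPICAL)].co2eq
        assert cl["potential_mean"] == pytest.approx(rate.mean)

    def test_unaccountable_cells_emit_nothing(self, toy_grid, ef_table):
        out = potential_emission_map(toy_grid, ef_table)
        assert (out.loc[~accountable_mask(out), "potential_mean"] == 0.0).all()

    def test_missing_ef_names_the_class(self, toy_grid):
        with pytest.raises(ValueError, match="CL-tropical"):
            potential_emission_map(toy_grid, {})

    def test_map_total_matches_brute_force_tally(self, small_world, small_grid, ef_table):
        out = potential_emission_map(small_grid, ef_table)
        # oracle: per-class area x class rate, tallied cell by cell
        acc = out[accountable_mask(out)]
        brute = sum(
            ef_table[(LandUse(r.landuse), ClimateZone(r.climate))].co2eq.mean * r.cell_area_ha
            for r in acc.itertuples()
        )
        assert out["potential_mean"].sum() == pytest.approx(brute, rel=1e-9)

    def test_zero_degradation_zeroes_the_actual_map(self, toy_grid, ef_table):
        grid = potential_emission_map(toy_grid, ef_table)
        grid["degradation"] = 0.0
        out = actual_emission_map(grid)
        assert (out["actual_mean"] == 0.0).all()

    def test_full_degradation_equals_potential(self, toy_grid, ef_table):
        grid = potential_emission_map(toy_grid, ef_table)
        grid["degradation"] = 1.0
        out = actual_emission_map(grid)
        np.testing.assert_allclose(out["actual_max"], out["potential_max"])

    def test_half_degraded_class_reports_half_the_rate(self, toy_grid, ef_table):
        # actual emission is per area of peatland, not per degraded area
        grid = potential_emission_map(toy_grid, ef_table)
        grid["degradation"] = 0.5
        out = actual_emission_map(grid)
        acc = accountable_mask(out)
        np.testing.assert_allclose(
            out.loc[acc, "actual_mean"], 0.5 * out.loc[acc, "potential_mean"]
        )

    def test_actual_never_exceeds_potential(self, small_world, small_grid, ef_table):
        grid = build_degradation_map(small_grid, allocate_table(small_world.country_table))
        out = actual_emission_map(potential_emission_map(grid, ef_table))
        for layer in ("min", "mean", "max"):
            assert (out[f"actual_{layer}"] <= out[f"potential_{layer}"] + 1e-12).all()

    def test_unfilled_degradation_rejected(self, toy_grid, ef_table):
        grid = potential_emission_map(toy_grid, ef_table)
        with pytest.raises(ValueError, match="degradation"):
            actual_emission_map(grid)


class TestSummarize:
    def test_empty_grid_summarizes_to_zero(self, toy_grid, ef_table):
        grid = toy_grid.copy()
        grid["peat"] = False
        grid["degradation"] = 0.0
        out = summarize(actual_emission_map(potential_emission_map(grid, ef_table)))
        assert (summary_totals(out) == 0.0).all()

    def test_totals_equal_brute_force_cell_sums(self, small_world, small_grid, ef_table):
        grid = build_degradation_map(small_grid, allocate_table(small_world.country_table))
        out = actual_emission_map(potential_emission_map(grid, ef_table))
        summary = summarize(out)
        totals = summary_totals(summary)
        assert totals["emission_mean_gt"] == pytest.approx(
            out["actual_mean"].sum() / 1e9, rel=1e-9
        )
        assert totals["area_mha"] == pytest.approx(
            out.loc[accountable_mask(out), "cell_area_ha"].sum() / 1e6, rel=1e-9
        )
        assert (summary["emission_min_gt"] <= summary["emission_mean_gt"]).all()
        assert (summary["emission_mean_gt"] <= summary["emission_max_gt"]).all()


class TestCO2eqToCeq:
    def test_conversion_factor(self):
        assert co2eq_to_ceq(44.0) == pytest.approx(12.0)

    def test_linearity(self):
        assert co2eq_to_ceq(1.91 + 3.38) == pytest.approx(
            co2eq_to_ceq(1.91) + co2eq_to_ceq(3.38)
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            co2eq_to_ceq(float("nan"))
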