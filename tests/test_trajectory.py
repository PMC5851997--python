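"""Pool-exhaustion trajectories, the mineral sink, equivalence, scenarios."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peatghg import (
    PoolState,
    Range,
    ScenarioConfig,
    annualized_n_avoidance,
    co2eq_to_ceq,
    equivalence_point,
    equivalence_range,
    mineral_sink,
    mm_expansion,
    peat_trajectory,
    scenario_asymptote,
    scenario_trajectory,
    table1_fixture,
)
from peatghg.report import fixture_pools


def _pool(pool=10.0, rate=1.0, label="x"):
    return PoolState(label, pool, Range(rate, rate, rate))


class TestPeatTrajectory:
    def test_linear_depletion_until_exhaustion(self):
        traj = peat_trajectory([_pool(10.0, 1.0)], horizon=20.0, dt=1.0)
        assert traj.loc[traj["t"] == 5.0, "mean"].item() == pytest.approx(5.0)
        assert traj.loc[traj["t"] == 10.0, "mean"].item() == pytest.approx(10.0)
        assert traj.loc[traj["t"] == 20.0, "mean"].item() == pytest.approx(10.0)

    def test_tropical_pool_exhausts_near_122_years(self):
        # quotient oracle: 49.1 Gt / (1.48 x 12/44 Gt/a) = 121.6 a
        rate = co2eq_to_ceq(1.48)
        traj = peat_trajectory([PoolState("tropical", 49.1, Range(rate, rate, rate))],
                               horizon=200.0, dt=0.1)
        exhausted = traj.loc[traj["mean"] >= 49.1 - 1e-9, "t"].min()
        assert exhausted == pytest.approx(49.1 / rate, abs=0.1)
        assert 121.0 < exhausted < 122.5

    def test_total_cumulative_capped_at_summed_stocks(self):
        summary, budgets = table1_fixture()
        pools = fixture_pools(budgets, summary)
        traj = peat_trajectory(pools, horizon=5000.0, dt=1.0)
        cap = budgets["degrading_c_gt"].sum()  # 80.7 from per-class stocks
        assert traj["mean"].iloc[-1] == pytest.approx(cap, rel=1e-9)
        for layer in ("min", "mean", "max"):
            assert (traj[layer] <= cap + 1e-9).all()
            assert (np.diff(traj[layer]) >= -1e-12).all()

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError):
            PoolState("x", -1.0, Range(0.0, 0.0, 0.0))


class TestMineralSink:
    def test_starts_at_zero(self):
        sink = mineral_sink(horizon=100.0, dt=1.0)
        assert (sink.iloc[0][["min", "mean", "max"]] == 0.0).all()

    def test_reaches_capacity_at_63_years_within_one_percent(self):
        sink = mineral_sink(Range(24.0, 44.0, 64.0), horizon=100.0, dt=1.0, t_seq=63.0)
        at63 = sink.loc[sink["t"] == 63.0].iloc[0]
        for layer, smax in (("min", 24.0), ("mean", 44.0), ("max", 64.0)):
            assert at63[layer] == pytest.approx(smax, rel=0.011)
            assert (sink[layer] <= smax + 1e-9).all()

    def test_nondecreasing(self):
        sink = mineral_sink(horizon=200.0, dt=0.5)
        for layer in ("min", "mean", "max"):
            assert (np.diff(sink[layer]) >= -1e-12).all()

    def test_pluggable_form_validated(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            mineral_sink(horizon=10.0, dt=1.0, form=lambda t, s: s * np.cos(t))


class TestEquivalencePoint:
    def test_identical_series_cross_at_origin(self):
        t = np.arange(0.0, 10.0)
        assert equivalence_point(t, t, t) == 0.0

    def test_zero_sink_crosses_at_origin(self):
        t = np.arange(0.0, 10.0)
        assert equivalence_point(0.5 * t, np.zeros_like(t), t) == 0.0

    def test_linear_ramp_oracle_crossing_at_88_years(self):
        # peat 0.5 Gt/a unlimited vs linear ramp to 44 Gt at 63 a:
        # crossing solves 0.5 t = 44 beyond the ramp -> t = 88
        t = np.arange(0.0, 200.0, 0.25)
        peat = 0.5 * t
        sink = np.minimum(44.0 * t / 63.0, 44.0)
        assert equivalence_point(peat, sink, t) == pytest.approx(88.0, abs=0.26)

    def test_no_crossing_returns_infinity(self):
        t = np.arange(0.0, 10.0)
        assert equivalence_point(0.1 * t, 10.0 + t, t) == float("inf")

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValueError):
            equivalence_point(np.zeros(5), np.zeros(4), np.arange(4.0))

    def test_fixture_mean_equivalence_exists_beyond_sink_horizon(self):
        # the published sink equation is not available; any valid curve
        # calibrated to 44 Gt at 63 a must yield a finite crossing past 63 a
        summary, budgets = table1_fixture()
        pools = fixture_pools(budgets, summary)
        peat = peat_trajectory(pools, horizon=4000.0, dt=0.5)
        sink = mineral_sink(horizon=4000.0, dt=0.5)
        eq = equivalence_range(peat, sink)
        assert 63.0 < eq.mean < float("inf")
        assert eq.min <= eq.mean <= eq.max

    def test_equivalence_monotone_in_rates_and_capacity(self):
        t_kw = dict(horizon=2000.0, dt=0.5)
        base_pools = [_pool(80.0, 0.5)]
        faster = [_pool(80.0, 0.8)]
        peat_base = peat_trajectory(base_pools, **t_kw)
        peat_fast = peat_trajectory(faster, **t_kw)
        small = mineral_sink(Range(24.0, 44.0, 64.0), **t_kw)
        big = mineral_sink(Range(30.0, 55.0, 80.0), **t_kw)
        t = peat_base["t"].to_numpy()
        eq_base = equivalence_point(peat_base["mean"].to_numpy(), small["mean"].to_numpy(), t)
        eq_fast = equivalence_point(peat_fast["mean"].to_numpy(), small["mean"].to_numpy(), t)
        eq_big = equivalence_point(peat_base["mean"].to_numpy(), big["mean"].to_numpy(), t)
        assert eq_fast <= eq_base <= eq_big

    def test_crossing_stable_under_dt_halving(self):
        summary, budgets = table1_fixture()
        pools = fixture_pools(budgets, summary)
        eqs = []
        for dt in (1.0, 0.5):
            peat = peat_trajectory(pools, horizon=400.0, dt=dt)
            sink = mineral_sink(horizon=400.0, dt=dt)
            eqs.append(
                equivalence_point(peat["mean"].to_numpy(), sink["mean"].to_numpy(),
                                  peat["t"].to_numpy())
            )
        assert abs(eqs[1] - eqs[0]) / eqs[0] < 0.01


class TestMMExpansion:
    def test_starts_at_current_area(self):
        assert mm_expansion(0.0) == 1.0

    def test_half_of_added_area_at_half_saturation(self):
        assert mm_expansion(60.0, ScenarioConfig(2.0, 60.0)) == pytest.approx(1.5)

    def test_asymptotic_doubling(self):
        assert mm_expansion(1e9) == pytest.approx(2.0, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mm_expansion(-1.0)


class TestScenarioTrajectory:
    def test_unit_multiplier_degenerates_to_baseline(self):
        pools = [_pool(20.0, 0.4)]
        base = peat_trajectory(pools, horizon=100.0, dt=0.5)
        scen = scenario_trajectory(pools, horizon=100.0, dt=0.5,
                                   config=ScenarioConfig(1.0, 60.0))
        np.testing.assert_allclose(scen["mean"], base["mean"], atol=1e-12)

    def test_scenario_dominates_baseline(self):
        summary, budgets = table1_fixture()
        pools = fixture_pools(budgets, summary)
        base = peat_trajectory(pools, horizon=600.0, dt=0.5)
        scen = scenario_trajectory(pools, horizon=600.0, dt=0.5)
        for layer in ("min", "mean", "max"):
            assert (scen[layer] >= base[layer] - 1e-12).all()

    def test_conservation_under_expansion(self):
        summary, budgets = table1_fixture()
        pools = fixture_pools(budgets, summary)
        scen = scenario_trajectory(pools, horizon=3000.0, dt=1.0)
        cap = scenario_asymptote(pools)  # 2 x summed stocks
        for layer in ("min", "mean", "max"):
            assert (scen[layer] <= cap + 1e-9).all()
            assert (np.diff(scen[layer]) >= -1e-12).all()

    def test_asymptote_doubles_the_stocks(self):
        summary, budgets = table1_fixture()
        pools = fixture_pools(budgets, summary)
        assert scenario_asymptote(pools) == pytest.approx(
            2 * budgets["degrading_c_gt"].sum()
        )

    def test_coarse_dt_warns(self):
        with pytest.warns(UserWarning, match="half-saturation"):
            scenario_trajectory([_pool()], horizon=100.0, dt=10.0)


class TestAnnualizedNAvoidance:
    def test_published_horizon_conversion(self):
        assert annualized_n_avoidance(2.3, 238.0) == pytest.approx(9.66, abs=0.01)

    def test_zero_nitrogen(self):
        assert annualized_n_avoidance(0.0, 100.0) == 0.0

    def test_halving_horizon_doubles_rate(self):
        assert annualized_n_avoidance(2.3, 119.0) == pytest.approx(
            2 * annualized_n_avoidance(2.3, 238.0)
        )

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError):
            annualized_n_avoidance(2.3, 0.0)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    pool=st.floats(1.0, 200.0),
    rate=st.floats(0.01, 2.0),
    horizon=st.floats(50.0, 500.0),
)
def test_cumulative_never_exceeds_pool(pool, rate, horizon):
    traj = peat_trajectory([_pool(pool, rate)], horizon=horizon, dt=1.0)
    assert (traj["mean"] <= pool + 1e-9).all()
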