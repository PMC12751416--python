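"""Cell mass balance: net input integration, stocks, budgets, brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacfilter.io import BedProfile, FlowSpec, TCCSeries
from bacfilter.massbalance import (
    budget_series,
    cell_budget,
    cumulative_net_input,
    standing_stock,
)
from bacfilter.simulate import SimConfig, generate_experiment
from bacfilter.quantitation import depth_cell_density

FLOW = FlowSpec(1440.0)  # 1 mL/min


def brute_force_net_input(inf: TCCSeries, eff: TCCSeries, q_ml_day, t_a, t_b):
    """Per-day bookkeeping on an integer grid (left-hold), independent oracle."""
    total = 0.0
    for day in range(int(t_a), int(t_b)):
        v_in = inf.tcc[np.searchsorted(inf.days, day, side="right") - 1]
        v_out = eff.tcc[np.searchsorted(eff.days, day, side="right") - 1]
        total += (v_in - v_out) * q_ml_day
    return total


class TestNetInput:
    def test_identical_series_cancel(self):
        s = TCCSeries("influent", [0.0, 10.0], [1e5, 2e5])
        e = TCCSeries("effluent", [0.0, 10.0], [1e5, 2e5])
        assert cumulative_net_input(s, e, FLOW, (0, 20)) == 0.0

    def test_constant_difference_hand_sum(self):
        # (1e5 - 5e4) cells/mL * 1440 mL/day * 10 days = 7.2e8
        inf = TCCSeries("influent", [0.0], [1e5])
        eff = TCCSeries("effluent", [0.0], [5e4])
        assert cumulative_net_input(inf, eff, FLOW, (0, 10)) == pytest.approx(7.2e8)

    def test_stepped_influent_hand_sum(self):
        # 5 days at 1e5 + 5 days at 2e5, effluent 0: 1440*(5e5+1e6) = 2.16e9
        inf = TCCSeries("influent", [0.0, 5.0], [1e5, 2e5])
        eff = TCCSeries("effluent", [0.0], [0.0])
        assert cumulative_net_input(inf, eff, FLOW, (0, 10)) == pytest.approx(2.16e9)

    def test_window_before_coverage_rejected(self):
        inf = TCCSeries("influent", [5.0], [1e5])
        eff = TCCSeries("effluent", [0.0], [0.0])
        with pytest.raises(ValueError, match="precedes"):
            cumulative_net_input(inf, eff, FLOW, (0, 10))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_additivity_over_interior_split(self, seed):
        rng = np.random.default_rng(seed)
        days = np.sort(rng.choice(np.arange(0, 60), size=6, replace=False)).astype(float)
        days[0] = 0.0
        inf = TCCSeries("influent", days, rng.uniform(0, 2e6, 6))
        eff = TCCSeries("effluent", days, rng.uniform(0, 5e5, 6))
        a, b, c = 0.0, float(rng.integers(1, 60)), 60.0
        if not a < b < c:
            b = 30.0
        whole = cumulative_net_input(inf, eff, FLOW, (a, c))
        parts = cumulative_net_input(inf, eff, FLOW, (a, b)) + cumulative_net_input(
            inf, eff, FLOW, (b, c)
        )
        assert whole == pytest.approx(parts, rel=1e-12, abs=1e-3)


class TestStandingStock:
    def test_two_section_hand_sum(self):
        profile = BedProfile(("top", "bottom"), (0.0, 2.0), (2.0, 90.0), (100.0, 130.0))
        assert standing_stock(profile, {"top": 1e8, "bottom": 1e6}) == pytest.approx(
            1.013e10
        )

    def test_uniform_density_factorises(self):
        profile = BedProfile(("a", "b"), (0.0, 10.0), (10.0, 20.0), (50.0, 70.0))
        q = 3.3e7
        assert standing_stock(profile, {"a": q, "b": q}) == pytest.approx(q * 120.0)

    def test_missing_section_named(self):
        profile = BedProfile(("a", "b"), (0.0, 10.0), (10.0, 20.0), (50.0, 70.0))
        with pytest.raises(KeyError, match="b"):
            standing_stock(profile, {"a": 1e7})


class TestCellBudget:
    def test_balanced_when_stock_change_equals_input(self):
        b = cell_budget(1e9, 1.5e9, 5e8, interval=10)
        assert b.delta_cells == 0.0
        assert b.phase == "balanced"

    def test_growth_arithmetic(self):
        b = cell_budget(1e8, 1e9, 7.2e8, interval=10)
        assert b.delta_cells == pytest.approx(1.8e8)
        assert b.rate == pytest.approx(1.8e7)
        assert b.phase == "growth"

    def test_decay_arithmetic(self):
        b = cell_budget(5e8, 5e8, 7.2e8, interval=10)
        assert b.delta_cells == pytest.approx(-7.2e8)
        assert b.rate == pytest.approx(-7.2e7)
        assert b.phase == "decay"

    def test_literal_equation_flips_sign(self):
        b = cell_budget(1e8, 1e9, 7.2e8, interval=10, eq1_literal=True)
        assert b.delta_cells == pytest.approx(-1.8e8)
        assert b.phase == "decay"

    def test_rate_is_delta_over_interval_exactly(self):
        b = cell_budget(0.0, 3e9, 1e9, interval=7)
        assert b.rate == b.delta_cells / 7

    def test_non_positive_interval_rejected(self):
        with pytest.raises(ValueError):
            cell_budget(0.0, 1.0, 0.0, interval=0)


class TestBudgetSeries:
    def test_two_takedowns_one_budget_plus_startup(self):
        inf = TCCSeries("influent", [0.0], [1e5])
        eff = TCCSeries("effluent", [0.0], [5e4])
        budgets = budget_series([10, 20], [1e9, 2e9], inf, eff, FLOW)
        assert len(budgets) == 2  # day 0 start-up interval + one takedown pair
        assert budgets[0].stock_start == 0.0
        no_start = budget_series([10, 20], [1e9, 2e9], inf, eff, FLOW, start_day=None)
        assert len(no_start) == 1

    def test_constant_stock_zero_input_balanced(self):
        inf = TCCSeries("influent", [0.0], [1e5])
        eff = TCCSeries("effluent", [0.0], [1e5])
        budgets = budget_series([5, 15], [1e9, 1e9], inf, eff, FLOW, start_day=None)
        assert all(b.phase == "balanced" for b in budgets)

    def test_scale_equivariance(self):
        inf = TCCSeries("influent", [0.0, 8.0], [2e5, 3e5])
        eff = TCCSeries("effluent", [0.0], [5e4])
        k = 3.7
        base = budget_series([10, 30], [1e9, 4e9], inf, eff, FLOW)
        scaled = budget_series(
            [10, 30],
            [k * 1e9, k * 4e9],
            TCCSeries("influent", inf.days, k * inf.tcc),
            TCCSeries("effluent", eff.days, k * eff.tcc),
            FLOW,
        )
        for b0, b1 in zip(base, scaled):
            assert b1.delta_cells == pytest.approx(k * b0.delta_cells, rel=1e-12)
            assert b1.rate == pytest.approx(k * b0.rate, rel=1e-12)

    def test_matches_brute_force_daily_simulator(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = rng.integers(3, 9)
            days = np.sort(rng.choice(np.arange(0, 120), size=n, replace=False)).astype(float)
            days[0] = 0.0
            inf = TCCSeries("influent", days, rng.uniform(0, 3e6, n))
            eff = TCCSeries("effluent", days, rng.uniform(0, 1e6, n))
            takedowns = np.sort(rng.choice(np.arange(1, 120), size=4, replace=False))
            stocks = rng.uniform(1e9, 2e11, 4)
            budgets = budget_series(takedowns.tolist(), stocks.tolist(), inf, eff, FLOW)
            bounds = [0, *takedowns.tolist()]
            for b, (t0, t1) in zip(budgets, zip(bounds, bounds[1:])):
                oracle = brute_force_net_input(inf, eff, FLOW.q_ml_per_day, t0, t1)
                assert abs(b.net_input - oracle) <= 1e-6 * max(abs(oracle), 1.0)

    def test_recovers_scripted_phases_from_truth(self):
        exp = generate_experiment(SimConfig(seed=2))
        dens = depth_cell_density(exp.atp, exp.meta, exp.bed)
        takedowns = sorted(dens.index)
        stocks = [
            float(np.dot(np.asarray(exp.bed.mass_g), dens.loc[d].to_numpy()))
            for d in takedowns
        ]
        budgets = budget_series(
            takedowns, stocks, exp.tcc_influent, exp.tcc_effluent, exp.flow
        )
        truth_phases = [p["phase"] for p in exp.truth["phases"]]
        assert [b.phase for b in budgets] == truth_phases
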