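"""Cohort engine: trace invariants, reward accrual, and the microsimulation oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrcc_cea.markov import accrue_outcomes, discount_factors, run_cohort
from mrcc_cea.parameters import (
    CostSet,
    ModelSettings,
    ParameterError,
    StrategyParameters,
    TransitionProbabilities,
    UtilitySet,
)

from _oracle import microsimulate

ANLOTINIB_TP = TransitionProbabilities(0.039, 0.022, 0.050)
SUNITINIB_TP = TransitionProbabilities(0.041, 0.022, 0.049)

ZERO_COSTS = CostSet(drug=0, tests=0, outpatient=0, societal=0,
                     adverse_events=0, progressive_state=0)


def _strategy(transitions, utilities=None, costs=None, ae_rate=0.0, name="arm"):
    return StrategyParameters(
        name=name,
        transitions=transitions,
        utilities=utilities or UtilitySet(1.0, 1.0, 0.0),
        costs=costs or ZERO_COSTS,
        ae_rate=ae_rate,
    )


feasible_transitions = st.tuples(
    st.floats(0.0, 0.5), st.floats(0.0, 0.5), st.floats(0.0, 1.0)
).map(lambda t: TransitionProbabilities(*t))


class TestCohortTrace:
    @given(transitions=feasible_transitions)
    def test_trace_conservation_and_absorption(self, transitions):
        settings = ModelSettings(horizon_cycles=60)
        trace = run_cohort(transitions, settings)
        occ = trace.occupancy
        assert occ.shape == (61, 3)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert occ.min() >= -1e-15 and occ.max() <= 1.0 + 1e-12
        assert np.all(np.diff(trace.dead) >= -1e-15)  # death is absorbing
        np.testing.assert_array_equal(occ[0], [1.0, 0.0, 0.0])
        # total person-cycles equal the integral of the survival curve
        assert (trace.stable + trace.progressive).sum() == pytest.approx(
            (1.0 - trace.dead).sum()
        )

    def test_no_movement_leaves_everyone_stable(self):
        trace = run_cohort(TransitionProbabilities(0, 0, 0), ModelSettings(horizon_cycles=10))
        np.testing.assert_array_equal(trace.occupancy[:, 0], np.ones(11))

    def test_single_step_matches_hand_computation(self):
        trace = run_cohort(ANLOTINIB_TP, ModelSettings(horizon_cycles=1))
        np.testing.assert_allclose(trace.occupancy[1], [0.939, 0.039, 0.022], atol=1e-15)

    @pytest.mark.parametrize("transitions", [ANLOTINIB_TP, SUNITINIB_TP])
    def test_nearly_everyone_dead_at_ten_years(self, transitions):
        trace = run_cohort(transitions, ModelSettings())
        assert trace.dead[-1] >= 0.99

    def test_infeasible_transition_rows_rejected(self):
        with pytest.raises(ParameterError):
            TransitionProbabilities(0.6, 0.5, 0.1)

    def test_dataframe_export_includes_discount(self):
        settings = ModelSettings(horizon_cycles=5)
        frame = run_cohort(ANLOTINIB_TP, settings).to_dataframe(settings)
        assert list(frame.columns) == ["cycle", "stable", "progressive", "dead",
                                       "discount_factor"]
        assert frame["discount_factor"].iloc[0] == 1.0
        assert frame["discount_factor"].is_monotonic_decreasing


class TestAccrual:
    def test_full_health_no_death_no_cost(self):
        settings = ModelSettings(annual_discount=0.0)
        outcome = accrue_outcomes(_strategy(TransitionProbabilities(0, 0, 0)), settings)
        assert outcome.life_years == pytest.approx(10.0)
        assert outcome.qalys == pytest.approx(10.0)
        assert outcome.total_cost == 0.0

    def test_two_state_limit_matches_geometric_closed_form(self):
        # with no progression the model is a simple survival model
        p_sd = 0.0315
        settings = ModelSettings()
        outcome = accrue_outcomes(
            _strategy(TransitionProbabilities(0.0, p_sd, 0.0)), settings
        )
        v = 1.0 / (1.0 + settings.cycle_discount)
        q = (1.0 - p_sd) * v
        horizon = settings.horizon_cycles
        # begin-of-cycle counting: sum_{t=1..H} (1-p)^(t-1) v^t / 12
        closed_form = v * (1.0 - q**horizon) / (1.0 - q) / 12.0
        assert outcome.life_years == pytest.approx(closed_form, rel=1e-9)

    def test_undiscounted_life_years_equal_person_time(self):
        settings = ModelSettings(annual_discount=0.0)
        outcome = accrue_outcomes(_strategy(ANLOTINIB_TP), settings)
        trace = outcome.trace
        assert outcome.life_years == pytest.approx(
            (trace.stable[:-1] + trace.progressive[:-1]).sum() / 12.0
        )

    def test_discounting_strictly_reduces_outcomes(self):
        strategy = _strategy(ANLOTINIB_TP, costs=CostSet(100, 0, 0, 0, 0, 200))
        undiscounted = accrue_outcomes(strategy, ModelSettings(annual_discount=0.0))
        discounted = accrue_outcomes(strategy, ModelSettings(annual_discount=0.05))
        assert discounted.life_years < undiscounted.life_years
        assert discounted.qalys < undiscounted.qalys
        assert discounted.total_cost < undiscounted.total_cost

    @pytest.mark.parametrize("component", ["drug", "tests", "outpatient", "societal",
                                           "adverse_events", "progressive_state"])
    def test_total_cost_weakly_increasing_in_each_component(self, component):
        settings = ModelSettings()
        from dataclasses import replace

        base_costs = CostSet(100, 100, 100, 100, 100, 100)
        bumped = replace(base_costs, **{component: 150.0})
        low = accrue_outcomes(_strategy(ANLOTINIB_TP, costs=base_costs), settings)
        high = accrue_outcomes(_strategy(ANLOTINIB_TP, costs=bumped), settings)
        assert high.total_cost >= low.total_cost

    @pytest.mark.parametrize("field", ["stable_to_dead", "progressive_to_dead"])
    def test_more_death_means_fewer_life_years_and_qalys(self, field):
        settings = ModelSettings()
        utilities = UtilitySet(0.73, 0.66, 0.0)
        base = {"stable_to_progressive": 0.039, "stable_to_dead": 0.022,
                "progressive_to_dead": 0.050}
        bumped = {**base, field: base[field] + 0.02}
        low = accrue_outcomes(
            _strategy(TransitionProbabilities(**bumped), utilities), settings
        )
        high = accrue_outcomes(
            _strategy(TransitionProbabilities(**base), utilities), settings
        )
        assert low.life_years <= high.life_years
        assert low.qalys <= high.qalys

    def test_qalys_never_exceed_life_years(self):
        settings = ModelSettings()
        outcome = accrue_outcomes(
            _strategy(ANLOTINIB_TP, UtilitySet(0.73, 0.66, 0.157), ae_rate=0.289),
            settings,
        )
        assert outcome.qalys <= outcome.life_years

    def test_counting_conventions_are_ordered(self):
        # occupancy of the alive states shrinks over a cycle, so
        # begin-of-cycle counting credits the most person-time
        strategy = _strategy(ANLOTINIB_TP)
        results = {
            counting: accrue_outcomes(
                strategy, ModelSettings(state_counting=counting)
            ).life_years
            for counting in ("begin", "half", "end")
        }
        assert results["begin"] > results["half"] > results["end"]
        assert results["half"] == pytest.approx(
            0.5 * (results["begin"] + results["end"])
        )

    def test_ae_disutility_modes_all_reduce_qalys(self):
        utilities = UtilitySet(0.73, 0.66, 0.157)
        strategy = _strategy(ANLOTINIB_TP, utilities, ae_rate=0.289)
        no_ae = accrue_outcomes(
            _strategy(ANLOTINIB_TP, utilities, ae_rate=0.0), ModelSettings()
        )
        results = {}
        for mode in ("per_cycle", "one_time", "duration_limited"):
            results[mode] = accrue_outcomes(
                strategy, ModelSettings(ae_disutility_mode=mode)
            ).qalys
            assert results[mode] < no_ae.qalys
        # a lump of ae_rate*disutility whole QALYs is a far larger penalty
        # than one month's worth
        assert results["one_time"] < results["duration_limited"]

    def test_discount_factor_grid(self):
        settings = ModelSettings(horizon_cycles=3)
        d = discount_factors(settings)
        r = settings.cycle_discount
        np.testing.assert_allclose(d, [(1 + r) ** -1, (1 + r) ** -2, (1 + r) ** -3])


class TestMicrosimulationOracle:
    @pytest.mark.parametrize(
        ("transitions", "ae_rate", "costs"),
        [
            (ANLOTINIB_TP, 0.289, CostSet(864.76, 248.96, 6.32, 54.58, 23.76, 4535.08)),
            (SUNITINIB_TP, 0.558, CostSet(1830.48, 248.96, 6.32, 54.58, 265.44, 4535.08)),
        ],
    )
    def test_cohort_aggregates_match_individual_simulation(
        self, transitions, ae_rate, costs
    ):
        """100,000 simulated patients agree with the cohort expectation (3 SE)."""
        settings = ModelSettings()
        strategy = _strategy(
            transitions, UtilitySet(0.73, 0.66, 0.157), costs, ae_rate
        )
        cohort = accrue_outcomes(strategy, settings)
        micro = microsimulate(strategy, settings, n_patients=100_000, seed=20_240)
        for attr in ("life_years", "qalys", "total_cost"):
            mean, se = micro[attr]
            assert abs(getattr(cohort, attr) - mean) < 3.0 * se, attr

    def test_oracle_agreement_for_one_time_ae_mode(self):
        settings = ModelSettings(ae_disutility_mode="one_time")
        strategy = _strategy(
            ANLOTINIB_TP, UtilitySet(0.73, 0.66, 0.157),
            CostSet(864.76, 248.96, 6.32, 54.58, 23.76, 4535.08), 0.289
        )
        cohort = accrue_outcomes(strategy, settings)
        micro = microsimulate(strategy, settings, n_patients=50_000, seed=77)
        for attr in ("life_years", "qalys", "total_cost"):
            mean, se = micro[attr]
            assert abs(getattr(cohort, attr) - mean) < 3.0 * se, attr
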