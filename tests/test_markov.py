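"""Cohort engine: transition matrices, traces, payoffs and summaries."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfref_cea.markov import (
    ArmOutcome,
    build_transition_matrix,
    cumulative_incidence,
    hospitalization_rate_at_risk,
    run_arm,
    run_cohort,
    summarize,
)
from hfref_cea.parameters import (
    NOT_REACHED,
    AgeMortalityTable,
    InvalidParameterError,
    TransitionSet,
)


def with_transitions(params, p_sh, p_sc, p_hc, both_arms=True):
    ts = TransitionSet(p_sh, p_sc, p_hc)
    arms = ("empagliflozin", "standard") if both_arms else ("standard",)
    transitions = dict(params.transitions)
    for arm in arms:
        transitions[arm] = ts
    return dataclasses.replace(params, transitions=transitions)


class TestTransitionMatrix:
    def test_standard_stable_row_age67(self, base):
        # hand arithmetic: 1 - 0.02171 - 0.00657 - 0.00082 and 0.00657 + 0.00082
        m = build_transition_matrix(base, "standard", 67.0).matrix
        assert m[0] == pytest.approx([0.97090, 0.02171, 0.00739], abs=1e-12)

    def test_empagliflozin_hospitalized_row_age67(self, base):
        # hand arithmetic: 1 - 0.03865 - 0.00082 and 0.03865 + 0.00082
        m = build_transition_matrix(base, "empagliflozin", 67.0).matrix
        assert m[1] == pytest.approx([0.96053, 0.0, 0.03947], abs=1e-12)

    def test_death_row_absorbing(self, base):
        for arm in ("empagliflozin", "standard"):
            m = build_transition_matrix(base, arm, 80.0).matrix
            assert m[2].tolist() == [0.0, 0.0, 1.0]

    @pytest.mark.parametrize("age, p_ncv", [(67, 0.00082), (72, 0.00103), (83, 0.00291), (99, 0.00822)])
    def test_age_band_lookup_feeds_matrix(self, base, age, p_ncv):
        m = build_transition_matrix(base, "standard", age).matrix
        assert m[0, 2] == pytest.approx(0.00657 + p_ncv, abs=1e-12)

    def test_rows_stochastic(self, base):
        for age in np.arange(67, 87, 0.5):
            m = build_transition_matrix(base, "standard", age).matrix
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()

    def test_exit_probabilities_above_one_raise(self, base):
        bad = with_transitions(base, 0.7, 0.4, 0.1)
        with pytest.raises(InvalidParameterError):
            build_transition_matrix(bad, "standard", 67.0)

    def test_unknown_arm(self, base):
        with pytest.raises(InvalidParameterError):
            build_transition_matrix(base, "placebo", 67.0)

    def test_rate_scale_combination_close_to_additive(self, base):
        add = build_transition_matrix(base, "standard", 67.0).matrix
        rate = build_transition_matrix(base, "standard", 67.0, mortality_combination="rate").matrix
        assert np.allclose(add, rate, atol=1e-4)
        assert rate[0, 2] < add[0, 2]  # rate-scale combination is sub-additive


class TestCohortTrace:
    def test_conservation_and_monotone_death(self, base):
        for arm in ("empagliflozin", "standard"):
            trace = run_cohort(base, arm)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert (np.diff(trace.occupancy[:, 2]) >= -1e-15).all()
            assert trace.occupancy[0].tolist() == [1.0, 0.0, 0.0]

    def test_immortal_stable_cohort(self, flat_mortality_params):
        """No exits: occupancy pinned at (1,0,0); QALYs = 0.871 * 20 years."""
        params = with_transitions(flat_mortality_params, 0.0, 0.0, 0.0)
        trace = run_cohort(params, "standard")
        assert np.allclose(trace.occupancy[:, 0], 1.0, atol=1e-12)
        assert trace.qaly_undisc.sum() == pytest.approx(0.871 * 20, rel=1e-12)
        assert summarize(trace, params).median_survival_years == NOT_REACHED

    def test_cycle_one_dead_fraction(self, base):
        trace = run_cohort(base, "standard")
        assert trace.occupancy[1, 2] == pytest.approx(0.00739, abs=1e-12)

    def test_two_cycle_hand_enumeration(self, flat_mortality_params):
        """Totals match a fully hand-computed 2-cycle enumeration.

        Oracle (independent spreadsheet-style arithmetic, frozen):
        p_sh=0.1, p_sc=0.05, p_hc=0.2, p_ncv=0.01, monthly cost 100,
        admission cost 1000, utilities 0.8/0.3, discount 5%/year.
        """
        p = flat_mortality_params
        p = dataclasses.replace(
            p, age_mortality=AgeMortalityTable(bands=((0.0, 200.0, 0.01),))
        )
        p = with_transitions(p, 0.1, 0.05, 0.2)
        costs = dict(p.costs)
        costs["standard"] = dataclasses.replace(
            costs["standard"], c_monthly_treatment=100.0, c_hospitalization=1000.0
        )
        p = dataclasses.replace(
            p,
            costs=costs,
            utilities=dataclasses.replace(p.utilities, u_stable=0.8, u_hosp=0.3),
            econ=dataclasses.replace(p.econ, n_cycles=2),
        )
        trace = run_cohort(p, "standard")
        assert trace.occupancy[1] == pytest.approx([0.84, 0.1, 0.06], abs=1e-12)
        assert trace.occupancy[2] == pytest.approx([0.7846, 0.084, 0.1314], abs=1e-12)
        assert trace.cost_disc.sum() == pytest.approx(369.96934970742245, abs=1e-12)
        assert trace.qaly_disc.sum() == pytest.approx(0.11856632060577141, abs=1e-14)

    def test_discount_free_limit(self, base):
        p = dataclasses.replace(
            base, econ=dataclasses.replace(base.econ, discount_rate_annual=0.0)
        )
        trace = run_cohort(p, "empagliflozin")
        assert np.array_equal(trace.cost_disc, trace.cost_undisc)
        assert np.array_equal(trace.qaly_disc, trace.qaly_undisc)

    def test_discounted_below_undiscounted(self, base):
        for arm in ("empagliflozin", "standard"):
            out = run_arm(base, arm)
            assert out.total_cost < out.total_cost_undiscounted
            assert out.total_qalys < out.total_qalys_undiscounted

    @given(
        p_sh=st.floats(0.0, 0.2),
        p_sc=st.floats(0.0, 0.2),
        p_hc=st.floats(0.0, 0.5),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_under_random_transitions(self, base, p_sh, p_sc, p_hc):
        params = with_transitions(base, p_sh, p_sc, p_hc)
        trace = run_cohort(params, "standard")
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert (np.diff(trace.occupancy[:, 2]) >= -1e-15).all()

    def test_lower_admission_probability_dominates(self, base):
        """Fewer admissions never means fewer QALYs or more hospitalizations."""
        ts = base.transitions["standard"]
        lowered = with_transitions(
            base, ts.p_stable_to_hosp * 0.5, ts.p_stable_to_cvdeath, ts.p_hosp_to_cvdeath,
            both_arms=False,
        )
        out_base = run_arm(base, "standard")
        out_low = run_arm(lowered, "standard")
        assert out_low.total_qalys >= out_base.total_qalys
        assert cumulative_incidence(out_low.trace, "hospitalization", 240) <= (
            cumulative_incidence(out_base.trace, "hospitalization", 240)
        )

    def test_trace_export_columns(self, base):
        frame = run_cohort(base, "standard").to_frame()
        assert list(frame.columns) == [
            "cycle", "state", "occupancy",
            "cost_undiscounted", "cost_discounted",
            "qaly_undiscounted", "qaly_discounted", "hosp_entries",
        ]
        assert len(frame) == 3 * 241


class TestSummaries:
    def test_median_survival_geometric_oracle(self, flat_mortality_params):
        """Constant monthly death probability p: median = ln 2 / -ln(1-p) months."""
        p_death = 0.02
        params = with_transitions(flat_mortality_params, 0.0, p_death, 0.0)
        out = run_arm(params, "standard")
        expected_months = math.log(2) / -math.log(1 - p_death)
        # linear interpolation of a geometric curve: agree to within half a cycle
        assert out.median_survival_years * 12 == pytest.approx(expected_months, abs=0.5)

    def test_median_survival_within_horizon(self, base):
        for arm in ("empagliflozin", "standard"):
            out = run_arm(base, arm)
            assert 0 < out.median_survival_years <= base.econ.n_cycles / 12

    def test_incidence_zero_at_cycle_zero(self, base):
        trace = run_cohort(base, "standard")
        for event in ("all_cause_death", "cv_death", "hospitalization"):
            assert cumulative_incidence(trace, event, 0) == 0.0

    def test_incidence_monotone(self, base):
        trace = run_cohort(base, "empagliflozin")
        for event in ("all_cause_death", "cv_death", "hospitalization", "first_hospitalization"):
            vals = [cumulative_incidence(trace, event, k) for k in range(0, 241, 12)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_unknown_event(self, base):
        trace = run_cohort(base, "standard")
        with pytest.raises(ValueError):
            cumulative_incidence(trace, "stroke", 16)

    def test_first_event_below_recurrent(self, base):
        trace = run_cohort(base, "standard")
        assert cumulative_incidence(trace, "first_hospitalization", 240) < (
            cumulative_incidence(trace, "hospitalization", 240)
        )

    def test_at_risk_rate_equals_monthly_probability_times_months(self, base):
        """With a constant admission hazard the at-risk event rate over m
        months is exactly m times the monthly probability."""
        trace = run_cohort(base, "standard")
        assert hospitalization_rate_at_risk(trace, 16) == pytest.approx(
            16 * 0.02171 * 100, rel=1e-12
        )

    def test_totals_match_trace_sums(self, base):
        out = run_arm(base, "empagliflozin")
        assert out.total_cost == pytest.approx(out.trace.cost_disc.sum(), abs=1e-9)
        assert out.total_qalys == pytest.approx(out.trace.qaly_disc.sum(), abs=1e-9)
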