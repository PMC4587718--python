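"""Markov engine: transition construction, stepping, accrual, and the
brute-force path-enumeration oracle."""

import numpy as np
import pytest

from afcea import (
    HealthState,
    build_transition_model,
    derive_therapy_rates,
    discount_factor,
    run_cohort,
    step_cohort,
)
from afcea.cohort_model import N_EVENTS, N_STATES, EventType

S = HealthState


def model_for(params, conversion=0.0):
    return build_transition_model(derive_therapy_rates(params), conversion, params)


def unit_vector(state, persons=1.0):
    v = np.zeros(N_STATES)
    v[state] = persons
    return v


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,cycle,expected",
        [(0.03, 0, 1.0), (0.0, 4, 1.0), (0.03, 1, 1 / 1.03)],
    )
    def test_values(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-12)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.03, -1)


class TestTransitionModel:
    def test_rows_stochastic_and_dead_absorbing(self, base_params):
        m = model_for(base_params, conversion=0.025)
        P = m.transition_matrix
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()
        assert P[S.DEAD, S.DEAD] == 1.0

    def test_null_dynamics_is_identity(self, quiet_params):
        m = model_for(quiet_params)
        # post-bleed recovery still routes POST_BLEED -> WELL_ASPIRIN
        expected = np.eye(N_STATES)
        expected[S.POST_BLEED, S.POST_BLEED] = 0
        expected[S.POST_BLEED, S.WELL_ASPIRIN] = 1
        np.testing.assert_allclose(m.transition_matrix, expected)

    def test_well_aspirin_death_probability(self, base_params):
        # fatal stroke + fatal ICH + fatal extracranial bleed, aspirin rates
        m = model_for(base_params)
        expected = 0.045 * 0.179 + 0.01475 * (0.2 * 0.364 + 0.8 * 0.049)
        assert m.transition_matrix[S.WELL_ASPIRIN, S.DEAD] == pytest.approx(
            expected, abs=1e-12
        )

    def test_conversion_applies_to_event_free_remainder(self, base_params):
        m = model_for(base_params, conversion=0.025)
        expected = (1 - 0.045 - 0.01475) * 0.025
        assert m.event_prob[S.WELL_ASPIRIN, EventType.CONVERT] == pytest.approx(
            expected, abs=1e-12
        )
        assert m.transition_matrix[S.WELL_ASPIRIN, S.WELL_WARFARIN] == pytest.approx(
            expected, abs=1e-12
        )

    def test_infeasible_event_probabilities_rejected(self, base_params):
        bad = base_params.replace(
            p_stroke_aspirin=0.7, p_bleed_warfarin=0.6, ranges={}
        )
        with pytest.raises(ValueError, match="exceeds 1"):
            model_for(bad)

    def test_bleed_discontinues_warfarin(self, base_params):
        m = model_for(base_params)
        assert m.event_dest[S.WELL_WARFARIN, EventType.BLEED_NONFATAL] == S.POST_BLEED
        assert (
            m.event_dest[S.POST_STROKE_WARFARIN, EventType.BLEED_NONFATAL]
            == S.POST_STROKE_ASPIRIN
        )
        assert m.stay_dest[S.POST_BLEED] == S.WELL_ASPIRIN


class TestStepCohort:
    def test_dead_cohort_unchanged(self, base_params):
        m = model_for(base_params)
        nxt, ev = step_cohort(unit_vector(S.DEAD, 1000), m)
        np.testing.assert_allclose(nxt, unit_vector(S.DEAD, 1000))
        assert ev.sum() == 0

    def test_expected_strokes_from_well_aspirin(self, base_params):
        m = model_for(base_params)
        _, ev = step_cohort(unit_vector(S.WELL_ASPIRIN, 1000), m)
        strokes = ev[EventType.STROKE_FATAL] + ev[EventType.STROKE_NONFATAL]
        assert strokes == pytest.approx(45.0)

    def test_mass_conserved(self, base_params):
        m = model_for(base_params, conversion=0.025)
        state = np.array([400.0, 100.0, 50.0, 25.0, 10.0, 5.0, 5.0, 405.0])
        nxt, _ = step_cohort(state, m)
        assert nxt.sum() == pytest.approx(state.sum(), abs=1e-9)

    def test_dimension_mismatch_rejected(self, base_params):
        with pytest.raises(ValueError):
            step_cohort(np.zeros(3), model_for(base_params))


class TestRunCohort:
    def test_closed_form_no_dynamics(self, quiet_params):
        m = model_for(quiet_params)
        trace = run_cohort(unit_vector(S.WELL_ASPIRIN, 1000), m, quiet_params)
        assert trace.total_qalys == pytest.approx(1000 * 5 * 0.998)
        assert trace.total_cost == pytest.approx(1000 * 5 * 10.0)

    def test_geometric_discounting(self, quiet_params):
        p = quiet_params.replace(
            discount_rate=0.03,
            switches=quiet_params.switches.model_copy(update={"discount_from": 0}),
        )
        m = model_for(p)
        trace = run_cohort(unit_vector(S.WELL_ASPIRIN, 1000), m, p)
        expected = 998.0 * sum(1.03 ** -t for t in range(5))
        assert trace.total_qalys == pytest.approx(expected, abs=1e-6)

    def test_conservation_every_cycle(self, base_params):
        m = model_for(base_params, conversion=0.025)
        trace = run_cohort(unit_vector(S.WELL_ASPIRIN, 1000), m, base_params)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1000.0, atol=1e-9)

    def test_linearity_superposition(self, base_params):
        m = model_for(base_params, conversion=0.025)
        a = unit_vector(S.WELL_ASPIRIN, 700)
        b = unit_vector(S.WELL_WARFARIN, 300)
        t_ab = run_cohort(a + b, m, base_params)
        t_a = run_cohort(a, m, base_params)
        t_b = run_cohort(b, m, base_params)
        assert t_ab.total_cost == pytest.approx(t_a.total_cost + t_b.total_cost,
                                                abs=1e-6)
        assert t_ab.total_qalys == pytest.approx(t_a.total_qalys + t_b.total_qalys,
                                                 abs=1e-9)
        np.testing.assert_allclose(
            t_ab.total_events, t_a.total_events + t_b.total_events, atol=1e-9
        )

    @pytest.mark.parametrize("bump", [0.005, 0.01, 0.015])
    def test_monotone_harm_in_stroke_rate(self, base_params, bump):
        lo = base_params.replace(ranges={})
        hi = base_params.replace(p_stroke_aspirin=0.045 + bump, ranges={})
        def strokes(p):
            tr = run_cohort(unit_vector(S.WELL_ASPIRIN, 1000), model_for(p), p)
            return (
                tr.event_total(EventType.STROKE_FATAL)
                + tr.event_total(EventType.STROKE_NONFATAL)
            )
        assert strokes(hi) > strokes(lo)

    def test_cumulative_tallies_non_decreasing(self, base_params):
        m = model_for(base_params, conversion=0.025)
        trace = run_cohort(unit_vector(S.WELL_ASPIRIN, 1000), m, base_params)
        per_cycle = trace.events.sum(axis=(1, 2))
        assert (per_cycle >= 0).all()
        cum = np.cumsum(per_cycle)
        assert (np.diff(cum) >= 0).all()


def enumerate_paths(state, model, params):
    """Independent oracle: exhaustive recursion over every event path of one
    person, accumulating discounted cost and QALYs per path probability."""
    sw = params.switches
    w = {"start": 0.0, "mid": 0.5, "end": 1.0}[sw.followup_accrual]

    def rec(s, t):
        if t == params.horizon_cycles:
            return 0.0, 0.0
        df = (1 + params.discount_rate) ** -(t + sw.discount_from)
        stay_p = 1.0 - model.event_prob[s].sum()
        options = [
            (model.event_prob[s, e], int(model.event_dest[s, e]),
             model.event_cost[s, e])
            for e in range(N_EVENTS)
            if model.event_prob[s, e] > 0
        ]
        options.append((stay_p, int(model.stay_dest[s]), 0.0))
        cost = qalys = 0.0
        for prob, nxt, one_time in options:
            if prob == 0:
                continue
            c_now = (
                model.drug_cost[s]
                + one_time
                + (1 - w) * model.monthly_cost[s]
                + w * model.monthly_cost[nxt]
            )
            c_rest, q_rest = rec(nxt, t + 1)
            cost += prob * (df * c_now + c_rest)
            qalys += prob * (df * model.utility[nxt] + q_rest)
        return cost, qalys

    return rec(int(state), 0)


@pytest.mark.parametrize("horizon", [1, 2, 3])
@pytest.mark.parametrize(
    "start", [S.WELL_ASPIRIN, S.WELL_WARFARIN, S.POST_STROKE_WARFARIN]
)
def test_engine_matches_path_enumeration(base_params, horizon, start):
    """For one person and short horizons the engine's expected cost and
    QALYs equal exhaustive enumeration over all event paths."""
    p = base_params.replace(horizon_cycles=horizon)
    m = model_for(p, conversion=0.025)
    trace = run_cohort(unit_vector(start, 1.0), m, p)
    cost, qalys = enumerate_paths(start, m, p)
    assert trace.total_cost == pytest.approx(cost, abs=1e-9)
    assert trace.total_qalys == pytest.approx(qalys, abs=1e-9)
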