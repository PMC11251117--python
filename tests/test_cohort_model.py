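"""Cohort engine: state space, transition assembly, propagation, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afcem import cohort_model as cm
from afcem.params import ParameterSet, ValidationError
from conftest import make_degenerate


class TestStateSpace:
    def test_fourteen_states(self):
        assert cm.N_STATES == 14
        assert len(cm.STATE_LABELS) == 14

    def test_cryo_cap_excludes_count_three(self):
        assert cm.max_substate("cryo", 3) == 2
        assert cm.max_substate("aad", 3) == 3
        assert cm.StateSpace("cryo", 3).forbidden == [3, 7, 11]
        assert cm.StateSpace("aad", 3).forbidden == []

    def test_state_index_round_trip(self):
        assert cm.state_index("NSR", 0) == 0
        assert cm.state_index("ST_EPISODIC", 2) == 6
        assert cm.state_index("PERMANENT") == 12
        assert cm.health_of(9) == "LT_PERSISTENT"
        with pytest.raises(ValidationError):
            cm.state_index("NSR", 5)


class TestTransitionMatrix:
    def test_identity_under_degenerate_inputs(self, base_params):
        p = make_degenerate(base_params)
        M = cm.build_transition_matrix(p, "cryo", 10)
        assert np.allclose(M, np.eye(cm.N_STATES))

    def test_rows_sum_to_one_every_cycle_both_arms(self, base_params):
        for arm in ("cryo", "aad"):
            for t in range(base_params.settings.n_cycles):
                M = cm.build_transition_matrix(base_params, arm, t)
                assert np.max(np.abs(M.sum(axis=1) - 1.0)) < 1e-10

    def test_no_reablation_from_capped_substate(self, base_params):
        M = cm.build_transition_matrix(base_params, "cryo", 20)
        i = cm.state_index("ST_EPISODIC", 2)  # at the cryo cap
        assert M[i, cm.state_index("NSR", 3)] == 0.0
        assert M[i, cm.state_index("ST_EPISODIC", 3)] == 0.0
        j = cm.state_index("ST_EPISODIC", 1)  # below the cap
        assert M[j, cm.state_index("NSR", 2)] > 0.0

    def test_death_row_absorbing_and_count_never_decreases(self, base_params):
        M = cm.build_transition_matrix(base_params, "aad", 30)
        assert M[cm.DEATH, cm.DEATH] == 1.0
        for k in range(1, 4):
            for base in (cm.NSR0, cm.ST0, cm.LT0):
                for k2 in range(k):
                    for base2 in (cm.NSR0, cm.ST0, cm.LT0):
                        assert M[base + k, base2 + k2] == 0.0

    def test_permanent_admits_no_return(self, base_params):
        M = cm.build_transition_matrix(base_params, "aad", 30)
        row = M[cm.PERM].copy()
        row[cm.PERM] = row[cm.DEATH] = 0.0
        assert np.all(row == 0.0)


class TestDecisionTree:
    def test_explicit_allocation_pass_through(self, base_params):
        d = base_params.to_dict()
        alloc = {"NSR:0": 0.7, "NSR:1": 0.05, "ST_EPISODIC:0": 0.2,
                 "ST_EPISODIC:1": 0.03, "DEATH": 0.02}
        d["clinical"]["per_arm"]["cryo"]["year1_allocation"] = alloc
        p = ParameterSet.from_dict(d)
        vec, _ = cm.run_decision_tree(p, "cryo")
        assert vec.sum() == pytest.approx(1.0)
        assert vec[cm.state_index("NSR", 0)] == 0.7
        assert vec[cm.DEATH] == 0.02

    def test_allocation_must_sum_to_one(self, base_params):
        d = base_params.to_dict()
        d["clinical"]["per_arm"]["cryo"]["year1_allocation"] = {"NSR:0": 0.5}
        p = ParameterSet.from_dict(d)
        with pytest.raises(ValidationError, match="allocation"):
            cm.run_decision_tree(p, "cryo")

    def test_zero_mortality_gives_zero_death_mass(self, base_params):
        p = make_degenerate(base_params)
        vec, _ = cm.run_decision_tree(p, "cryo")
        assert vec[cm.DEATH] == 0.0

    def test_year_one_reablation_expectations(self, base_params):
        """Calibrated tree tallies ~0.07 (cryo) and ~0.25 (drug arm) re-ablations."""
        _, ev_cryo = cm.run_decision_tree(base_params, "cryo")
        _, ev_aad = cm.run_decision_tree(base_params, "aad")
        assert ev_cryo["reablations"].sum() == pytest.approx(0.07, rel=0.25)
        assert ev_aad["reablations"].sum() == pytest.approx(0.25, rel=0.25)


class TestMarkov:
    def test_initial_vector_must_sum_to_one(self, base_params):
        bad = np.zeros(cm.N_STATES)
        bad[0] = 0.5
        with pytest.raises(ValidationError):
            cm.run_markov(bad, base_params, "cryo")

    def test_constant_trace_under_identity_dynamics(self, base_params):
        p = make_degenerate(base_params, horizon_years=5)
        trace = cm.run_arm(p, "cryo")
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_death_only_dynamics_closed_form(self, base_params):
        g = 0.08  # annual rate; engine converts to a per-cycle probability
        p = make_degenerate(base_params, mortality_rate=g, horizon_years=10)
        q = 1 - np.exp(-g / 4)
        trace = cm.run_arm(p, "cryo")
        t = np.arange(trace.n_cycles + 1)
        assert np.allclose(trace.occupancy[:, cm.DEATH], 1 - (1 - q) ** t, atol=1e-12)

    def test_three_state_reduction_matches_matrix_power_oracle(self, base_params):
        """With age-constant inputs the engine equals v0 @ M^t to 1e-12."""
        p = make_degenerate(base_params, mortality_rate=0.02, horizon_years=10)
        d = p.to_dict()
        arm = d["clinical"]["per_arm"]["cryo"]
        arm["recurrence"] = 0.05
        arm["resolution"] = 0.15
        arm["year1"]["recurrence"] = 0.05
        arm["year1"]["resolution"] = 0.15
        p = ParameterSet.from_dict(d)
        M = cm.build_transition_matrix(p, "cryo", 0)
        # constant dynamics: every cycle's matrix must be identical
        assert np.array_equal(M, cm.build_transition_matrix(p, "cryo", 25))
        trace = cm.run_arm(p, "cryo")
        v = cm.initial_occupancy()
        for t in range(trace.n_cycles + 1):
            assert np.allclose(trace.occupancy[t], v, atol=1e-12)
            v = v @ M

    def test_cryo_trace_has_zero_mass_in_count_three(self, det_results, base_params):
        trace = cm.run_arm(base_params, "cryo")
        assert np.max(np.abs(trace.occupancy[:, [3, 7, 11]])) == 0.0

    def test_death_monotone_in_base_case(self, base_params):
        for arm in ("cryo", "aad"):
            trace = cm.run_arm(base_params, arm)
            death = trace.occupancy[:, cm.DEATH]
            assert np.all(np.diff(death) >= -1e-15)


class TestOccupancyYears:
    def test_full_occupancy_undiscounted(self, base_params):
        p = make_degenerate(base_params)
        trace = cm.run_arm(p, "cryo")  # sits in ST-episodic for 40 years
        years = cm.state_occupancy_years(trace)
        assert years["ST_EPISODIC"] == pytest.approx(40.0)
        assert years["NSR"] == 0.0

    def test_discounted_geometric_closed_form(self, base_params):
        p = make_degenerate(base_params)
        trace = cm.run_arm(p, "cryo")
        got = cm.state_occupancy_years(trace, discounted=True, rate=0.03)
        expect = 0.25 * sum(1.03 ** (-0.25 * t) for t in range(160))
        assert got["ST_EPISODIC"] == pytest.approx(expect, rel=1e-12)


@st.composite
def random_clinical(draw):
    def p(hi=0.3):
        return draw(st.floats(0.0, hi, allow_nan=False))
    return dict(
        recurrence=p(), resolution=p(0.4), progression_st_lt=p(0.2),
        progression_lt_perm=p(0.2), reablation_uptake_st=p(0.2),
        reablation_uptake_lt=p(0.2),
        reablation_success=draw(st.floats(0.0, 1.0)),
    )


class TestConservationProperty:
    @given(cryo=random_clinical(), aad=random_clinical(),
           mortality=st.floats(0.0, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_rows_conserve_mass_for_arbitrary_valid_inputs(
        self, cryo, aad, mortality
    ):
        base = make_degenerate(_BASE, mortality_rate=mortality, horizon_years=10)
        d = base.to_dict()
        for arm, block in (("cryo", cryo), ("aad", aad)):
            d["clinical"]["per_arm"][arm].update(block)
            y1 = d["clinical"]["per_arm"][arm]["year1"]
            y1["recurrence"] = block["recurrence"]
            y1["resolution"] = block["resolution"]
            y1["reablation_uptake"] = block["reablation_uptake_st"]
        p = ParameterSet.from_dict(d)
        for arm in ("cryo", "aad"):
            trace = cm.run_arm(p, arm)
            sums = trace.occupancy.sum(axis=1)
            assert np.max(np.abs(sums - 1.0)) < 1e-9
            assert np.all(np.diff(trace.occupancy[:, cm.DEATH]) >= -1e-15)

    @given(cryo=random_clinical())
    @settings(max_examples=10, deadline=None)
    def test_substate_mass_monotone_without_mortality_or_permanence(self, cryo):
        """Mass at ablation count >= k never decreases when no mass exits via
        death or the (count-less) permanent state."""
        base = make_degenerate(_BASE, horizon_years=10)
        d = base.to_dict()
        cryo = dict(cryo, progression_lt_perm=0.0)
        d["clinical"]["per_arm"]["cryo"].update(cryo)
        p = ParameterSet.from_dict(d)
        trace = cm.run_arm(p, "cryo")
        for k in (1, 2):
            idx = [b + j for b in (cm.NSR0, cm.ST0, cm.LT0) for j in range(k, 4)]
            mass = trace.occupancy[:, idx].sum(axis=1)
            assert np.all(np.diff(mass) >= -1e-12)


_BASE = None


@pytest.fixture(autouse=True, scope="module")
def _stash_base(base_params):
    global _BASE
    _BASE = base_params
    yield
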