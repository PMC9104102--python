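"""BLS rule engine: sequencing, CPR budgets, iCPR timetable, hypothermia staging."""

import itertools
import math

import pytest

from avarescue import (
    UNLIMITED,
    InjuryAssessment,
    PatientState,
    assumed_cooling_gradient,
    bls_sequence,
    cpr_budget,
    hypothermia_stage,
    icpr_plan,
    max_defibrillations,
)
from avarescue.protocol import decision_trace


def patient(**overrides):
    base = dict(avpu="U", breathing_normal=False, vital_signs_present=False,
                burial_duration_min=30)
    base.update(overrides)
    return PatientState(**base)


def enumerate_valid_states():
    """Exhaustive grid over the discrete patient-state space (valid states only)."""
    states = []
    for (avpu, breathing, agonal, vitals, airway, pocket,
         shortage, duration, injured) in itertools.product(
        "AVPU",
        (True, False),
        (True, False),
        (True, False),
        ("clear", "partially_obstructed", "fully_obstructed", "unknown"),
        ("present", "absent", "unknown"),
        (True, False),
        (30.0, 90.0),
        (True, False),
    ):
        try:
            states.append(
                PatientState(
                    avpu=avpu,
                    breathing_normal=breathing,
                    agonal_breathing=agonal,
                    vital_signs_present=vitals,
                    burial_duration_min=duration,
                    airway_status=airway,
                    air_pocket=pocket,
                    shortage=shortage,
                    injuries=InjuryAssessment(high_fall=injured),
                )
            )
        except ValueError:
            continue
    return states


class TestStateValidation:
    def test_alert_requires_vital_signs(self):
        with pytest.raises(ValueError):
            patient(avpu="A", vital_signs_present=False)

    def test_contradictory_breathing_flags_rejected(self):
        with pytest.raises(ValueError):
            patient(breathing_normal=True, agonal_breathing=True,
                    vital_signs_present=True)

    def test_normal_breathing_implies_vital_signs(self):
        with pytest.raises(ValueError):
            patient(breathing_normal=True, vital_signs_present=False)

    def test_unknown_enum_values_rejected(self):
        with pytest.raises(ValueError):
            patient(avpu="X")
        with pytest.raises(ValueError):
            patient(airway_status="blocked")


class TestBlsSequence:
    def test_rescue_breaths_precede_cpr_for_arrested_patient(self):
        d = bls_sequence(patient())
        assert "rescue_breaths_5" in d.actions and "cpr_30_2" in d.actions
        assert d.actions.index("rescue_breaths_5") < d.actions.index("cpr_30_2")

    def test_agonal_breathing_is_not_a_sign_of_life(self):
        d = bls_sequence(patient(agonal_breathing=True))
        assert "cpr_30_2" in d.actions

    def test_vitals_after_breaths_route_to_wilderness_first_aid(self):
        d = bls_sequence(patient(avpu="P", vital_signs_present=True))
        assert "wilderness_first_aid" in d.actions
        assert "cpr_30_2" not in d.actions

    def test_conscious_uninjured_under_shortage_postponed_before_treatment(self):
        d = bls_sequence(patient(avpu="A", breathing_normal=True,
                                 vital_signs_present=True, shortage=True))
        assert d.disposition in ("postpone", "enlist")
        assert "cpr_30_2" not in d.actions and "rescue_breaths_5" not in d.actions

    def test_clear_answers_make_conscious_subject_enlistable(self):
        d = bls_sequence(patient(avpu="A", breathing_normal=True,
                                 vital_signs_present=True, shortage=True,
                                 clear_answers=True))
        assert d.disposition == "enlist"

    def test_incompatible_injuries_withhold_treatment(self):
        d = bls_sequence(patient(injuries=InjuryAssessment(high_fall=True)))
        assert d.disposition == "withhold"

    def test_unsalvageable_prolonged_burial_obstructed_airway_no_pocket(self):
        d = bls_sequence(patient(burial_duration_min=90,
                                 airway_status="fully_obstructed",
                                 air_pocket="absent"))
        assert d.disposition == "withhold"
        assert "cpr_30_2" not in d.actions

    def test_airway_cleared_first_when_not_clear(self):
        d = bls_sequence(patient(airway_status="partially_obstructed"))
        assert d.actions[0] == "clear_airway"
        d = bls_sequence(patient(airway_status="clear"))
        assert "clear_airway" not in d.actions

    def test_breaths_before_cpr_on_exhaustive_state_space(self):
        """Whenever a plan contains CPR and breathing was not normal, the five
        rescue breaths come strictly first; every state yields one disposition."""
        states = enumerate_valid_states()
        assert len(states) > 500
        for p in states:
            d = bls_sequence(p)
            assert d.disposition in ("treat", "postpone", "enlist", "withhold")
            if "cpr_30_2" in d.actions and not p.breathing_normal:
                assert "rescue_breaths_5" in d.actions
                assert d.actions.index("rescue_breaths_5") < d.actions.index("cpr_30_2")
            if d.cpr_budget_min == 6.0:
                assert p.shortage and p.normothermic

    def test_icpr_plan_attached_only_beyond_normothermic_boundary(self):
        assert bls_sequence(patient(burial_duration_min=90)).icpr is not None
        assert bls_sequence(patient(burial_duration_min=30)).icpr is None


class TestCprBudget:
    def test_normothermic_shortage_six_minutes(self):
        assert cpr_budget(patient(burial_duration_min=40, shortage=True)) == 6.0

    def test_normothermic_without_shortage_unlimited(self):
        assert cpr_budget(patient(burial_duration_min=40, shortage=False)) == UNLIMITED

    def test_prolonged_burial_unknown_airway_unlimited(self):
        assert cpr_budget(patient(burial_duration_min=90,
                                  airway_status="unknown")) == UNLIMITED

    def test_prolonged_burial_fully_obstructed_no_pocket_zero(self):
        assert cpr_budget(patient(burial_duration_min=90,
                                  airway_status="fully_obstructed",
                                  air_pocket="absent")) == 0.0

    def test_never_six_minutes_without_shortage(self):
        for p in enumerate_valid_states():
            if not p.shortage:
                assert cpr_budget(p) != 6.0


class TestDefibrillation:
    def test_potentially_hypothermic_capped_at_three(self):
        assert max_defibrillations(patient(burial_duration_min=90)) == 3

    def test_normothermic_standard_aed_guidance(self):
        assert max_defibrillations(patient(burial_duration_min=30)) == UNLIMITED

    def test_countdown_after_delivered_shocks(self):
        p = patient(burial_duration_min=90)
        assert max_defibrillations(p, shocks_delivered=3) == 0
        assert max_defibrillations(p, shocks_delivered=2) == 1


class TestHypothermiaStaging:
    def test_alert_stage_one_moves_actively(self):
        a = hypothermia_stage("A", True)
        assert a.stage == 1
        assert "move_actively" in a.actions and "warm_sugary_drink" in a.actions

    def test_voice_stage_two_drink_conditional(self):
        a = hypothermia_stage("V", True)
        assert a.stage == 2 and a.drink_conditional
        assert "insulate" in a.actions and "heat_packs" in a.actions

    def test_pain_stage_three_no_drink(self):
        a = hypothermia_stage("P", True)
        assert a.stage == 3
        assert "warm_sugary_drink" not in a.actions

    def test_unresponsive_without_vitals_stage_four_cpr(self):
        a = hypothermia_stage("U", False)
        assert a.stage == 4
        assert "cpr_30_2" in a.actions

    def test_unresponsive_with_vitals_flagged_conservative(self):
        a = hypothermia_stage("U", True)
        assert a.stage == 3
        assert a.warning is not None


class TestCoolingAndICPR:
    def test_cooling_gradient_examples(self):
        assert assumed_cooling_gradient(1.0) == pytest.approx(7.0)
        assert assumed_cooling_gradient(2.0) == pytest.approx(3.5)

    def test_gradient_decreases_with_duration(self):
        hours = [0.5, 1, 2, 4, 8]
        grads = [assumed_cooling_gradient(h) for h in hours]
        assert all(a > b for a, b in zip(grads, grads[1:]))

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            assumed_cooling_gradient(0.0)

    def test_boundary_burial_first_interruption_at_25_minutes(self):
        plan = icpr_plan(60)
        assert plan.pre_phase_min == pytest.approx(20.0)
        assert plan.first_interruption_at_min == pytest.approx(25.0)

    def test_ninety_minute_burial_timetable(self):
        plan = icpr_plan(90)
        assert plan.pre_phase_min == pytest.approx(30.0)
        assert plan.first_interruption_at_min == pytest.approx(35.0)

    def test_exact_cooling_time_uses_three_point_five_divisor(self):
        assert icpr_plan(70).exact_cooling_time_min == pytest.approx(20.0)

    def test_normothermic_burial_not_eligible(self):
        with pytest.raises(ValueError):
            icpr_plan(45)

    def test_safety_margin_always_positive(self):
        for duration in range(60, 600, 7):
            plan = icpr_plan(duration)
            assert plan.pre_phase_min > plan.exact_cooling_time_min


class TestDecisionTrace:
    def test_one_row_per_action_with_monotone_timestamps(self):
        d = bls_sequence(patient(shortage=True))
        rows = decision_trace(d)
        assert [r["action"] for r in rows] == list(d.actions)
        starts = [r["starts_at_min"] for r in rows]
        assert starts == sorted(starts)

    def test_cpr_row_duration_is_budget_when_finite(self):
        d = bls_sequence(patient(shortage=True, burial_duration_min=40))
        rows = {r["action"]: r for r in decision_trace(d)}
        assert rows["cpr_30_2"]["nominal_duration_min"] == 6.0
        d = bls_sequence(patient(shortage=False, burial_duration_min=40))
        rows = {r["action"]: r for r in decision_trace(d)}
        assert rows["cpr_30_2"]["nominal_duration_min"] is None
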