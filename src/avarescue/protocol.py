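"""BLS treatment rule engine: sequencing, CPR budgeting, iCPR, hypothermia staging.

The avalanche patient differs from the generic cardiac-arrest patient in one
decisive way: the dominant pathology is asphyxia, so rescue breaths come
before everything else ("no rescue breaths -> no oxygen -> no return of
spontaneous circulation -> no survival"). The engine below maps a
BLS-observable patient state to an ordered action plan plus three numeric
policies:

* a CPR time budget — 6 minutes (three 2-minute windows) for normothermic
  patients when resources are short, unlimited otherwise, zero for the
  unsalvageable combination of prolonged burial, fully obstructed airway and
  no air pocket;
* a defibrillation cap — three shocks for potentially hypothermic patients
  (burial beyond 60 min), standard unlimited AED guidance otherwise;
* an intermittent-CPR (iCPR) timetable for potentially hypothermic arrest:
  uninterrupted CPR for one third of the burial duration before cycling
  5 min on / at most 5 min off.

Normothermia is operationalized purely on burial duration (<= 60 min);
surface-temperature estimates by cold, stressed rescuers are deliberately
not an input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .triage import InjuryAssessment, injuries_incompatible_with_life

__all__ = [
    "UNLIMITED",
    "AVPU_LEVELS",
    "AIRWAY_STATUSES",
    "AIR_POCKET_STATES",
    "PatientState",
    "ProtocolDecision",
    "ICPRPlan",
    "HypothermiaAssessment",
    "bls_sequence",
    "cpr_budget",
    "max_defibrillations",
    "hypothermia_stage",
    "assumed_cooling_gradient",
    "icpr_plan",
    "decision_trace",
]

#: Sentinel for "no fixed limit" (CPR until handover / standard AED rules).
UNLIMITED: float = math.inf

AVPU_LEVELS = ("A", "V", "P", "U")
AIRWAY_STATUSES = ("clear", "partially_obstructed", "fully_obstructed", "unknown")
AIR_POCKET_STATES = ("present", "absent", "unknown")

#: Burial duration (min) separating operationally normothermic patients from
#: potentially hypothermic ones.
NORMOTHERMIC_BURIAL_LIMIT_MIN: float = 60.0

#: CPR budget (min) for normothermic arrest under resource shortage:
#: three treatment windows of two minutes each.
SHORTAGE_CPR_BUDGET_MIN: float = 6.0

#: Defibrillation cap for potentially hypothermic patients.
HYPOTHERMIC_DEFIB_CAP: int = 3


@dataclass(frozen=True)
class PatientState:
    """BLS-observable findings for one avalanche patient.

    ``vital_signs_present`` is the assessment made *after* the five rescue
    breaths where those apply; ``shortage`` is the scene-level resource
    state. ``clear_answers`` and ``life_threatening_injury`` feed the
    conscious-patient filter and rescuer enlistment.
    """

    avpu: str
    breathing_normal: bool
    vital_signs_present: bool
    burial_duration_min: float
    agonal_breathing: bool = False
    airway_status: str = "unknown"
    air_pocket: str = "unknown"
    injuries: InjuryAssessment = field(default_factory=InjuryAssessment)
    shortage: bool = False
    clear_answers: bool = False
    life_threatening_injury: bool = False

    def __post_init__(self):
        if self.avpu not in AVPU_LEVELS:
            raise ValueError(f"avpu must be one of {AVPU_LEVELS}, got {self.avpu!r}")
        if self.airway_status not in AIRWAY_STATUSES:
            raise ValueError(f"airway_status must be one of {AIRWAY_STATUSES}")
        if self.air_pocket not in AIR_POCKET_STATES:
            raise ValueError(f"air_pocket must be one of {AIR_POCKET_STATES}")
        if self.burial_duration_min < 0:
            raise ValueError("burial_duration_min must be non-negative")
        if self.avpu == "A" and not self.vital_signs_present:
            raise ValueError("an alert patient has vital signs by definition")
        if self.breathing_normal and self.agonal_breathing:
            raise ValueError(
                "breathing_normal and agonal_breathing are mutually exclusive"
            )
        if self.breathing_normal and not self.vital_signs_present:
            raise ValueError("normal breathing is itself a vital sign")

    @property
    def normothermic(self) -> bool:
        return self.burial_duration_min <= NORMOTHERMIC_BURIAL_LIMIT_MIN


@dataclass(frozen=True)
class HypothermiaAssessment:
    """AVPU-derived hypothermia stage and its treatment bundle."""

    stage: int
    actions: tuple[str, ...]
    drink_conditional: bool = False
    warning: Optional[str] = None


@dataclass(frozen=True)
class ICPRPlan:
    """Intermittent-CPR timetable for potentially hypothermic arrest.

    ``pre_phase_min`` is the uninterrupted CPR required before cycling may
    start (one third of burial duration — the deliberately conservative
    rule); ``exact_cooling_time_min`` is the underlying 2 degC cooling time
    (burial duration / 3.5) exposed for reporting. Cycling is at least 5 min
    of CPR on, at most 5 min off; the first interruption can therefore occur
    no earlier than ``pre_phase_min`` plus one full on-cycle.
    """

    pre_phase_min: float
    first_interruption_at_min: float
    exact_cooling_time_min: float
    cycle_on_min: float = 5.0
    cycle_off_max_min: float = 5.0

    def __post_init__(self):
        if self.pre_phase_min < 0:
            raise ValueError("pre_phase_min must be non-negative")
        if self.cycle_on_min < 5.0:
            raise ValueError("cycle_on_min must be at least 5 min")
        if self.cycle_off_max_min > 5.0:
            raise ValueError("cycle_off_max_min must be at most 5 min")
        if not math.isclose(
            self.first_interruption_at_min, self.pre_phase_min + self.cycle_on_min
        ):
            raise ValueError("first interruption must follow pre-phase + one on-cycle")


@dataclass(frozen=True)
class ProtocolDecision:
    """Ordered action plan and numeric policies emitted by the rule engine."""

    actions: tuple[str, ...]
    cpr_budget_min: float
    max_defibrillations: float
    disposition: str  # treat | postpone | enlist | withhold
    hypothermia: Optional[HypothermiaAssessment] = None
    icpr: Optional[ICPRPlan] = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if self.disposition not in ("treat", "postpone", "enlist", "withhold"):
            raise ValueError(f"unknown disposition {self.disposition!r}")
        if self.cpr_budget_min < 0:
            raise ValueError("cpr_budget_min must be non-negative")
        if not self.actions and self.disposition not in ("postpone", "withhold"):
            raise ValueError("action list may be empty only when postponing/withholding")


def cpr_budget(p: PatientState) -> float:
    """CPR time budget (min) once cardiac arrest is established.

    Normothermic arrest (burial <= 60 min): 6 min under resource shortage
    (prolonging CPR past that costs more lives among the still-buried than it
    saves), unlimited otherwise. Potentially hypothermic arrest (burial >
    60 min): zero if the airway was fully obstructed with no air pocket (no
    gas exchange was possible — unsalvageable), otherwise unlimited.
    """
    if p.normothermic:
        return SHORTAGE_CPR_BUDGET_MIN if p.shortage else UNLIMITED
    if p.airway_status == "fully_obstructed" and p.air_pocket == "absent":
        return 0.0
    return UNLIMITED


def max_defibrillations(p: PatientState, shocks_delivered: int = 0) -> float:
    """Remaining defibrillations allowed for this patient.

    Potentially hypothermic patients (burial > 60 min) get at most three
    shocks — a cold myocardium rarely holds a successful defibrillation and
    repeated shocks injure it. Otherwise standard AED guidance applies
    (no fixed cap).
    """
    if shocks_delivered < 0:
        raise ValueError("shocks_delivered must be non-negative")
    if p.burial_duration_min > NORMOTHERMIC_BURIAL_LIMIT_MIN:
        return max(0, HYPOTHERMIC_DEFIB_CAP - shocks_delivered)
    return UNLIMITED


def hypothermia_stage(avpu: str, vital_signs: bool) -> HypothermiaAssessment:
    """Derive hypothermia stage 1-4 and its treatment bundle from AVPU.

    Shivering is deliberately not an input (unreliable, age- and
    trauma-dependent). Stage 1 (alert): active rewarming by moving plus warm
    sugary drinks. Stage 2 (voice-responsive): insulate, heat packs, drink
    only if able to swallow with the upper body slightly inclined. Stage 3
    (pain-responsive): insulate and heat packs only. Stage 4 (unresponsive,
    no vital signs): effective CPR is the priority.

    An unresponsive patient *with* preserved vital signs has no canonical
    stage on the arrest branch; the conservative stage-3 bundle is returned
    with a warning rather than declaring stage 4 in a perfusing patient.
    """
    if avpu not in AVPU_LEVELS:
        raise ValueError(f"avpu must be one of {AVPU_LEVELS}")
    if avpu == "A":
        return HypothermiaAssessment(1, ("move_actively", "warm_sugary_drink"))
    if avpu == "V":
        return HypothermiaAssessment(
            2, ("insulate", "heat_packs", "warm_sugary_drink"), drink_conditional=True
        )
    if avpu == "P":
        return HypothermiaAssessment(3, ("insulate", "heat_packs"))
    if vital_signs:
        return HypothermiaAssessment(
            3,
            ("insulate", "heat_packs"),
            warning="unresponsive with preserved vital signs: staged conservatively as 3",
        )
    return HypothermiaAssessment(4, ("cpr_30_2",))


def assumed_cooling_gradient(burial_duration_h: float) -> float:
    """Assumed core cooling gradient (degC per hour) during burial.

    Worst-case assumption: the patient reached hypothermic arrest at 30 degC
    (7 degC below normal core temperature) immediately before head and chest
    were freed, hence a gradient of 7 degC divided by the burial duration in
    hours.
    """
    if burial_duration_h <= 0:
        raise ValueError("burial_duration_h must be positive")
    return 7.0 / burial_duration_h


def icpr_plan(burial_duration_min: float) -> ICPRPlan:
    """Intermittent-CPR timetable for an arrested, potentially hypothermic patient.

    iCPR is only permissible below an assumed core temperature of 28 degC.
    Cooling the assumed 2 degC further (from the 30 degC arrest assumption)
    takes burial_duration / 3.5 at the assumed linear gradient; the applied
    rule uses burial_duration / 3, adding a safety margin for imprecisely
    known burial times. Patients at or below the 60 min normothermic boundary
    are not eligible.
    """
    if burial_duration_min < NORMOTHERMIC_BURIAL_LIMIT_MIN:
        raise ValueError(
            "iCPR applies only to potentially hypothermic patients "
            f"(burial duration >= {NORMOTHERMIC_BURIAL_LIMIT_MIN:.0f} min)"
        )
    pre = burial_duration_min / 3.0
    return ICPRPlan(
        pre_phase_min=pre,
        first_interruption_at_min=pre + 5.0,
        exact_cooling_time_min=burial_duration_min / 3.5,
    )


def bls_sequence(p: PatientState) -> ProtocolDecision:
    """Map a patient state to an ordered BLS action plan and disposition.

    Under resource shortage, conscious patients without life-threatening
    injuries are filtered out first: their treatment is postponed and, if
    they qualify, they are enlisted as rescuers. Patients with injuries
    incompatible with life have further treatment withheld. Everyone else is
    treated: clear the airway if needed, check breathing, give five rescue
    breaths when breathing is not normal (agonal breathing counts as not
    normal and is never a sign of life), then either continue with wilderness
    first aid (vital signs present) or start 30:2 CPR under the applicable
    time budget and defibrillation cap.
    """
    staging = hypothermia_stage(p.avpu, p.vital_signs_present)
    warnings = (staging.warning,) if staging.warning else ()

    # first filter: conscious, not obviously injured, resources short
    if p.avpu == "A" and not p.life_threatening_injury and p.shortage:
        from .triage import can_enlist_recovered_subject

        eligible, _monitor = can_enlist_recovered_subject(p)
        if eligible:
            return ProtocolDecision(
                actions=staging.actions,
                cpr_budget_min=0.0,
                max_defibrillations=0,
                disposition="enlist",
                hypothermia=staging,
                warnings=("monitor enlisted former burial subject",),
            )
        return ProtocolDecision(
            actions=(),
            cpr_budget_min=0.0,
            max_defibrillations=0,
            disposition="postpone",
            hypothermia=staging,
        )

    if injuries_incompatible_with_life(p.injuries):
        return ProtocolDecision(
            actions=(),
            cpr_budget_min=0.0,
            max_defibrillations=0,
            disposition="withhold",
            hypothermia=staging,
            warnings=warnings + ("injuries incompatible with life",),
        )

    actions: list[str] = []
    if p.airway_status != "clear":
        actions.append("clear_airway")
    actions.append("check_breathing")

    if p.breathing_normal:
        actions.append("wilderness_first_aid")
        actions.extend(staging.actions)
        return ProtocolDecision(
            actions=tuple(actions),
            cpr_budget_min=0.0,
            max_defibrillations=0,
            disposition="treat",
            hypothermia=staging,
            warnings=warnings,
        )

    # not breathing normally (agonal counts): five rescue breaths first
    actions.append("rescue_breaths_5")
    if p.vital_signs_present:
        actions.append("wilderness_first_aid")
        actions.extend(staging.actions)
        return ProtocolDecision(
            actions=tuple(actions),
            cpr_budget_min=0.0,
            max_defibrillations=0,
            disposition="treat",
            hypothermia=staging,
            warnings=warnings,
        )

    # cardiac arrest path
    budget = cpr_budget(p)
    if budget == 0.0:
        return ProtocolDecision(
            actions=tuple(actions),
            cpr_budget_min=0.0,
            max_defibrillations=0,
            disposition="withhold",
            hypothermia=staging,
            warnings=warnings
            + ("prolonged burial with fully obstructed airway and no air pocket",),
        )
    actions.append("cpr_30_2")
    actions.append("defibrillate")
    actions.append("handover")
    plan = None
    if p.burial_duration_min >= NORMOTHERMIC_BURIAL_LIMIT_MIN:
        plan = icpr_plan(p.burial_duration_min)
    return ProtocolDecision(
        actions=tuple(actions),
        cpr_budget_min=budget,
        max_defibrillations=max_defibrillations(p),
        disposition="treat",
        hypothermia=staging,
        icpr=plan,
        warnings=warnings,
    )


#: Nominal planning durations (min) used only for the decision-trace export.
_ACTION_DURATIONS_MIN = {
    "clear_airway": 1.0,
    "check_breathing": 0.5,
    "rescue_breaths_5": 1.0,
    "wilderness_first_aid": 10.0,
    "move_actively": 0.0,
    "warm_sugary_drink": 0.0,
    "insulate": 2.0,
    "heat_packs": 1.0,
    "defibrillate": 0.0,
    "handover": 0.0,
}


def decision_trace(decision: ProtocolDecision) -> list[dict]:
    """Flatten a decision into trace rows (action, nominal start/duration).

    The trace doubles as a minimal patient data record for handover: one row
    per planned action with a nominal timeline. CPR duration is the budget
    when finite, open-ended otherwise.
    """
    rows = []
    t = 0.0
    for action in decision.actions:
        if action == "cpr_30_2":
            dur = (
                decision.cpr_budget_min
                if math.isfinite(decision.cpr_budget_min)
                else None
            )
        else:
            dur = _ACTION_DURATIONS_MIN.get(action, 0.0)
        rows.append(
            {
                "action": action,
                "starts_at_min": round(t, 2),
                "nominal_duration_min": dur,
                "disposition": decision.disposition,
            }
        )
        t += dur if dur is not None else 0.0
    return rows
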