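"""Search-and-excavate triage rules for multiple burials.

Pure predicates encoding the field decision logic: when a shortage of
resources exists (fewer than two rescuers per remaining buried subject),
when excavation of a deeply buried subject should be postponed (depth at or
beyond the 150 cm triage threshold), the avalanche-specific definition of
injuries incompatible with life, and the criteria for enlisting a recovered
subject as an additional rescuer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .protocol import PatientState

__all__ = [
    "RescueState",
    "InjuryAssessment",
    "resource_shortage",
    "should_postpone_excavation",
    "injuries_incompatible_with_life",
    "can_enlist_recovered_subject",
    "DEPTH_TRIAGE_THRESHOLD_CM",
]

#: Burial-depth triage threshold: postpone excavation at or beyond this depth
#: when resources are short. Inclusive comparison (>= 150 cm).
DEPTH_TRIAGE_THRESHOLD_CM: float = 150.0


@dataclass(frozen=True)
class InjuryAssessment:
    """Avalanche-specific evidence of injuries incompatible with life.

    Blunt trauma dominates avalanche impact patterns, so the classical
    "obvious lethal injuries" filter (decapitation, truncal transection,
    whole body frozen) filters almost nothing; the criteria below replace it.
    """

    severe_mechanical_impact_evidence: bool = False
    high_fall: bool = False
    severe_collision_trees_rocks: bool = False
    head_truncal_position_incompatible: bool = False


@dataclass(frozen=True)
class RescueState:
    """Resource and per-subject context during the search-and-excavate phase."""

    n_rescuers: int
    n_remaining_buried: int
    current_subject_depth_cm: float = 0.0
    conscious: bool = False
    clear_answers: bool = False
    life_threatening_injury: bool = False

    def __post_init__(self):
        if self.n_rescuers < 0 or self.n_remaining_buried < 0:
            raise ValueError("counts must be non-negative")
        if self.current_subject_depth_cm < 0:
            raise ValueError("depth must be non-negative")


def resource_shortage(n_rescuers: int, n_remaining: int) -> bool:
    """True when there are fewer than two rescuers per remaining buried subject.

    Two rescuers per subject is the minimum for an efficient conveyor-belt
    excavation at typical burial depths and slope angles; at or above that
    ratio every subject can be excavated immediately. With nobody left buried
    there is no shortage by definition.
    """
    if n_rescuers < 0 or n_remaining < 0:
        raise ValueError("counts must be non-negative")
    return n_remaining > 0 and n_rescuers < 2 * n_remaining


def should_postpone_excavation(
    depth_cm: float, shortage: bool, threshold_cm: float = DEPTH_TRIAGE_THRESHOLD_CM
) -> bool:
    """Postpone excavation iff resources are short and the subject lies at or
    beyond the depth threshold (inclusive)."""
    if depth_cm < 0:
        raise ValueError("depth_cm must be non-negative")
    return bool(shortage) and depth_cm >= threshold_cm


def injuries_incompatible_with_life(a: InjuryAssessment) -> bool:
    """Disjunction of the four avalanche-specific lethal-injury criteria."""
    return (
        a.severe_mechanical_impact_evidence
        or a.high_fall
        or a.severe_collision_trees_rocks
        or a.head_truncal_position_incompatible
    )


def can_enlist_recovered_subject(p: "PatientState") -> tuple[bool, bool]:
    """Whether a recovered subject may join the rescue effort.

    Returns ``(eligible, monitoring_required)``. Eligible only if the patient
    is alert with clear answers, shows no life-threatening injury and is at
    worst hypothermia stage 1 (alert implies stage <= 1 on the AVPU-derived
    staging). Enlisted former burial subjects always require ongoing
    monitoring.
    """
    from .protocol import hypothermia_stage  # local import avoids cycle

    eligible = (
        p.avpu == "A"
        and p.clear_answers
        and not p.life_threatening_injury
        and not injuries_incompatible_with_life(p.injuries)
        and hypothermia_stage(p.avpu, p.vital_signs_present).stage <= 1
    )
    return eligible, True
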