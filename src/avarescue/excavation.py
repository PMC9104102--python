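"""Snow-conveyor-belt geometry, rescuer staffing and excavation time.

Buried subjects are dug out with the snow conveyor belt technique: rescuers
form a line downhill of the probe and displace snow in segments. The belt
must stay below a maximum ramp angle (26 degrees by default, the empirical
angle above which snow slides back towards the hole), which fixes the belt
length from burial depth and slope inclination. Staffing follows from the
belt length at a nominal 80 cm of belt per rescuer, stretchable to 90 cm.
Team dig rates are field-measured medians: 13.20 cm/min in hard debris
(hand-hardness one finger or harder) and 25.32 cm/min in soft debris
(four fingers or softer).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "DebrisHardness",
    "ExcavationSpec",
    "belt_length",
    "required_rescuers",
    "segment_length",
    "excavation_time",
]


class DebrisHardness(enum.Enum):
    """Avalanche-deposit hand-hardness category.

    ``HARD`` is a hand-hardness of one finger or harder, ``SOFT`` four
    fingers or softer. Hardness, not density, dominates dig rates.
    """

    HARD = "hard"
    SOFT = "soft"

    @classmethod
    def parse(cls, value) -> "DebrisHardness":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"hardness must be 'hard' or 'soft', got {value!r}"
            ) from None


@dataclass(frozen=True)
class ExcavationSpec:
    """Geometry, staffing and dig-rate parameters for conveyor-belt digging."""

    ramp_angle_deg: float = 26.0
    nominal_segment_cm: float = 80.0
    stretch_segment_cm: float = 90.0
    rate_hard_cm_per_min: float = 13.20
    rate_soft_cm_per_min: float = 25.32

    def __post_init__(self):
        if not 0 < self.ramp_angle_deg < 90:
            raise ValueError("ramp_angle_deg must lie in (0, 90)")
        if not 0 < self.nominal_segment_cm <= self.stretch_segment_cm:
            raise ValueError(
                "need 0 < nominal_segment_cm <= stretch_segment_cm"
            )
        if self.rate_hard_cm_per_min <= 0 or self.rate_soft_cm_per_min <= 0:
            raise ValueError("dig rates must be positive")
        if self.rate_soft_cm_per_min < self.rate_hard_cm_per_min:
            raise ValueError("rate_soft_cm_per_min must be >= rate_hard_cm_per_min")

    def rate(self, hardness: DebrisHardness) -> float:
        hardness = DebrisHardness.parse(hardness)
        return (
            self.rate_hard_cm_per_min
            if hardness is DebrisHardness.HARD
            else self.rate_soft_cm_per_min
        )


def belt_length(depth_cm: float, slope_deg: float, spec: ExcavationSpec | None = None) -> int:
    """Required conveyor-belt length (cm, nearest integer).

    The belt runs downhill from the probe at the maximum ramp angle, so its
    horizontal reach is ``depth * tan(90deg - ramp_angle - slope)``. At a
    slope of exactly ``90 - ramp_angle`` degrees the belt angle is zero and
    the length degenerates to 0 cm; steeper slopes have no valid geometry.
    """
    spec = spec or ExcavationSpec()
    if depth_cm < 0:
        raise ValueError("depth_cm must be non-negative")
    if not 0 <= slope_deg <= 90 - spec.ramp_angle_deg:
        raise ValueError(
            f"slope_deg must lie in [0, {90 - spec.ramp_angle_deg}] "
            f"for a ramp angle of {spec.ramp_angle_deg} deg"
        )
    angle = math.radians(90.0 - spec.ramp_angle_deg - slope_deg)
    # round half up: matches the printed worked example (100 cm / 3 deg -> 180 cm)
    return int(math.floor(depth_cm * math.tan(angle) + 0.5))


def required_rescuers(belt_length_cm: float, spec: ExcavationSpec | None = None) -> int:
    """Number of rescuers needed to staff a belt of the given length.

    Round ``belt_length / nominal_segment`` to the nearest integer (ties up,
    conservative staffing), with a minimum of one rescuer; if rounding down
    would stretch per-rescuer segments beyond the tolerated maximum, add a
    rescuer.
    """
    spec = spec or ExcavationSpec()
    if belt_length_cm < 0:
        raise ValueError("belt_length_cm must be non-negative")
    n = max(1, int(math.floor(belt_length_cm / spec.nominal_segment_cm + 0.5)))
    while belt_length_cm / n > spec.stretch_segment_cm:
        n += 1
    return n


def segment_length(belt_length_cm: float, n_rescuers: int) -> float:
    """Per-rescuer belt segment (cm) when the belt is split among ``n_rescuers``."""
    if n_rescuers < 1:
        raise ValueError("n_rescuers must be >= 1")
    if belt_length_cm < 0:
        raise ValueError("belt_length_cm must be non-negative")
    return belt_length_cm / n_rescuers


def excavation_time(
    depth_cm: float,
    hardness: DebrisHardness,
    spec: ExcavationSpec | None = None,
    staffing_factor: float = 1.0,
) -> float:
    """Minutes to dig down to a subject at ``depth_cm`` in the given debris.

    Uses the team-level median dig rate for the hardness category; rates
    assume the belt is staffed with at least the required rescuer count.
    ``staffing_factor`` in (0, 1] scales the rate down for understaffed teams
    (sensitivity-analysis plumbing, default fully staffed).
    """
    spec = spec or ExcavationSpec()
    if depth_cm < 0:
        raise ValueError("depth_cm must be non-negative")
    if not 0 < staffing_factor <= 1:
        raise ValueError("staffing_factor must lie in (0, 1]")
    return depth_cm / (spec.rate(hardness) * staffing_factor)
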