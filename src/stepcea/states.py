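"""State space of the cohort model.

Twelve mutually exclusive health states: three physical-activity (PA)
levels crossed with {healthy, diabetes, hypertension} (nine living states
that carry a PA level), one complication state per disease (cardiovascular
disease for diabetes, stroke for hypertension), and an absorbing dead
state. Complication states and dead carry no PA level. An individual can
develop diabetes or hypertension but never both; complications are chronic
(no recovery).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class PALevel(str, Enum):
    """Physical-activity level; ``inactive`` is the reference for all relative risks."""

    INACTIVE = "inactive"
    LOW = "low"
    MOD_HIGH = "mod_high"


PA_LEVELS = (PALevel.INACTIVE, PALevel.LOW, PALevel.MOD_HIGH)

#: Living disease groups that carry a PA level.
PA_GROUPS = ("healthy", "diabetes", "hypertension")

#: Chronic complication states (all-inpatient, no PA level, no recovery).
COMPLICATIONS = ("diabetes_cvd", "hypertension_stroke")

#: Parent uncomplicated disease of each complication state.
COMPLICATION_PARENT = {"diabetes_cvd": "diabetes", "hypertension_stroke": "hypertension"}

DISEASES = ("diabetes", "hypertension")

_VALID_DISEASES = PA_GROUPS + COMPLICATIONS + ("dead",)


@dataclass(frozen=True)
class HealthState:
    """One of the 12 model states.

    ``pa`` is defined iff ``disease`` is one of the nine PA-carrying living
    groups; complication states and ``dead`` carry none.
    """

    disease: str
    pa: PALevel | None = None

    def __post_init__(self) -> None:
        if self.disease not in _VALID_DISEASES:
            raise ValueError(f"unknown disease group {self.disease!r}")
        if self.disease in PA_GROUPS:
            if self.pa is None:
                raise ValueError(f"{self.disease} state requires a PA level")
        elif self.pa is not None:
            raise ValueError(f"{self.disease} state carries no PA level")

    @property
    def label(self) -> str:
        return f"{self.disease}/{self.pa.value}" if self.pa is not None else self.disease

    @property
    def is_living(self) -> bool:
        return self.disease != "dead"


#: Canonical state ordering used by every matrix and occupancy vector.
STATES: tuple[HealthState, ...] = tuple(
    [HealthState(g, pa) for g in PA_GROUPS for pa in PA_LEVELS]
    + [HealthState(c) for c in COMPLICATIONS]
    + [HealthState("dead")]
)

N_STATES = len(STATES)
STATE_LABELS = tuple(s.label for s in STATES)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
LABEL_INDEX = {s.label: i for i, s in enumerate(STATES)}

DEAD = STATE_INDEX[HealthState("dead")]
LIVING = tuple(i for i, s in enumerate(STATES) if s.is_living)


def state_index(disease: str, pa: PALevel | str | None = None) -> int:
    """Index of a state in the canonical ordering."""
    if isinstance(pa, str):
        pa = PALevel(pa)
    return STATE_INDEX[HealthState(disease, pa)]
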