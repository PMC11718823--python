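"""Core domain types for the decision matrix.

The matrix evaluates a structured preoperative patient record through four
sequential phases (diagnosis, staging/modality, resection planning + risk,
surgical feasibility, prognosis) under a four-level traffic-light semantics:

* GREEN  — proceed;
* YELLOW — proceed with warning (flag is kept in a cumulative ledger);
* ORANGE — temporary exclusion: the patient is parked until the triggering
  issue is resolved, then re-enters the matrix from the beginning;
* RED    — permanent exclusion from this matrix (referral elsewhere).

Severity is totally ordered GREEN < YELLOW < ORANGE < RED.  ORANGE sits below
RED because a temporary exclusion is subsumed by a permanent one: when both
fire in the same phase, the patient is excluded, not parked.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Iterable, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = [
    "TrafficLight",
    "Flag",
    "PhaseResult",
    "SegmentInvolvement",
    "PatientRecord",
    "ValidationFinding",
    "RecordFormatError",
    "IncompleteWorkupError",
    "SequencingError",
    "combine_lights",
    "validate_record",
    "record_from_dict",
    "SEGMENT_UNITS",
    "CLASSICAL_SEGMENT",
    "PHASES",
]


class TrafficLight(enum.IntEnum):
    """Four-level indicator; integer value is the severity rank."""

    GREEN = 0
    YELLOW = 1
    ORANGE = 2
    RED = 3

    def __str__(self) -> str:  # serialized form used in configs and reports
        return self.name.lower()

    @classmethod
    def parse(cls, text: str) -> "TrafficLight":
        try:
            return cls[str(text).upper()]
        except KeyError:
            raise ValueError(f"unknown traffic light {text!r}") from None


#: Phase identifiers in execution order.
PHASES = ("phase1", "phase2a", "phase2b", "phase3", "phase4")

#: The nine anatomical units of the involvement vector.  IVa/IVb are distinct
#: units but collapse onto classical Couinaud segment IV for segment counts.
SEGMENT_UNITS = ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII")

CLASSICAL_SEGMENT = {
    "I": "I", "II": "II", "III": "III",
    "IVa": "IV", "IVb": "IV",
    "V": "V", "VI": "VI", "VII": "VII", "VIII": "VIII",
}


def combine_lights(lights: Iterable[TrafficLight]) -> TrafficLight:
    """Combine per-parameter lights into an overall light (maximum severity).

    An empty collection combines to GREEN: nothing evaluated, nothing to
    object to.  The operation is idempotent, commutative and monotone.
    """
    result = TrafficLight.GREEN
    for light in lights:
        if light > result:
            result = light
    return result


@dataclass(frozen=True)
class Flag:
    """A non-green outcome attached to one parameter within one phase.

    Green outcomes are recorded in the trace (as evaluated lights), never as
    flags; ``reason`` is always non-empty human-readable text.
    """

    parameter_id: str
    phase_id: str
    light: TrafficLight
    reason: str

    def __post_init__(self) -> None:
        if self.light == TrafficLight.GREEN:
            raise ValueError("green outcomes are not flagged")
        if not self.reason:
            raise ValueError("flag reason must be non-empty")

    def to_dict(self) -> dict:
        return {
            "parameter_id": self.parameter_id,
            "phase_id": self.phase_id,
            "light": str(self.light),
            "reason": self.reason,
        }


@dataclass
class PhaseResult:
    """Outcome of one phase: all evaluated lights plus phase-specific payload.

    ``overall_light`` is the maximum severity among evaluated lights (the
    resection planner applies its modified red-handling *before* lights reach
    this result — an unmatched pattern is not a flag, only the final
    no-procedure verdict is).
    """

    phase_id: str
    overall_light: TrafficLight
    lights: dict[str, TrafficLight] = field(default_factory=dict)
    flags: list[Flag] = field(default_factory=list)
    payload: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "phase_id": self.phase_id,
            "overall_light": str(self.overall_light),
            "lights": {k: str(v) for k, v in self.lights.items()},
            "flags": [f.to_dict() for f in self.flags],
            "payload": self.payload,
        }


def phase_result(
    phase_id: str,
    lights: dict[str, TrafficLight],
    reasons: dict[str, str],
    payload: Optional[dict] = None,
) -> PhaseResult:
    """Assemble a PhaseResult from evaluated lights, flagging non-greens."""
    flags = [
        Flag(parameter_id=p, phase_id=phase_id, light=l,
             reason=reasons.get(p, f"{p} is {l}"))
        for p, l in lights.items()
        if l != TrafficLight.GREEN
    ]
    return PhaseResult(
        phase_id=phase_id,
        overall_light=combine_lights(lights.values()),
        lights=dict(lights),
        flags=flags,
        payload=payload or {},
    )


class RecordFormatError(ValueError):
    """A record is structurally unreadable (distinct from out-of-range values)."""


class IncompleteWorkupError(ValueError):
    """A phase requires a diagnostic that was not performed (``not_done``)."""


class SequencingError(RuntimeError):
    """A phase or state transition was attempted out of order."""


class SegmentInvolvement(BaseModel):
    """9-way Couinaud involvement vector (segment IV split into IVa/IVb)."""

    model_config = ConfigDict(frozen=True)

    I: bool = False
    II: bool = False
    III: bool = False
    IVa: bool = False
    IVb: bool = False
    V: bool = False
    VI: bool = False
    VII: bool = False
    VIII: bool = False

    def involved_units(self) -> frozenset[str]:
        return frozenset(u for u in SEGMENT_UNITS if getattr(self, u))

    @classmethod
    def from_units(cls, units: Iterable[str]) -> "SegmentInvolvement":
        units = set(units)
        unknown = units - set(SEGMENT_UNITS)
        if unknown:
            raise RecordFormatError(f"unknown anatomical units: {sorted(unknown)}")
        return cls(**{u: True for u in units})


class PatientRecord(BaseModel):
    """All preoperative inputs a single matrix evaluation consumes.

    Categorical fields are plain strings/ints here; their admissible levels are
    owned by the parameter registry and checked by :func:`validate_record`, so
    an invalid level (e.g. Child grade "D") is reported as a validation
    finding naming the allowed levels, while a structurally unreadable record
    (wrong JSON type, missing field) raises :class:`RecordFormatError`.
    Missing optional diagnostics are explicit (``"not_done"``), never
    defaulted.
    """

    model_config = ConfigDict(extra="ignore")

    patient_id: str

    # demographics
    age: float
    sex: str
    bmi: float
    asa_class: int

    # medical history
    nyha: int
    gold: int
    child: str
    hepatitis_b: bool
    hepatitis_c: bool
    ckd_stage: int
    acute_cholangitis: bool

    # laboratory values
    hemoglobin: float          # g/dL
    platelets: float           # 10^9/L
    wbc: float                 # per uL
    total_bilirubin: float     # umol/L
    direct_bilirubin: float    # umol/L
    albumin: float             # g/L
    ap: float                  # U/L
    got: float                 # U/L
    gpt: float                 # U/L
    ggt: float                 # U/L
    crp: float                 # mg/L
    ptt: float                 # s
    gfr: float                 # mL/min/1.73 m^2

    # tumor markers
    ca19_9: float              # U/mL
    cea: float                 # ng/L (unit as configured; see registry)
    afp: float                 # ng/mL

    # imaging
    ct_category: str
    distant_metastasis: bool
    peritoneal_metastasis: bool
    regional_lymph_nodes: bool
    ascites_grade: int
    steatosis_grade: int
    portal_hypertension: bool
    rlv_fraction: float
    vascular_involvement: bool
    tumor_count: int
    tumor_max_size: float      # cm

    # diagnostic procedures
    histopathology: str
    endoscopy_primary_tumor_found: Union[bool, Literal["not_done"]]

    # 9-way segment involvement (flat, so records stay flat JSON objects)
    segment_I: bool = False
    segment_II: bool = False
    segment_III: bool = False
    segment_IVa: bool = False
    segment_IVb: bool = False
    segment_V: bool = False
    segment_VI: bool = False
    segment_VII: bool = False
    segment_VIII: bool = False

    # surgeon / facility context
    surgeon_reconstruction_capable: bool
    reconstruction_feasible: bool
    icu_available: bool

    @property
    def segments(self) -> SegmentInvolvement:
        return SegmentInvolvement(
            **{u: getattr(self, f"segment_{u}") for u in SEGMENT_UNITS}
        )

    def with_updates(self, **updates: Any) -> "PatientRecord":
        return self.model_copy(update=updates)


def record_from_dict(data: dict) -> PatientRecord:
    """Parse a flat mapping into a record, distinguishing structural errors."""
    if not isinstance(data, dict):
        raise RecordFormatError(f"record must be a mapping, got {type(data).__name__}")
    try:
        return PatientRecord(**data)
    except ValidationError as exc:
        raise RecordFormatError(f"structurally unreadable record: {exc}") from exc


@dataclass(frozen=True)
class ValidationFinding:
    """One out-of-range or invalid-level value in a record."""

    field: str
    value: Any
    message: str

    def to_dict(self) -> dict:
        return {"field": self.field, "value": self.value, "message": self.message}


def validate_record(record: PatientRecord, registry) -> list[ValidationFinding]:
    """Check every populated field against its registry valid range / levels.

    Returns an empty list iff all record invariants hold.  Findings identify
    the field, the offending value and the violated bound.  Structural
    problems (wrong types, unreadable input) are raised earlier by
    :func:`record_from_dict`, never reported here.
    """
    findings: list[ValidationFinding] = []
    for param in registry.parameters.values():
        value = registry.record_value(record, param.id)
        if value is None:
            continue  # derived or not carried on the record
        if param.data_kind in ("continuous", "discrete"):
            lo, hi = param.valid_range
            if not (lo <= value <= hi):
                findings.append(ValidationFinding(
                    field=param.record_field or param.id,
                    value=value,
                    message=(
                        f"{param.id} = {value} outside valid range "
                        f"[{lo}, {hi}] {param.unit}".rstrip()
                    ),
                ))
        else:  # nominal / ordinal: enumerated levels
            levels = param.levels
            if value not in levels:
                findings.append(ValidationFinding(
                    field=param.record_field or param.id,
                    value=value,
                    message=(
                        f"{param.id} = {value!r} is not one of the "
                        f"enumerated levels {list(levels)}"
                    ),
                ))
    if not record.segments.involved_units():
        findings.append(ValidationFinding(
            field="segments",
            value=[],
            message="no tumor involvement: at least one of the nine "
                    "anatomical units must be involved",
        ))
    return findings
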