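"""Phase IIb — anatomical resection planning and resection-risk gating.

Layer 1 matches the 9-way Couinaud segment-involvement vector against the 18
location-permutation rules (9 procedure names in 3 categories) looking for a
resection with R0 potential.  The traffic-light model is applied in a
modified way here: a pattern that does not fit is *not* an exclusion — every
pattern is examined, and only if none fits is the patient marked red and
directed toward palliative/neoadjuvant options.  A rule fits when each of
its required-involvement groups intersects the involved units and every
involved unit lies inside the rule's resected set ("all other segments are
free" read as containment).  Among fitting rules the minimal-extent one is
selected: fewest resected units, ties broken by category (minor <
intermediate < major), then by name — minimal parenchymal sacrifice being
the standard surgical principle.

Layer 2 gates the chosen procedure's category on liver cirrhosis
(Child-Pugh), steatosis grade, and ICU availability via the configured risk
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    PatientRecord,
    PhaseResult,
    SegmentInvolvement,
    TrafficLight,
    combine_lights,
    phase_result,
)
from .registry import CATEGORIES, ParameterRegistry, ProcedureDefinition

__all__ = [
    "EmptyInvolvementError",
    "ResectionPlan",
    "match_procedures",
    "select_resection",
    "assess_resection_risk",
    "run_phase2b",
]

PHASE_ID = "phase2b"
DESTINATION_RED = "palliative/neoadjuvant matrix"

CATEGORY_ORDER = {c: i for i, c in enumerate(CATEGORIES)}

RISK_PARAMS = ("child", "steatosis_grade", "icu_available")


class EmptyInvolvementError(ValueError):
    """No anatomical unit is involved: nothing to plan a resection for."""


@dataclass
class ResectionPlan:
    """Full pattern truth table plus the selected minimal-extent procedure."""

    matched: list[tuple[ProcedureDefinition, bool]] = field(default_factory=list)
    selected: Optional[ProcedureDefinition] = None
    r0_possible: bool = False

    def fitting(self) -> list[ProcedureDefinition]:
        return [p for p, fits in self.matched if fits]

    def to_dict(self) -> dict:
        return {
            "r0_possible": self.r0_possible,
            "selected": self.selected.rule_id if self.selected else None,
            "matched": {p.rule_id: fits for p, fits in self.matched},
        }


def _selection_key(proc: ProcedureDefinition):
    return (len(proc.resected_units), CATEGORY_ORDER[proc.category],
            proc.name, proc.rule_id)


def match_procedures(segments: SegmentInvolvement,
                     table: Sequence[ProcedureDefinition],
                     ) -> list[ProcedureDefinition]:
    """All rules whose pattern clause holds for the involvement vector."""
    involved = segments.involved_units()
    if not involved:
        raise EmptyInvolvementError(
            "no tumor involvement: at least one anatomical unit must be involved")
    return [proc for proc in table if proc.fits(involved)]


def select_resection(segments: SegmentInvolvement,
                     table: Sequence[ProcedureDefinition]) -> ResectionPlan:
    """Examine ALL patterns, then select the minimal-extent fitting one."""
    involved = segments.involved_units()
    if not involved:
        raise EmptyInvolvementError(
            "no tumor involvement: at least one anatomical unit must be involved")
    matched = [(proc, proc.fits(involved)) for proc in table]
    fitting = [p for p, fits in matched if fits]
    if not fitting:
        return ResectionPlan(matched=matched, selected=None, r0_possible=False)
    selected = min(fitting, key=_selection_key)
    return ResectionPlan(matched=matched, selected=selected, r0_possible=True)


def assess_resection_risk(category: str, child: str, steatosis_grade: int,
                          icu_available: bool,
                          registry: ParameterRegistry) -> PhaseResult:
    """Layer 2: gate a selected procedure category on cirrhosis/steatosis/ICU."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown resection category {category!r}")
    values = {"child": child, "steatosis_grade": steatosis_grade,
              "icu_available": icu_available}
    lights = {p: registry.evaluate_risk(p, values[p], category)
              for p in RISK_PARAMS}
    reasons = {
        p: (f"{registry.parameter(p).display_name} = {values[p]} is "
            f"{l} for a {category} resection")
        for p, l in lights.items()
    }
    result = phase_result(PHASE_ID, lights, reasons,
                          payload={"layer": "resection_risk",
                                   "category": category})
    if child == "B" and category == "major":
        result.payload.setdefault("assumptions", []).append(
            "Child B with a major resection is marked red as a conservative "
            "completion of the configured escalation (the printed risk table "
            "stops at intermediate)")
    return result


def run_phase2b(record: PatientRecord, registry: ParameterRegistry,
                table: Optional[Sequence[ProcedureDefinition]] = None,
                ) -> PhaseResult:
    """Plan the resection, then gate it; red leads to palliative/neoadjuvant."""
    table = list(table) if table is not None else registry.procedures
    plan = select_resection(record.segments, table)
    if not plan.r0_possible:
        lights = {"tumor_location": TrafficLight.RED}
        reasons = {"tumor_location":
                   "no location permutation offers the potential for a "
                   "tumor-free resection margin (R0)"}
        result = phase_result(PHASE_ID, lights, reasons,
                              payload={"plan": plan.to_dict(),
                                       "destination": DESTINATION_RED})
        return result

    selected = plan.selected
    assert selected is not None
    risk = assess_resection_risk(selected.category, record.child,
                                 record.steatosis_grade, record.icu_available,
                                 registry)
    lights = {"tumor_location": TrafficLight.GREEN, **risk.lights}
    result = PhaseResult(
        phase_id=PHASE_ID,
        overall_light=combine_lights(lights.values()),
        lights=lights,
        flags=list(risk.flags),
        payload={
            "plan": plan.to_dict(),
            "procedure": selected.name,
            "rule_id": selected.rule_id,
            "category": selected.category,
            "resected_units": sorted(selected.resected_units),
        },
    )
    if "assumptions" in risk.payload:
        result.payload["assumptions"] = list(risk.payload["assumptions"])
    if result.overall_light == TrafficLight.RED:
        result.payload["destination"] = DESTINATION_RED
    return result
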