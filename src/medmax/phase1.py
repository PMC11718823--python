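"""Phase I — confirm or rule out suspected ihCC.

History, laboratory values and diagnostic procedures are screened with the
traffic-light model.  The orientation of the lab bands is diagnostic, not
prognostic: values that *favor* an ihCC diagnosis (high AP, GGT, albumin,
CA 19-9, CEA; low GOT, GPT, bilirubin, AFP) are green, intermediate or
borderline values that do not rule the diagnosis out are yellow.  Only the
three diagnostic procedures (histopathology, endoscopy, CT) can produce red:
a finding of a *different* tumor entity permanently excludes the patient
from this matrix (they belong in another one).
"""

from __future__ import annotations

from typing import Any, Mapping, Optional, Union

from .core import (
    IncompleteWorkupError,
    PatientRecord,
    PhaseResult,
    TrafficLight,
    phase_result,
)
from .registry import ParameterRegistry

__all__ = [
    "PHASE1_HISTORY",
    "PHASE1_LABS",
    "PHASE1_PROCEDURES",
    "assess_history",
    "assess_labs_phase1",
    "assess_procedures",
    "run_phase1",
]

PHASE_ID = "phase1"

PHASE1_HISTORY = ("hepatitis_b", "hepatitis_c", "child")
#: The nine diagnostic laboratory parameters of Phase I.
PHASE1_LABS = ("ap", "ggt", "albumin", "ca19_9", "cea",
               "got", "gpt", "total_bilirubin", "afp")
PHASE1_PROCEDURES = ("histopathology", "endoscopy_primary_tumor_found",
                     "ct_category")

DESTINATION_RED = "transfer to another matrix"


def assess_history(hepatitis_b: bool, hepatitis_c: bool, child: str,
                   registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """History screen: absent liver condition green, present yellow (never red)."""
    values = {"hepatitis_b": hepatitis_b, "hepatitis_c": hepatitis_c,
              "child": child}
    return {p: registry.evaluate(p, values[p], PHASE_ID) for p in PHASE1_HISTORY}


def assess_labs_phase1(values: Mapping[str, float],
                       registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """Evaluate the nine Phase-I labs; all bands end at yellow at worst."""
    missing = [p for p in PHASE1_LABS if p not in values]
    if missing:
        raise IncompleteWorkupError(
            f"incomplete laboratory workup, missing: {missing}")
    return {p: registry.evaluate(p, values[p], PHASE_ID) for p in PHASE1_LABS}


def assess_procedures(histopathology: str,
                      endoscopy_primary_tumor_found: Union[bool, str],
                      ct_category: str,
                      registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """Histopathology / endoscopy / CT screen.

    CT is the mandatory workup: ``not_done`` raises an incomplete-workup
    error.  Histopathology and endoscopy marked ``not_done`` are simply not
    evaluated (no light), never defaulted.
    """
    if ct_category == "not_done":
        if (histopathology == "not_done"
                and endoscopy_primary_tumor_found == "not_done"):
            raise IncompleteWorkupError(
                "insufficient workup: histopathology, endoscopy and CT all not done")
        raise IncompleteWorkupError("CT is required in Phase I but was not done")
    lights: dict[str, TrafficLight] = {}
    if histopathology != "not_done":
        lights["histopathology"] = registry.evaluate(
            "histopathology", histopathology, PHASE_ID)
    if endoscopy_primary_tumor_found != "not_done":
        lights["endoscopy_primary_tumor_found"] = registry.evaluate(
            "endoscopy_primary_tumor_found", endoscopy_primary_tumor_found,
            PHASE_ID)
    lights["ct_category"] = registry.evaluate("ct_category", ct_category, PHASE_ID)
    return lights


def run_phase1(record: PatientRecord, registry: ParameterRegistry) -> PhaseResult:
    """Run the diagnostic phase; red means exclusion toward another matrix."""
    lights: dict[str, TrafficLight] = {}
    lights.update(assess_history(record.hepatitis_b, record.hepatitis_c,
                                 record.child, registry))
    lights.update(assess_labs_phase1(
        {p: getattr(record, p) for p in PHASE1_LABS}, registry))
    lights.update(assess_procedures(
        record.histopathology, record.endoscopy_primary_tumor_found,
        record.ct_category, registry))
    reasons = {
        p: registry.reason(p, PHASE_ID, _value_of(record, p), l)
        for p, l in lights.items()
    }
    result = phase_result(PHASE_ID, lights, reasons)
    if result.overall_light == TrafficLight.RED:
        result.payload["destination"] = DESTINATION_RED
    return result


def _value_of(record: PatientRecord, param: str) -> Any:
    return getattr(record, param)
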