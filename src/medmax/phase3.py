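"""Phase III — feasibility of the selected surgery.

Three critical aspects are screened: the patient's condition (comorbidity
grades, labs, baseline data, imaging), the surgeon's qualifications relative
to the complexity of the case, and the hospital's facilities.  Severe
comorbidity (NYHA IV, GOLD IV, Child B/C, ASA V) or an infeasible required
reconstruction is red (palliative pathway); acute cholangitis, severe anemia
(Hb < 7 g/dL) and leukocytosis (> 10,000/uL) are orange — temporary
exclusions that park the patient until corrected, after which the matrix is
restarted from the beginning.  This phase only gates the procedure selected
in Phase IIb; it never changes it.
"""

from __future__ import annotations

from typing import Optional

from .core import (
    PatientRecord,
    PhaseResult,
    TrafficLight,
    phase_result,
)
from .registry import ParameterRegistry

__all__ = [
    "assess_condition",
    "assess_labs_phase3",
    "assess_baseline",
    "assess_imaging_phase3",
    "assess_surgeon_facility",
    "run_phase3",
]

PHASE_ID = "phase3"
DESTINATION_RED = "palliative matrix"

CONDITION_PARAMS = ("nyha", "gold", "child", "asa_class", "ckd_stage",
                    "acute_cholangitis")
LAB_PARAMS = ("hemoglobin", "platelets", "wbc", "total_bilirubin", "ptt", "gfr")
BASELINE_PARAMS = ("age", "bmi")
IMAGING_PARAMS = ("ascites_grade", "steatosis_grade", "portal_hypertension",
                  "rlv_fraction")


def _evaluate(registry: ParameterRegistry, values: dict) -> dict[str, TrafficLight]:
    return {p: registry.evaluate(p, v, PHASE_ID) for p, v in values.items()}


def assess_condition(nyha: int, gold: int, child: str, asa_class: int,
                     ckd_stage: int, acute_cholangitis: bool,
                     registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """Comorbidity screen; acute cholangitis is the only orange here."""
    return _evaluate(registry, {
        "nyha": nyha, "gold": gold, "child": child, "asa_class": asa_class,
        "ckd_stage": ckd_stage, "acute_cholangitis": acute_cholangitis,
    })


def assess_labs_phase3(hemoglobin: float, platelets: float, wbc: float,
                       total_bilirubin: float, ptt: float, gfr: float,
                       registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """Severe deviations (anemia, leukocytosis) orange; mild abnormalities yellow."""
    return _evaluate(registry, {
        "hemoglobin": hemoglobin, "platelets": platelets, "wbc": wbc,
        "total_bilirubin": total_bilirubin, "ptt": ptt, "gfr": gfr,
    })


def assess_baseline(age: float, bmi: float,
                    registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """Age >= 75 years and BMI >= 40 kg/m^2 are yellow; never red or orange."""
    return _evaluate(registry, {"age": age, "bmi": bmi})


def assess_imaging_phase3(ascites_grade: int, steatosis_grade: int,
                          portal_hypertension: bool, rlv_fraction: float,
                          registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """Each significant CT finding is a yellow warning."""
    return _evaluate(registry, {
        "ascites_grade": ascites_grade, "steatosis_grade": steatosis_grade,
        "portal_hypertension": portal_hypertension,
        "rlv_fraction": rlv_fraction,
    })


def assess_surgeon_facility(vascular_involvement: bool,
                            reconstruction_feasible: bool,
                            surgeon_reconstruction_capable: bool,
                            icu_available: bool,
                            registry: ParameterRegistry,
                            ) -> tuple[TrafficLight, TrafficLight]:
    """Combined surgeon-capability rule and facility (ICU) rule.

    Vascular involvement means a vascular/biliary reconstruction is required:
    red if the reconstruction is infeasible or the surgeon lacks the
    expertise; yellow (heightened risk) if the surgeon is qualified; green
    when no reconstruction is needed.  The facility light follows the ICU
    availability threshold.
    """
    if vascular_involvement:
        if not reconstruction_feasible or not surgeon_reconstruction_capable:
            surgeon = TrafficLight.RED
        else:
            # qualified surgeon, feasible reconstruction, but high-risk case
            surgeon = registry.evaluate("vascular_involvement", True, PHASE_ID)
    else:
        surgeon = TrafficLight.GREEN
    facility = registry.evaluate("icu_available", icu_available, PHASE_ID)
    return surgeon, facility


def run_phase3(record: PatientRecord, registry: ParameterRegistry) -> PhaseResult:
    lights: dict[str, TrafficLight] = {}
    lights.update(assess_condition(
        record.nyha, record.gold, record.child, record.asa_class,
        record.ckd_stage, record.acute_cholangitis, registry))
    lights.update(assess_labs_phase3(
        record.hemoglobin, record.platelets, record.wbc,
        record.total_bilirubin, record.ptt, record.gfr, registry))
    lights.update(assess_baseline(record.age, record.bmi, registry))
    lights.update(assess_imaging_phase3(
        record.ascites_grade, record.steatosis_grade,
        record.portal_hypertension, record.rlv_fraction, registry))
    surgeon, facility = assess_surgeon_facility(
        record.vascular_involvement, record.reconstruction_feasible,
        record.surgeon_reconstruction_capable, record.icu_available, registry)
    lights["surgeon"] = surgeon
    lights["facility"] = facility

    reasons = {}
    for p in (CONDITION_PARAMS + LAB_PARAMS + BASELINE_PARAMS + IMAGING_PARAMS):
        reasons[p] = registry.reason(p, PHASE_ID, getattr(record, p), lights[p])
    if surgeon == TrafficLight.RED:
        reasons["surgeon"] = (
            "required vascular/biliary reconstruction is not feasible"
            if not record.reconstruction_feasible
            else "surgeon lacks the expertise for the required reconstruction")
    elif surgeon == TrafficLight.YELLOW:
        reasons["surgeon"] = ("qualified surgeon but high-risk case "
                              "(major vascular involvement)")
    reasons["facility"] = "lack of adequate intensive care support"

    result = phase_result(PHASE_ID, lights, reasons)
    if result.overall_light == TrafficLight.RED:
        result.payload["destination"] = DESTINATION_RED
    elif result.overall_light == TrafficLight.ORANGE:
        result.payload["pending_issues"] = [
            f.parameter_id for f in result.flags
            if f.light == TrafficLight.ORANGE
        ]
    return result
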