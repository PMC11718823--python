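"""Phase IIa — treatment modality: screen for metastases and tumor burden.

Distant or peritoneal metastases on imaging exclude the patient from the
surgical pathway (red: systemic/palliative therapy).  Very high tumor-marker
levels (CEA > 14.4 ng/L, CA 19-9 > 1000 U/mL) or regional lymph-node
involvement signal extensive spread that could endanger resectability —
yellow warnings that travel with the patient, never exclusions.  This phase
emits no orange under any input.
"""

from __future__ import annotations

from .core import (
    PatientRecord,
    PhaseResult,
    TrafficLight,
    combine_lights,
    phase_result,
)
from .registry import ParameterRegistry

__all__ = ["assess_metastasis", "assess_tumor_burden", "run_phase2a"]

PHASE_ID = "phase2a"

DESTINATION_RED = "systemic therapy / palliative matrix"
MODALITY_SURGERY = "surgery candidate"

BURDEN_PARAMS = ("cea", "ca19_9", "regional_lymph_nodes")


def assess_metastasis(distant_metastasis: bool, peritoneal_metastasis: bool,
                      registry: ParameterRegistry) -> TrafficLight:
    """RED if either distant or peritoneal metastases are detected."""
    return combine_lights([
        registry.evaluate("distant_metastasis", distant_metastasis, PHASE_ID),
        registry.evaluate("peritoneal_metastasis", peritoneal_metastasis, PHASE_ID),
    ])


def assess_tumor_burden(cea: float, ca19_9: float,
                        regional_lymph_nodes: bool,
                        registry: ParameterRegistry) -> dict[str, TrafficLight]:
    """Independent per-parameter yellow flags for extensive tumor spread."""
    values = {"cea": cea, "ca19_9": ca19_9,
              "regional_lymph_nodes": regional_lymph_nodes}
    return {p: registry.evaluate(p, values[p], PHASE_ID) for p in BURDEN_PARAMS}


def run_phase2a(record: PatientRecord, registry: ParameterRegistry) -> PhaseResult:
    lights = {
        "distant_metastasis": registry.evaluate(
            "distant_metastasis", record.distant_metastasis, PHASE_ID),
        "peritoneal_metastasis": registry.evaluate(
            "peritoneal_metastasis", record.peritoneal_metastasis, PHASE_ID),
    }
    lights.update(assess_tumor_burden(
        record.cea, record.ca19_9, record.regional_lymph_nodes, registry))
    values = {
        "distant_metastasis": record.distant_metastasis,
        "peritoneal_metastasis": record.peritoneal_metastasis,
        "cea": record.cea,
        "ca19_9": record.ca19_9,
        "regional_lymph_nodes": record.regional_lymph_nodes,
    }
    reasons = {p: registry.reason(p, PHASE_ID, values[p], l)
               for p, l in lights.items()}
    result = phase_result(PHASE_ID, lights, reasons)
    if result.overall_light == TrafficLight.RED:
        result.payload["destination"] = DESTINATION_RED
        result.payload["modality"] = "systemic therapy"
    else:
        result.payload["modality"] = MODALITY_SURGERY
    return result
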