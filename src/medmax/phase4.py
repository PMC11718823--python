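"""Phase IV — 5-year overall-survival risk stratum for completed evaluations.

The calibrated factor cut-offs of the original tumor-board model are not
available, so this module ships a transparent, fully configurable default
scorer and makes no claim to be a fitted survival model: the score is a
weighted count of the yellow flags accumulated in Phases I-III plus weighted
contributions from the prognosis-bound parameters (CA 19-9 band, nodal
status, tumor number and size, vascular involvement, ALBI grade, CRP, direct
bilirubin).  Two configured score boundaries map the score onto three ordinal
strata (favorable / intermediate / unfavorable).  The whole section —
weights, boundaries, strata names — is replaceable via the rules config, and
the prognosis never alters the treatment recommendation fixed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import (
    Flag,
    PatientRecord,
    PhaseResult,
    SequencingError,
    TrafficLight,
    phase_result,
)
from .registry import ParameterRegistry, PrognosisConfig

__all__ = ["PrognosisResult", "predict_prognosis", "run_phase4"]

PHASE_ID = "phase4"

GATED_PHASES = ("phase1", "phase2a", "phase2b", "phase3")


@dataclass
class PrognosisResult:
    stratum: str
    score: float
    contributing_flags: list[Flag] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "score": self.score,
            "contributing_flags": [f.to_dict() for f in self.contributing_flags],
        }


def _check_sequencing(prior_results: Sequence[PhaseResult]) -> None:
    seen = [r.phase_id for r in prior_results]
    if seen != list(GATED_PHASES):
        raise SequencingError(
            f"prognosis requires completed phases {list(GATED_PHASES)}, "
            f"got {seen}")
    for result in prior_results:
        if result.overall_light >= TrafficLight.ORANGE:
            raise SequencingError(
                f"prognosis requires a trace without red/orange; "
                f"{result.phase_id} is {result.overall_light}")


def predict_prognosis(prior_results: Sequence[PhaseResult],
                      record: PatientRecord,
                      registry: ParameterRegistry,
                      config: PrognosisConfig | None = None) -> PrognosisResult:
    """Score a completed trace and map it onto a risk stratum.

    ``prior_results`` are the Phase I-III results of the final run, in order.
    """
    _check_sequencing(prior_results)
    config = config or registry.prognosis

    yellow_flags = [f for r in prior_results for f in r.flags
                    if f.light == TrafficLight.YELLOW]
    score = config.yellow_flag_weight * len(yellow_flags)

    factor_flags: list[Flag] = []
    for param_id, weight in sorted(config.factor_weights.items()):
        value = registry.record_value(record, param_id)
        light = registry.evaluate(param_id, value, PHASE_ID)
        if light != TrafficLight.GREEN:
            score += weight
            factor_flags.append(Flag(
                parameter_id=param_id, phase_id=PHASE_ID, light=light,
                reason=registry.reason(param_id, PHASE_ID, value, light)))

    low, high = config.strata_boundaries
    if score <= low:
        stratum = config.strata[0]
    elif score <= high:
        stratum = config.strata[1]
    else:
        stratum = config.strata[2]
    return PrognosisResult(stratum=stratum, score=score,
                           contributing_flags=yellow_flags + factor_flags)


def run_phase4(record: PatientRecord, registry: ParameterRegistry,
               prior_results: Sequence[PhaseResult],
               config: PrognosisConfig | None = None) -> PhaseResult:
    """Wrap the prognosis as a phase result (factor lights, stratum payload)."""
    prognosis = predict_prognosis(prior_results, record, registry, config)
    config = config or registry.prognosis
    lights: dict[str, TrafficLight] = {}
    reasons: dict[str, str] = {}
    for param_id in sorted(config.factor_weights):
        value = registry.record_value(record, param_id)
        light = registry.evaluate(param_id, value, PHASE_ID)
        lights[param_id] = light
        reasons[param_id] = registry.reason(param_id, PHASE_ID, value, light)
    result = phase_result(PHASE_ID, lights, reasons,
                          payload={"prognosis": prognosis.to_dict()})
    return result
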