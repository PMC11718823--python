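"""Engine — orchestrates the four phases as an auditable state machine.

Phases run in strict order (I, IIa, IIb, III, IV).  Within a phase *all*
parameters are evaluated before the stop decision, so exclusion reasons are
complete; the stop applies between phases.  A red overall light terminates
the run permanently (``excluded_red`` with a destination), an orange light
parks the patient (``parked_orange`` with a pending-issue list).  When both
red and orange triggers fire in the same phase, red dominates: permanent
exclusion subsumes temporary exclusion.  A parked patient re-enters via
:func:`resolve_and_reenter`, which restarts the whole matrix from Phase I on
a fresh record snapshot — tumors are dynamic, so nothing from the earlier run
is reused — while prior runs stay in the trace for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    Flag,
    PatientRecord,
    PhaseResult,
    SequencingError,
    TrafficLight,
    ValidationFinding,
    validate_record,
)
from .phase1 import run_phase1
from .phase2a import run_phase2a
from .phase3 import run_phase3
from .phase4 import PrognosisResult, predict_prognosis, run_phase4
from .planner import run_phase2b
from .registry import (
    ParameterRegistry,
    PrognosisConfig,
    ProcedureDefinition,
    default_registry,
)

__all__ = [
    "MatrixState",
    "DecisionTrace",
    "InvalidRecordError",
    "run_matrix",
    "resolve_and_reenter",
    "trace_severity",
]


class InvalidRecordError(ValueError):
    """The record failed registry validation before Phase I."""

    def __init__(self, findings: Sequence[ValidationFinding]):
        self.findings = list(findings)
        details = "; ".join(f.message for f in self.findings)
        super().__init__(f"record failed validation: {details}")


@dataclass
class MatrixState:
    """Terminal (or parked) state of an evaluation."""

    status: str  # active | completed | excluded_red | parked_orange
    current_phase: str
    run_index: int = 1
    pending_issues: list[Flag] = field(default_factory=list)
    destination: str = ""

    def __post_init__(self) -> None:
        if self.status == "parked_orange" and not self.pending_issues:
            raise ValueError("parked_orange requires pending issues")
        if self.status == "excluded_red" and not self.destination:
            raise ValueError("excluded_red requires a destination")

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "current_phase": self.current_phase,
            "run_index": self.run_index,
            "pending_issues": [f.to_dict() for f in self.pending_issues],
            "destination": self.destination,
        }


@dataclass
class DecisionTrace:
    """Ordered phase results per run, yellow ledger, final state, decision."""

    patient_id: str
    runs: list[list[PhaseResult]]
    final_state: MatrixState
    recommendation: dict
    yellow_ledger: list[Flag] = field(default_factory=list)
    prognosis: Optional[PrognosisResult] = None
    assumptions_log: list[str] = field(default_factory=list)

    @property
    def final_run(self) -> list[PhaseResult]:
        return self.runs[-1]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "runs": [[r.to_dict() for r in run] for run in self.runs],
            "yellow_ledger": [f.to_dict() for f in self.yellow_ledger],
            "final_state": self.final_state.to_dict(),
            "recommendation": self.recommendation,
            "prognosis": self.prognosis.to_dict() if self.prognosis else None,
            "assumptions_log": list(self.assumptions_log),
        }


def trace_severity(trace: DecisionTrace) -> TrafficLight:
    """Maximum light severity across the final run (for monotonicity checks)."""
    return max((r.overall_light for r in trace.final_run),
               default=TrafficLight.GREEN)


def _run_once(record: PatientRecord, registry: ParameterRegistry,
              table: Optional[Sequence[ProcedureDefinition]],
              prognosis_config: Optional[PrognosisConfig],
              run_index: int,
              ) -> tuple[list[PhaseResult], MatrixState, dict,
                         Optional[PrognosisResult], list[str]]:
    results: list[PhaseResult] = []
    assumptions: list[str] = []

    phase_runners = [
        ("phase1", lambda: run_phase1(record, registry)),
        ("phase2a", lambda: run_phase2a(record, registry)),
        ("phase2b", lambda: run_phase2b(record, registry, table)),
        ("phase3", lambda: run_phase3(record, registry)),
    ]
    for phase_id, runner in phase_runners:
        result = runner()
        results.append(result)
        assumptions.extend(result.payload.get("assumptions", []))
        if result.overall_light == TrafficLight.RED:
            if (phase_id == "phase3" and record.child == "B"
                    and result.lights.get("child") == TrafficLight.RED):
                assumptions.append(
                    "documented inconsistency: Child B is tolerated for a "
                    "minor resection at planning (Phase IIb) but is red at "
                    "feasibility (Phase III); both rules applied as configured")
            state = MatrixState(
                status="excluded_red", current_phase=phase_id,
                run_index=run_index,
                destination=result.payload.get("destination", "excluded"))
            recommendation = {
                "kind": "systemic_or_palliative",
                "destination": state.destination,
            }
            return results, state, recommendation, None, assumptions
        if result.overall_light == TrafficLight.ORANGE:
            pending = [f for f in result.flags
                       if f.light == TrafficLight.ORANGE]
            state = MatrixState(
                status="parked_orange", current_phase=phase_id,
                run_index=run_index, pending_issues=pending)
            recommendation = {
                "kind": "re_evaluate_after_resolution",
                "pending_issues": [f.parameter_id for f in pending],
            }
            return results, state, recommendation, None, assumptions

    prognosis = predict_prognosis(results, record, registry, prognosis_config)
    phase4_result = run_phase4(record, registry, results, prognosis_config)
    results.append(phase4_result)
    phase2b_payload = results[2].payload
    recommendation = {
        "kind": "surgery",
        "procedure": phase2b_payload["procedure"],
        "rule_id": phase2b_payload["rule_id"],
        "category": phase2b_payload["category"],
        "prognosis_stratum": prognosis.stratum,
    }
    state = MatrixState(status="completed", current_phase="phase4",
                        run_index=run_index)
    return results, state, recommendation, prognosis, assumptions


def run_matrix(record: PatientRecord,
               registry: Optional[ParameterRegistry] = None,
               table: Optional[Sequence[ProcedureDefinition]] = None,
               prognosis_config: Optional[PrognosisConfig] = None,
               ) -> DecisionTrace:
    """Evaluate one validated record through all phases; returns the trace.

    Raises :class:`InvalidRecordError` before Phase I if any field is out of
    range or no anatomical unit is involved.
    """
    registry = registry or default_registry()
    findings = validate_record(record, registry)
    if findings:
        raise InvalidRecordError(findings)
    results, state, recommendation, prognosis, assumptions = _run_once(
        record, registry, table, prognosis_config, run_index=1)
    return DecisionTrace(
        patient_id=record.patient_id,
        runs=[results],
        yellow_ledger=_yellow_ledger(results),
        final_state=state,
        recommendation=recommendation,
        prognosis=prognosis,
        assumptions_log=assumptions,
    )


def resolve_and_reenter(trace: DecisionTrace, updated_record: PatientRecord,
                        registry: Optional[ParameterRegistry] = None,
                        table: Optional[Sequence[ProcedureDefinition]] = None,
                        prognosis_config: Optional[PrognosisConfig] = None,
                        ) -> DecisionTrace:
    """Re-enter a parked patient: restart from Phase I on the updated record.

    No cached phase results are reused; the prior runs are retained in the
    returned trace for audit.  Re-entry on a non-parked trace is a state
    violation.
    """
    if trace.final_state.status != "parked_orange":
        raise SequencingError(
            f"re-entry requires a parked_orange trace, got "
            f"{trace.final_state.status!r}")
    registry = registry or default_registry()
    findings = validate_record(updated_record, registry)
    if findings:
        raise InvalidRecordError(findings)
    run_index = trace.final_state.run_index + 1
    results, state, recommendation, prognosis, assumptions = _run_once(
        updated_record, registry, table, prognosis_config, run_index=run_index)
    return DecisionTrace(
        patient_id=updated_record.patient_id,
        runs=[*trace.runs, results],
        yellow_ledger=_yellow_ledger(results),
        final_state=state,
        recommendation=recommendation,
        prognosis=prognosis,
        assumptions_log=[*trace.assumptions_log, *assumptions],
    )


def _yellow_ledger(results: Sequence[PhaseResult]) -> list[Flag]:
    """All yellow flags of one run, in phase order, without duplication."""
    seen: set[tuple[str, str]] = set()
    ledger: list[Flag] = []
    for result in results:
        for flag in result.flags:
            if flag.light != TrafficLight.YELLOW:
                continue
            key = (flag.phase_id, flag.parameter_id)
            if key in seen:
                continue
            seen.add(key)
            ledger.append(flag)
    return ledger
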