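"""Readers and writers: records (JSON/CSV), cohorts, traces, rule dumps.

JSON is the canonical record format (one flat object per patient, or a list
of them); CSV is a convenience projection with one column per parameter and
the nine segment flags as 0/1 columns (RFC-4180, UTF-8, "." decimal).
Unknown columns are ignored with a warning for forward compatibility.
Trace reports serialize to JSON (lossless round-trip, deterministic bytes:
sorted keys, no timestamps) or to a human-readable table that ends with the
effective-threshold footer rendered from the registry, so every number in a
report traces to a registry entry or a record field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import ExpectedOutcome
from .core import (
    PatientRecord,
    RecordFormatError,
    ValidationFinding,
    record_from_dict,
    validate_record,
)
from .engine import DecisionTrace
from .registry import ParameterRegistry, dump_rules

__all__ = [
    "RecordSetValidationError",
    "load_records",
    "read_records",
    "validate_records",
    "records_to_csv",
    "records_to_json",
    "write_cohort",
    "trace_to_json",
    "render_trace_table",
    "write_trace",
    "render_threshold_footer",
]

logger = logging.getLogger("medmax.io")

_FIELDS = list(PatientRecord.model_fields)
_BOOL_FIELDS = [
    "hepatitis_b", "hepatitis_c", "acute_cholangitis", "distant_metastasis",
    "peritoneal_metastasis", "regional_lymph_nodes", "portal_hypertension",
    "vascular_involvement", "surgeon_reconstruction_capable",
    "reconstruction_feasible", "icu_available",
] + [f"segment_{u}" for u in
     ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII")]
_INT_FIELDS = ["asa_class", "nyha", "gold", "ckd_stage", "ascites_grade",
               "steatosis_grade", "tumor_count"]


class RecordSetValidationError(ValueError):
    """Aggregated validation findings for a whole file of records."""

    def __init__(self, findings: dict[str, list[ValidationFinding]]):
        self.findings = findings
        lines = [f"{pid}: {f.message}" for pid, fs in findings.items() for f in fs]
        super().__init__("record validation failed:\n" + "\n".join(lines))


def _coerce_bool(field: str, value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str) and value.strip().lower() in ("0", "1", "true", "false"):
        return value.strip().lower() in ("1", "true")
    raise RecordFormatError(f"{field}: cannot read {value!r} as a 0/1 boolean")


def _row_to_record(row: dict) -> PatientRecord:
    # unwrap numpy scalars coming out of pandas
    data = {k: (v.item() if hasattr(v, "item") else v) for k, v in row.items()}
    for f in _BOOL_FIELDS:
        if f in data:
            data[f] = _coerce_bool(f, data[f])
    for f in _INT_FIELDS:
        if f in data and data[f] is not None:
            data[f] = int(data[f])
    endo = data.get("endoscopy_primary_tumor_found")
    if isinstance(endo, str) and endo != "not_done":
        data["endoscopy_primary_tumor_found"] = _coerce_bool(
            "endoscopy_primary_tumor_found", endo)
    elif isinstance(endo, (int, float)) and not isinstance(endo, bool):
        data["endoscopy_primary_tumor_found"] = _coerce_bool(
            "endoscopy_primary_tumor_found", endo)
    return record_from_dict(data)


def load_records(path: Union[str, Path]) -> list[PatientRecord]:
    """Parse a JSON or CSV file into records (structural validation only)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise RecordFormatError(f"{path}: malformed JSON: {exc}") from exc
        rows = payload if isinstance(payload, list) else [payload]
        records = []
        for row in rows:
            unknown = set(row) - set(_FIELDS) if isinstance(row, dict) else set()
            if unknown:
                logger.warning("%s: ignoring unknown fields %s",
                               path, sorted(unknown))
            records.append(_row_to_record(row))
        return records
    if path.suffix.lower() == ".csv":
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # malformed file, distinct from invalid values
            raise RecordFormatError(f"{path}: malformed CSV: {exc}") from exc
        unknown = [c for c in frame.columns if c not in _FIELDS]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, unknown)
            frame = frame.drop(columns=unknown)
        return [_row_to_record(row) for row in frame.to_dict(orient="records")]
    raise RecordFormatError(f"{path}: unsupported record format {path.suffix!r}")


def validate_records(records: Sequence[PatientRecord],
                     registry: ParameterRegistry,
                     ) -> dict[str, list[ValidationFinding]]:
    """All findings per record id; empty dict iff every record is valid."""
    findings: dict[str, list[ValidationFinding]] = {}
    for record in records:
        record_findings = validate_record(record, registry)
        if record_findings:
            findings[record.patient_id] = record_findings
    return findings


def read_records(path: Union[str, Path],
                 registry: ParameterRegistry) -> list[PatientRecord]:
    """Load and validate; aggregates all findings per file before raising."""
    records = load_records(path)
    findings = validate_records(records, registry)
    if findings:
        raise RecordSetValidationError(findings)
    return records


def _record_row(record: PatientRecord) -> dict:
    row = record.model_dump()
    for f in _BOOL_FIELDS:
        row[f] = int(row[f])
    endo = row["endoscopy_primary_tumor_found"]
    if endo != "not_done":
        row["endoscopy_primary_tumor_found"] = int(endo)
    return row


def records_to_csv(records: Sequence[PatientRecord],
                   path: Union[str, Path]) -> None:
    frame = pd.DataFrame([_record_row(r) for r in records], columns=_FIELDS)
    # %.17g round-trips doubles exactly through the CSV projection
    frame.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def records_to_json(records: Sequence[PatientRecord],
                    path: Union[str, Path]) -> None:
    rows = [r.model_dump() for r in records]
    payload = rows[0] if len(rows) == 1 else rows
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def write_cohort(records: Sequence[PatientRecord],
                 outcomes: Sequence[ExpectedOutcome],
                 records_path: Union[str, Path],
                 truth_path: Union[str, Path]) -> None:
    """Cohort CSV plus truth-table CSV (expected outcome per record)."""
    records_to_csv(records, records_path)
    truth = pd.DataFrame([
        {"patient_id": r.patient_id, **o.to_dict()}
        for r, o in zip(records, outcomes)
    ])
    truth.to_csv(truth_path, index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# Trace reports
# --------------------------------------------------------------------------

def trace_to_json(trace: DecisionTrace) -> str:
    """Deterministic JSON report (sorted keys, no timestamps)."""
    return json.dumps(trace.to_dict(), indent=2, sort_keys=True) + "\n"


def _format_edge(value: float) -> str:
    return f"{value:g}"


def render_threshold_footer(registry: ParameterRegistry) -> str:
    """Every effective threshold, rendered from the registry (audit footer)."""
    lines = ["effective thresholds (registry v%s):" % registry.version]
    for pid in sorted(registry.parameters):
        param = registry.parameters[pid]
        for phase_id in sorted(param.phase_bindings):
            binding = param.phase_bindings[phase_id]
            if binding.kind == "bands":
                parts = []
                for band in binding.bands:
                    lo_b = "[" if band.lo_inclusive else "("
                    hi_b = "]" if band.hi_inclusive else ")"
                    parts.append(f"{band.light} {lo_b}{_format_edge(band.lo)}, "
                                 f"{_format_edge(band.hi)}{hi_b}")
                unit = f" {param.unit}" if param.unit else ""
                lines.append(f"  {pid}/{phase_id}{unit}: " + " | ".join(parts))
            elif binding.kind == "levels":
                parts = [f"{level}={light}"
                         for level, light in binding.levels.items()]
                lines.append(f"  {pid}/{phase_id}: " + ", ".join(parts))
            elif binding.kind == "risk_table":
                for level, row in binding.risk_table.items():
                    cells = ", ".join(f"{c}={l}" for c, l in row.items())
                    lines.append(f"  {pid}/{phase_id} [{level}]: {cells}")
    lines.append(f"  albi grade boundaries: grade1 <= "
                 f"{_format_edge(registry.albi_grade1_max)}, grade3 > "
                 f"{_format_edge(registry.albi_grade2_max)}")
    return "\n".join(lines)


def render_trace_table(trace: DecisionTrace,
                       registry: Optional[ParameterRegistry] = None) -> str:
    """Human-readable report: per-phase lights, flags, assumptions, footer."""
    lines = [f"patient: {trace.patient_id}"]
    for run_no, run in enumerate(trace.runs, start=1):
        lines.append(f"run {run_no}:")
        for result in run:
            lines.append(f"  {result.phase_id}: {result.overall_light}")
            for pid, light in result.lights.items():
                lines.append(f"    {pid:32s} {light}")
            for flag in result.flags:
                lines.append(f"    ! {flag.light}: {flag.parameter_id} — "
                             f"{flag.reason}")
            if "procedure" in result.payload:
                lines.append(f"    -> procedure: {result.payload['procedure']} "
                             f"({result.payload['category']})")
    state = trace.final_state
    lines.append(f"final state: {state.status} at {state.current_phase} "
                 f"(run {state.run_index})")
    if state.destination:
        lines.append(f"destination: {state.destination}")
    lines.append(f"recommendation: {json.dumps(trace.recommendation, sort_keys=True)}")
    if trace.prognosis is not None:
        lines.append(f"prognosis: {trace.prognosis.stratum} "
                     f"(score {trace.prognosis.score:g})")
    if trace.yellow_ledger:
        lines.append("yellow ledger:")
        for flag in trace.yellow_ledger:
            lines.append(f"  {flag.phase_id}/{flag.parameter_id}: {flag.reason}")
    if trace.assumptions_log:
        lines.append("assumptions:")
        for note in trace.assumptions_log:
            lines.append(f"  - {note}")
    if registry is not None:
        lines.append(render_threshold_footer(registry))
    return "\n".join(lines) + "\n"


def write_trace(trace: DecisionTrace, format: str = "json",
                registry: Optional[ParameterRegistry] = None) -> str:
    """Serialized report; ``format`` is ``json`` or ``table``."""
    if format == "json":
        return trace_to_json(trace)
    if format == "table":
        return render_trace_table(trace, registry)
    raise ValueError(f"unknown report format {format!r}")
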