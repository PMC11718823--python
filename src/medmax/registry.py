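"""Parameter registry: the 45 clinical factors, all thresholds, ALBI scoring.

Every numeric cut-off the matrix uses lives in an external rules document
(YAML), loaded into a :class:`ParameterRegistry`.  Each parameter carries, per
phase, a threshold-to-light mapping in one of four forms:

``bands``
    An ordered-breakpoint partition of the valid range for continuous /
    discrete parameters.  Each band states only its *upper* edge and whether
    that edge is inclusive; the next band starts at the complementary open /
    closed edge, and the last band runs to the top of the valid range.  A
    partition therefore holds by construction, and out-of-order breakpoints
    are rejected as overlapping intervals.
``levels``
    A level-to-light map for nominal / ordinal parameters.  The special level
    ``not_done`` may be left unmapped: evaluating it raises an
    incomplete-workup error instead of guessing.
``risk_table``
    A level × resection-category (minor / intermediate / major) light table,
    used by the resection-risk layer.
``pattern_table``
    Marker binding for tumor location: the segment-involvement pattern table
    (see :mod:`medmax.planner`) is the threshold structure.

The ALBI (albumin-bilirubin) score is
``log10(bilirubin [umol/L]) * 0.66 + albumin [g/L] * (-0.085)`` with grade 1
at score <= -2.60, grade 3 above -1.39, grade 2 between; both boundaries are
configuration constants.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import yaml

from .core import (
    CLASSICAL_SEGMENT,
    PHASES,
    SEGMENT_UNITS,
    IncompleteWorkupError,
    PatientRecord,
    TrafficLight,
)

__all__ = [
    "RulesConfigError",
    "UnknownParameterError",
    "MissingPhaseBindingError",
    "MalformedIntervalError",
    "Band",
    "PhaseBinding",
    "ParameterDefinition",
    "ProcedureDefinition",
    "PrognosisConfig",
    "AlbiResult",
    "ParameterRegistry",
    "albi_score",
    "albi_grade",
    "compute_albi",
    "evaluate_parameter",
    "load_rules",
    "default_registry",
    "dump_rules",
]

CATEGORIES = ("minor", "intermediate", "major")


class RulesConfigError(ValueError):
    """The rules configuration violates its schema."""


class UnknownParameterError(RulesConfigError):
    """A rule references a parameter id that is not defined."""


class MissingPhaseBindingError(RulesConfigError):
    """A parameter is bound to no phase (each must be used in at least one)."""


class MalformedIntervalError(RulesConfigError):
    """Band breakpoints are out of order, overlapping, or outside the range."""


# --------------------------------------------------------------------------
# ALBI score
# --------------------------------------------------------------------------

def albi_score(bilirubin: float, albumin: float) -> float:
    """Albumin-bilirubin score: log10(bilirubin)*0.66 + albumin*(-0.085).

    ``bilirubin`` in umol/L, ``albumin`` in g/L; both must be positive.
    """
    if bilirubin <= 0:
        raise ValueError(f"bilirubin must be positive (got {bilirubin})")
    if albumin <= 0:
        raise ValueError(f"albumin must be positive (got {albumin})")
    return math.log10(bilirubin) * 0.66 + albumin * (-0.085)


def albi_grade(score: float, grade1_max: float = -2.60,
               grade2_max: float = -1.39) -> int:
    """Grade 1 iff score <= grade1_max; grade 3 iff score > grade2_max."""
    if not math.isfinite(score):
        raise ValueError(f"ALBI score must be finite (got {score})")
    if score <= grade1_max:
        return 1
    if score <= grade2_max:
        return 2
    return 3


@dataclass(frozen=True)
class AlbiResult:
    score: float
    grade: int


def compute_albi(bilirubin: float, albumin: float, grade1_max: float = -2.60,
                 grade2_max: float = -1.39) -> AlbiResult:
    score = albi_score(bilirubin, albumin)
    return AlbiResult(score=score, grade=albi_grade(score, grade1_max, grade2_max))


# --------------------------------------------------------------------------
# Threshold structures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One interval of a partition, with explicit edge inclusivity."""

    light: TrafficLight
    lo: float
    lo_inclusive: bool
    hi: float
    hi_inclusive: bool
    reason: str = ""

    def contains(self, value: float) -> bool:
        above = value > self.lo or (self.lo_inclusive and value == self.lo)
        below = value < self.hi or (self.hi_inclusive and value == self.hi)
        return above and below


@dataclass
class PhaseBinding:
    """Threshold-to-light mapping of one parameter within one phase."""

    kind: str  # bands | levels | risk_table | pattern_table
    bands: list[Band] = field(default_factory=list)
    levels: dict[Any, TrafficLight] = field(default_factory=dict)
    risk_table: dict[Any, dict[str, TrafficLight]] = field(default_factory=dict)
    reasons: dict[Any, str] = field(default_factory=dict)


@dataclass
class ParameterDefinition:
    """One clinical factor: identity, data kind, unit, range, phase bindings."""

    id: str
    display_name: str
    data_kind: str  # nominal | ordinal | continuous | discrete
    unit: str = ""
    valid_range: Optional[tuple[float, float]] = None
    levels: tuple = ()
    record_field: Optional[str] = None
    provenance: str = ""
    phase_bindings: dict[str, PhaseBinding] = field(default_factory=dict)


@dataclass(frozen=True)
class ProcedureDefinition:
    """One location-permutation rule: a named resection and its pattern.

    ``required_groups`` is a conjunction of disjunctions over anatomical
    units ("tumor present in IVa or IVb or I" -> one group); the implicit
    "all other segments are free" clause is containment: every involved unit
    must lie inside ``resected_units``.
    """

    rule_id: str
    name: str
    category: str
    resected_units: frozenset[str]
    required_groups: tuple[frozenset[str], ...]

    def classical_segment_count(self) -> int:
        """Resected classical Couinaud segments (IVa+IVb collapse to IV)."""
        return len({CLASSICAL_SEGMENT[u] for u in self.resected_units})

    def fits(self, involved: frozenset[str]) -> bool:
        if not involved <= self.resected_units:
            return False
        return all(involved & group for group in self.required_groups)


@dataclass
class PrognosisConfig:
    yellow_flag_weight: float
    factor_weights: dict[str, float]
    strata_boundaries: tuple[float, float]
    strata: tuple[str, str, str]


# --------------------------------------------------------------------------
# Registry
# --------------------------------------------------------------------------

@dataclass
class ParameterRegistry:
    """All parameter definitions plus the planner table and scorer config."""

    parameters: dict[str, ParameterDefinition]
    procedures: list[ProcedureDefinition]
    prognosis: PrognosisConfig
    albi_grade1_max: float
    albi_grade2_max: float
    version: str = "1.0"

    @property
    def provenance(self) -> dict[str, str]:
        return {p.id: p.provenance for p in self.parameters.values()}

    def parameter(self, param_id: str) -> ParameterDefinition:
        try:
            return self.parameters[param_id]
        except KeyError:
            raise UnknownParameterError(f"unknown parameter id {param_id!r}") from None

    def record_value(self, record: PatientRecord, param_id: str) -> Any:
        """Value a parameter takes on a record; None for derived parameters."""
        param = self.parameter(param_id)
        if param.record_field is None:
            if param_id == "albi_grade":
                return compute_albi(
                    record.total_bilirubin, record.albumin,
                    self.albi_grade1_max, self.albi_grade2_max,
                ).grade
            return None  # tumor_location: consumed as a segment vector
        return getattr(record, param.record_field)

    def evaluate(self, param_id: str, value: Any, phase_id: str) -> TrafficLight:
        return evaluate_parameter(self.parameter(param_id), value, phase_id)

    def evaluate_risk(self, param_id: str, value: Any, category: str) -> TrafficLight:
        """Resolve a risk_table binding (resection-risk layer, phase2b)."""
        binding = _binding(self.parameter(param_id), "phase2b")
        if binding.kind != "risk_table":
            raise RulesConfigError(
                f"{param_id} phase2b binding is {binding.kind}, expected risk_table")
        if value not in binding.risk_table:
            raise RulesConfigError(
                f"{param_id}: no risk row for level {value!r}")
        row = binding.risk_table[value]
        if category not in row:
            raise RulesConfigError(
                f"{param_id}: no risk entry for category {category!r}")
        return row[category]

    def reason(self, param_id: str, phase_id: str, value: Any,
               light: TrafficLight) -> str:
        """Human-readable reason for a flag, from config where provided."""
        param = self.parameter(param_id)
        binding = _binding(param, phase_id)
        text = ""
        if binding.kind == "bands":
            for band in binding.bands:
                if band.contains(value):
                    text = band.reason
                    break
        else:
            text = binding.reasons.get(_freeze(value), "")
        if text:
            return text
        unit = f" {param.unit}" if param.unit else ""
        return f"{param.display_name} = {value}{unit} is {light} in {phase_id}"

    def to_config_dict(self) -> dict:
        return _registry_to_dict(self)


def _freeze(value: Any) -> Any:
    return value if isinstance(value, (str, bool, int)) else str(value)


def _binding(param: ParameterDefinition, phase_id: str) -> PhaseBinding:
    try:
        return param.phase_bindings[phase_id]
    except KeyError:
        raise RulesConfigError(
            f"parameter {param.id!r} is not bound to {phase_id!r}; "
            f"bound phases: {sorted(param.phase_bindings)}"
        ) from None


def evaluate_parameter(definition: ParameterDefinition, value: Any,
                       phase_id: str) -> TrafficLight:
    """Light of the unique interval/level containing ``value`` in ``phase_id``.

    Raises a configuration error for an unbound phase (never a silent green)
    and an :class:`IncompleteWorkupError` when a required diagnostic is
    ``not_done``.
    """
    binding = _binding(definition, phase_id)
    if binding.kind == "levels":
        if value in binding.levels:
            return binding.levels[value]
        if value == "not_done":
            raise IncompleteWorkupError(
                f"{definition.id} was not performed but is required in {phase_id}")
        raise RulesConfigError(
            f"{definition.id}: level {value!r} has no light in {phase_id}")
    if binding.kind == "bands":
        for band in binding.bands:
            if band.contains(value):
                return band.light
        lo, hi = definition.valid_range
        raise ValueError(
            f"{definition.id} = {value} outside valid range [{lo}, {hi}]")
    raise RulesConfigError(
        f"{definition.id} {phase_id} binding of kind {binding.kind!r} "
        "cannot be evaluated as a scalar parameter")


# --------------------------------------------------------------------------
# Loading / dumping
# --------------------------------------------------------------------------

def _parse_light(text: Any) -> TrafficLight:
    return TrafficLight.parse(text)


def _parse_bands(param_id: str, phase_id: str, spec: Sequence[Mapping],
                 valid_range: tuple[float, float]) -> list[Band]:
    if valid_range is None:
        raise RulesConfigError(
            f"{param_id}: bands binding requires a numeric valid_range")
    lo, hi = valid_range
    bands: list[Band] = []
    cursor, cursor_inclusive = lo, True
    for i, raw in enumerate(spec):
        last = i == len(spec) - 1
        if "max" in raw and last:
            raise MalformedIntervalError(
                f"{param_id}/{phase_id}: last band must run to the top of "
                "the valid range (no 'max')")
        if "max" not in raw and not last:
            raise MalformedIntervalError(
                f"{param_id}/{phase_id}: band {i} needs a 'max' breakpoint")
        if last:
            upper, upper_inclusive = hi, True
        else:
            upper = float(raw["max"])
            upper_inclusive = bool(raw.get("max_inclusive", True))
            if not (lo <= upper <= hi):
                raise MalformedIntervalError(
                    f"{param_id}/{phase_id}: breakpoint {upper} outside "
                    f"valid range [{lo}, {hi}]")
        if upper < cursor or (upper == cursor and not (cursor_inclusive or upper_inclusive)):
            raise MalformedIntervalError(
                f"{param_id}/{phase_id}: overlapping or out-of-order "
                f"intervals at breakpoint {upper}")
        bands.append(Band(
            light=_parse_light(raw["light"]),
            lo=cursor, lo_inclusive=cursor_inclusive,
            hi=upper, hi_inclusive=upper_inclusive,
            reason=raw.get("reason", ""),
        ))
        cursor, cursor_inclusive = upper, not upper_inclusive
    if not bands:
        raise MalformedIntervalError(f"{param_id}/{phase_id}: empty bands list")
    return bands


def _parse_binding(param_id: str, phase_id: str, raw: Mapping,
                   levels: tuple, valid_range) -> PhaseBinding:
    kind = raw.get("kind", "bands" if "bands" in raw else "levels")
    reasons = dict(raw.get("reasons", {}))
    if kind == "bands":
        bands = _parse_bands(param_id, phase_id, raw["bands"], valid_range)
        return PhaseBinding(kind="bands", bands=bands, reasons=reasons)
    if kind == "levels":
        mapping = {k: _parse_light(v) for k, v in raw["levels"].items()}
        required = [l for l in levels if l != "not_done"]
        missing = [l for l in required if l not in mapping]
        if missing:
            raise RulesConfigError(
                f"{param_id}/{phase_id}: levels binding misses {missing}")
        return PhaseBinding(kind="levels", levels=mapping, reasons=reasons)
    if kind == "risk_table":
        table: dict[Any, dict[str, TrafficLight]] = {}
        for level, row in raw["table"].items():
            table[level] = {c: _parse_light(v) for c, v in row.items()}
            unknown = set(table[level]) - set(CATEGORIES)
            if unknown:
                raise RulesConfigError(
                    f"{param_id}/{phase_id}: unknown categories {sorted(unknown)}")
        return PhaseBinding(kind="risk_table", risk_table=table, reasons=reasons)
    if kind == "pattern_table":
        return PhaseBinding(kind="pattern_table", reasons=reasons)
    raise RulesConfigError(f"{param_id}/{phase_id}: unknown binding kind {kind!r}")


def _parse_parameter(param_id: str, raw: Mapping) -> ParameterDefinition:
    data_kind = raw.get("data_kind")
    if data_kind not in ("nominal", "ordinal", "continuous", "discrete"):
        raise RulesConfigError(f"{param_id}: invalid data_kind {data_kind!r}")
    valid_range = None
    if raw.get("valid_range") is not None:
        lo, hi = raw["valid_range"]
        valid_range = (float(lo), float(hi))
    levels = tuple(raw.get("levels", ()))
    phases_raw = raw.get("phases") or {}
    if not phases_raw:
        raise MissingPhaseBindingError(
            f"parameter {param_id!r} is bound to no phase; every parameter "
            "must be used in at least one phase")
    bindings = {}
    for phase_id, binding_raw in phases_raw.items():
        if phase_id not in PHASES:
            raise RulesConfigError(f"{param_id}: unknown phase {phase_id!r}")
        bindings[phase_id] = _parse_binding(
            param_id, phase_id, binding_raw, levels, valid_range)
    return ParameterDefinition(
        id=param_id,
        display_name=raw.get("display_name", param_id),
        data_kind=data_kind,
        unit=raw.get("unit", "") or "",
        valid_range=valid_range,
        levels=levels,
        record_field=raw.get("record_field", param_id),
        provenance=raw.get("provenance", ""),
        phase_bindings=bindings,
    )


def _parse_procedure(raw: Mapping) -> ProcedureDefinition:
    units = frozenset(raw["resected_units"])
    unknown = units - set(SEGMENT_UNITS)
    if unknown:
        raise RulesConfigError(
            f"procedure {raw.get('rule_id')}: unknown units {sorted(unknown)}")
    category = raw["category"]
    if category not in CATEGORIES:
        raise RulesConfigError(
            f"procedure {raw.get('rule_id')}: unknown category {category!r}")
    groups = tuple(frozenset(g) for g in raw["required_groups"])
    for g in groups:
        if not g <= units:
            raise RulesConfigError(
                f"procedure {raw.get('rule_id')}: required group {sorted(g)} "
                "not inside resected_units")
    return ProcedureDefinition(
        rule_id=raw["rule_id"],
        name=raw["name"],
        category=category,
        resected_units=units,
        required_groups=groups,
    )


def load_rules(source: Union[str, Path, Mapping, io.TextIOBase]) -> ParameterRegistry:
    """Load and validate a rules configuration into a registry.

    ``source`` may be a path, a YAML string, an open text stream, or an
    already-parsed mapping.  Unknown parameter ids, missing phase bindings
    and malformed intervals each raise a distinct schema error.
    """
    if isinstance(source, Mapping):
        config = dict(source)
    else:
        if isinstance(source, Path) or (
                isinstance(source, str) and "\n" not in source
                and Path(source).exists()):
            text = Path(source).read_text(encoding="utf-8")
        elif isinstance(source, str):
            text = source
        else:
            text = source.read()
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise RulesConfigError("rules config must be a mapping")

    parameters = {
        pid: _parse_parameter(pid, raw)
        for pid, raw in (config.get("parameters") or {}).items()
    }
    procedures = [_parse_procedure(p) for p in config.get("procedures", [])]

    albi_cfg = config.get("albi", {})
    g1 = float(albi_cfg.get("grade1_max", -2.60))
    g2 = float(albi_cfg.get("grade2_max", -1.39))
    if g1 >= g2:
        raise RulesConfigError("ALBI grade boundaries must increase")

    prog_raw = config.get("prognosis", {})
    weights = {k: float(v) for k, v in prog_raw.get("factor_weights", {}).items()}
    for pid in weights:
        if pid not in parameters:
            raise UnknownParameterError(
                f"prognosis factor weight references unknown parameter {pid!r}")
        if "phase4" not in parameters[pid].phase_bindings:
            raise RulesConfigError(
                f"prognosis factor {pid!r} is not bound to phase4")
    boundaries = tuple(float(b) for b in prog_raw.get("strata_boundaries", (1.0, 4.0)))
    if len(boundaries) != 2 or boundaries[0] > boundaries[1]:
        raise RulesConfigError("strata_boundaries must be two ascending numbers")
    strata = tuple(prog_raw.get("strata", ("favorable", "intermediate", "unfavorable")))
    if len(strata) != 3:
        raise RulesConfigError("exactly three strata are required")
    prognosis = PrognosisConfig(
        yellow_flag_weight=float(prog_raw.get("yellow_flag_weight", 1.0)),
        factor_weights=weights,
        strata_boundaries=boundaries,  # type: ignore[arg-type]
        strata=strata,  # type: ignore[arg-type]
    )

    return ParameterRegistry(
        parameters=parameters,
        procedures=procedures,
        prognosis=prognosis,
        albi_grade1_max=g1,
        albi_grade2_max=g2,
        version=str(config.get("version", "1.0")),
    )


def default_registry() -> ParameterRegistry:
    """Registry loaded from the packaged default rules document."""
    text = resources.files("medmax.data").joinpath("default_rules.yaml").read_text(
        encoding="utf-8")
    return load_rules(text)


def _binding_to_dict(param: ParameterDefinition, binding: PhaseBinding) -> dict:
    out: dict[str, Any] = {"kind": binding.kind}
    if binding.reasons:
        out["reasons"] = dict(binding.reasons)
    if binding.kind == "bands":
        bands = []
        for i, b in enumerate(binding.bands):
            entry: dict[str, Any] = {"light": str(b.light)}
            if i < len(binding.bands) - 1:
                entry["max"] = b.hi
                entry["max_inclusive"] = b.hi_inclusive
            if b.reason:
                entry["reason"] = b.reason
            bands.append(entry)
        out["bands"] = bands
    elif binding.kind == "levels":
        out["levels"] = {k: str(v) for k, v in binding.levels.items()}
    elif binding.kind == "risk_table":
        out["table"] = {
            level: {c: str(v) for c, v in row.items()}
            for level, row in binding.risk_table.items()
        }
    return out


def _registry_to_dict(registry: ParameterRegistry) -> dict:
    params: dict[str, Any] = {}
    for pid, p in registry.parameters.items():
        params[pid] = {
            "display_name": p.display_name,
            "data_kind": p.data_kind,
            "unit": p.unit,
            "valid_range": list(p.valid_range) if p.valid_range else None,
            "levels": list(p.levels),
            "record_field": p.record_field,
            "provenance": p.provenance,
            "phases": {
                phase: _binding_to_dict(p, b)
                for phase, b in p.phase_bindings.items()
            },
        }
    return {
        "version": registry.version,
        "albi": {
            "grade1_max": registry.albi_grade1_max,
            "grade2_max": registry.albi_grade2_max,
        },
        "parameters": params,
        "procedures": [
            {
                "rule_id": p.rule_id,
                "name": p.name,
                "category": p.category,
                "resected_units": sorted(p.resected_units,
                                         key=SEGMENT_UNITS.index),
                "required_groups": [
                    sorted(g, key=SEGMENT_UNITS.index) for g in p.required_groups
                ],
            }
            for p in registry.procedures
        ],
        "prognosis": {
            "yellow_flag_weight": registry.prognosis.yellow_flag_weight,
            "factor_weights": dict(registry.prognosis.factor_weights),
            "strata_boundaries": list(registry.prognosis.strata_boundaries),
            "strata": list(registry.prognosis.strata),
        },
    }


def dump_rules(registry: ParameterRegistry) -> str:
    """Effective configuration as YAML (stable key order for audit diffs)."""
    return yaml.safe_dump(registry.to_config_dict(), sort_keys=True,
                          default_flow_style=False, allow_unicode=True)
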