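"""Synthetic patient cohorts with constructed ground-truth outcomes.

No clinical cohort ships with the package, so every phase and the end-to-end
engine are exercised on synthetic tumor-board-style records whose outcome is
true *by construction*: each archetype forces exactly the triggers of one
terminal state while sampling every other parameter strictly inside the
interior of its favorable band (open intervals, so boundary ambiguity can
never blur a truth label; boundary behavior is tested separately by
deterministic sweeps).  Segment-involvement patterns come from small
hand-verified tables: resectable patterns paired with the procedure the
minimal-extent rule must select, and patterns no procedure's resected set can
contain.

Marginal distributions are test-oriented, not population-calibrated ihCC
epidemiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import PatientRecord

__all__ = [
    "ARCHETYPES",
    "RESECTABLE_PATTERNS",
    "UNRESECTABLE_PATTERNS",
    "CohortProfile",
    "ExpectedOutcome",
    "generate_patient",
    "generate_cohort",
]

ARCHETYPES = (
    "clean_pass",
    "yellow_pass",
    "red_phase1",
    "red_phase2a",
    "unresectable_phase2b",
    "risk_red_phase2b",
    "red_phase3",
    "orange_phase3",
)

#: Hand-verified involvement patterns and the rule the minimal-extent
#: selection must pick for them (with its category).
RESECTABLE_PATTERNS: list[tuple[frozenset, str, str]] = [
    (frozenset({"V"}), "segmentectomy_V", "minor"),
    (frozenset({"II", "III"}), "bisegmentectomy_II_III", "minor"),
    (frozenset({"VI", "VII"}), "bisegmentectomy_VI_VII", "minor"),
    (frozenset({"V", "VIII"}), "right_mesohepatectomy", "intermediate"),
    (frozenset({"IVa", "IVb"}), "left_mesohepatectomy", "intermediate"),
    (frozenset({"V", "VI"}), "right_hemihepatectomy", "intermediate"),
    (frozenset({"II", "IVb"}), "left_hemihepatectomy", "intermediate"),
    (frozenset({"IVa", "V"}), "central_mesohepatectomy", "major"),
    (frozenset({"IVb", "V", "VI"}), "extended_right_hepatectomy", "major"),
    (frozenset({"II", "IVa", "VIII"}), "extended_left_hepatectomy", "major"),
]

#: Hand-verified patterns that no procedure's resected set contains.
UNRESECTABLE_PATTERNS: list[frozenset] = [
    frozenset({"II", "VI"}),
    frozenset({"I", "VI"}),
    frozenset({"III", "VIII"}),
    frozenset({"II", "V"}),
    frozenset({"I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII"}),
]


@dataclass(frozen=True)
class ExpectedOutcome:
    """Constructed truth for one synthetic record."""

    archetype: str
    status: str            # completed | excluded_red | parked_orange
    terminal_phase: str    # phase at which the run ends
    final_light: str       # green/yellow (completed), red, or orange
    procedure_rule_id: Optional[str] = None  # for completed records
    category: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "archetype": self.archetype,
            "status": self.status,
            "terminal_phase": self.terminal_phase,
            "final_light": self.final_light,
            "procedure_rule_id": self.procedure_rule_id or "",
            "category": self.category or "",
        }


@dataclass
class CohortProfile:
    """Cohort recipe: size, archetype mix, seed, band-interior jitter scale."""

    n: int
    mix: dict[str, float] = field(
        default_factory=lambda: {a: 1 / len(ARCHETYPES) for a in ARCHETYPES})
    seed: int = 0
    noise: float = 1.0  # 0..1: fraction of each open band interior sampled

    def __post_init__(self) -> None:
        unknown = set(self.mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(self.mix.values())
        if self.mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix proportions must sum to 1 (got {total})")
        if not (0 < self.noise <= 1):
            raise ValueError("noise must be in (0, 1]")


def _uniform(rng: np.random.Generator, lo: float, hi: float,
             noise: float = 1.0) -> float:
    """Sample strictly inside (lo, hi), optionally shrunk toward the center."""
    center, half = (lo + hi) / 2, (hi - lo) / 2
    margin = half * (1 - 0.98 * noise)
    return float(rng.uniform(center - half + margin, center + half - margin))


def _favorable_record(rng: np.random.Generator, patient_id: str,
                      segments: frozenset, noise: float) -> dict:
    """All parameters strictly inside their green/favorable band interiors."""
    u = lambda lo, hi: _uniform(rng, lo, hi, noise)
    return {
        "patient_id": patient_id,
        "age": u(40, 70),
        "sex": str(rng.choice(["male", "female"])),
        "bmi": u(20, 30),
        "asa_class": int(rng.integers(1, 3)),
        "nyha": int(rng.integers(0, 2)),
        "gold": int(rng.integers(0, 2)),
        "child": "none",
        "hepatitis_b": False,
        "hepatitis_c": False,
        "ckd_stage": int(rng.integers(0, 2)),
        "acute_cholangitis": False,
        "hemoglobin": u(12, 16),
        "platelets": u(200, 350),
        "wbc": u(4500, 9000),
        # bilirubin/albumin kept inside ALBI grade-1 territory
        "total_bilirubin": u(5, 15),
        "direct_bilirubin": u(2, 6),
        "albumin": u(40, 47),
        "ap": u(270, 500),
        "got": u(15, 35),
        "gpt": u(15, 35),
        "ggt": u(130, 300),
        "crp": u(1, 8),
        "ptt": u(25, 35),
        "gfr": u(70, 110),
        "ca19_9": u(110, 450),
        "cea": u(6, 14),
        "afp": u(1, 6),
        "ct_category": "ihcc_consistent",
        "distant_metastasis": False,
        "peritoneal_metastasis": False,
        "regional_lymph_nodes": False,
        "ascites_grade": 0,
        "steatosis_grade": 1,
        "portal_hypertension": False,
        "rlv_fraction": u(0.35, 0.6),
        "vascular_involvement": False,
        "tumor_count": 1,
        "tumor_max_size": u(2.0, 4.8),
        "histopathology": "ihcc",
        "endoscopy_primary_tumor_found": False,
        **{f"segment_{unit}": (unit in segments) for unit in
           ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII")},
        "surgeon_reconstruction_capable": True,
        "reconstruction_feasible": True,
        "icu_available": True,
    }


def _pick(rng: np.random.Generator, options: list):
    return options[int(rng.integers(0, len(options)))]


#: Yellow triggers that warn but never stop a run (independent of the
#: selected procedure's category).
_YELLOW_TRIGGERS = (
    ("hepatitis_b", lambda rng, u: {"hepatitis_b": True}),
    ("hepatitis_c", lambda rng, u: {"hepatitis_c": True}),
    ("age", lambda rng, u: {"age": u(75.5, 85)}),
    ("bmi", lambda rng, u: {"bmi": u(40.5, 48)}),
    ("nodes", lambda rng, u: {"regional_lymph_nodes": True}),
    ("nyha", lambda rng, u: {"nyha": 3}),
    ("gold", lambda rng, u: {"gold": 3}),
    ("ascites", lambda rng, u: {"ascites_grade": 1}),
    ("portal_htn", lambda rng, u: {"portal_hypertension": True}),
    ("platelets", lambda rng, u: {"platelets": u(80, 140)}),
    ("ptt", lambda rng, u: {"ptt": u(42, 60)}),
    ("gfr", lambda rng, u: {"gfr": u(12, 28)}),
    ("vascular", lambda rng, u: {"vascular_involvement": True}),
    ("ca19_9_prog", lambda rng, u: {"ca19_9": u(550, 900)}),
    ("multifocal", lambda rng, u: {"tumor_count": int(rng.integers(2, 5))}),
)


def generate_patient(archetype: str, seed: int,
                     noise: float = 1.0) -> tuple[PatientRecord, ExpectedOutcome]:
    """One synthetic record plus its constructed expected outcome."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = np.random.default_rng(seed)
    u = lambda lo, hi: _uniform(rng, lo, hi, noise)
    patient_id = f"{archetype}-{seed}"

    pattern, rule_id, category = _pick(rng, RESECTABLE_PATTERNS)
    data = _favorable_record(rng, patient_id, pattern, noise)

    if archetype == "clean_pass":
        expected = ExpectedOutcome(archetype, "completed", "phase4",
                                   "green", rule_id, category)

    elif archetype == "yellow_pass":
        k = int(rng.integers(1, 4))
        idx = rng.choice(len(_YELLOW_TRIGGERS), size=k, replace=False)
        for i in sorted(int(j) for j in idx):
            data.update(_YELLOW_TRIGGERS[i][1](rng, u))
        expected = ExpectedOutcome(archetype, "completed", "phase4",
                                   "yellow", rule_id, category)

    elif archetype == "red_phase1":
        data.update(_pick(rng, [
            {"histopathology": "other_tumor"},
            {"endoscopy_primary_tumor_found": True},
            {"ct_category": "other_tumor"},
        ]))
        expected = ExpectedOutcome(archetype, "excluded_red", "phase1", "red")

    elif archetype == "red_phase2a":
        data.update(_pick(rng, [
            {"distant_metastasis": True},
            {"peritoneal_metastasis": True},
            {"distant_metastasis": True, "peritoneal_metastasis": True},
        ]))
        expected = ExpectedOutcome(archetype, "excluded_red", "phase2a", "red")

    elif archetype == "unresectable_phase2b":
        pattern = _pick(rng, UNRESECTABLE_PATTERNS)
        for unit in ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII"):
            data[f"segment_{unit}"] = unit in pattern
        expected = ExpectedOutcome(archetype, "excluded_red", "phase2b", "red")

    elif archetype == "risk_red_phase2b":
        choice = _pick(rng, ["child_c", "steatosis3", "no_icu"])
        if choice == "child_c":
            data["child"] = "C"
        elif choice == "steatosis3":
            pattern, rule_id, category = _pick(
                rng, [p for p in RESECTABLE_PATTERNS
                      if p[2] in ("intermediate", "major")])
            for unit in ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII"):
                data[f"segment_{unit}"] = unit in pattern
            data["steatosis_grade"] = 3
        else:
            pattern, rule_id, category = _pick(
                rng, [p for p in RESECTABLE_PATTERNS if p[2] == "major"])
            for unit in ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII"):
                data[f"segment_{unit}"] = unit in pattern
            data["icu_available"] = False
        expected = ExpectedOutcome(archetype, "excluded_red", "phase2b", "red")

    elif archetype == "red_phase3":
        choice = _pick(rng, ["nyha4", "gold4", "asa5", "child_b_minor",
                             "reconstruction_infeasible", "surgeon_unqualified"])
        if choice == "nyha4":
            data["nyha"] = 4
        elif choice == "gold4":
            data["gold"] = 4
        elif choice == "asa5":
            data["asa_class"] = 5
        elif choice == "child_b_minor":
            # Child B passes the resection-risk layer for a minor resection
            # but is red at feasibility (documented inconsistency).
            pattern, rule_id, category = _pick(
                rng, [p for p in RESECTABLE_PATTERNS if p[2] == "minor"])
            for unit in ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII"):
                data[f"segment_{unit}"] = unit in pattern
            data["child"] = "B"
        elif choice == "reconstruction_infeasible":
            data["vascular_involvement"] = True
            data["reconstruction_feasible"] = False
        else:
            data["vascular_involvement"] = True
            data["surgeon_reconstruction_capable"] = False
        expected = ExpectedOutcome(archetype, "excluded_red", "phase3", "red")

    elif archetype == "orange_phase3":
        data.update(_pick(rng, [
            {"acute_cholangitis": True},
            {"hemoglobin": u(4.0, 6.8)},
            {"wbc": u(10500, 19000)},
        ]))
        expected = ExpectedOutcome(archetype, "parked_orange", "phase3", "orange")

    else:  # pragma: no cover
        raise AssertionError(archetype)

    return PatientRecord(**data), expected


def _archetype_counts(profile: CohortProfile) -> dict[str, int]:
    """Largest-remainder apportionment of n over the mix proportions."""
    quotas = {a: profile.n * p for a, p in profile.mix.items()}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    remainder = profile.n - sum(counts.values())
    by_fraction = sorted(quotas, key=lambda a: (-(quotas[a] - counts[a]), a))
    for a in by_fraction[:remainder]:
        counts[a] += 1
    return counts


def generate_cohort(profile: CohortProfile,
                    ) -> tuple[list[PatientRecord], list[ExpectedOutcome]]:
    """n records with per-record constructed truth; deterministic under seed."""
    counts = _archetype_counts(profile)
    seeder = np.random.default_rng(profile.seed)
    records: list[PatientRecord] = []
    outcomes: list[ExpectedOutcome] = []
    for archetype in ARCHETYPES:
        for _ in range(counts.get(archetype, 0)):
            seed = int(seeder.integers(0, 2**31 - 1))
            record, expected = generate_patient(archetype, seed, profile.noise)
            records.append(record)
            outcomes.append(expected)
    return records, outcomes
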