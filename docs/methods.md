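# Methods

## Model

The package implements a rule matrix, not a learned model: a fixed set of
clinical parameters, each typed (nominal / ordinal / continuous / discrete)
with a valid range and, per decision phase, a threshold-to-light mapping.
Four lights form a total severity order — green (proceed), yellow (proceed
with warning; the flag joins a cumulative ledger used for risk
stratification), orange (temporary exclusion with re-entry), red (permanent
exclusion from this matrix, with a destination note such as the palliative
pathway). Orange sits **below** red: when both fire in one phase, permanent
exclusion subsumes temporary exclusion, so the patient is excluded, not
parked.

Phases run strictly in order (diagnosis → staging/modality → resection
planning + risk → feasibility → prognosis). Within a phase *all* bound
parameters are evaluated before the stop decision, so an exclusion always
carries the complete reason list; stopping applies between phases. A parked
patient re-enters only from phase 1 on a fresh record snapshot — tumor
biology is dynamic, so no cached phase result is ever reused — with all prior
runs retained in the decision trace for audit. The engine performs no
staleness or time-window checks on re-entry; how long resolution may take is
an advisory clinical matter outside the model.

### Assumptions

* Complete workups: a phase that needs a diagnostic marked `not_done` raises
  an incomplete-workup error rather than guessing (CT is mandatory in
  phase 1; histopathology and endoscopy may individually be `not_done`).
* Records are single-timepoint snapshots; no longitudinal reasoning.
* Units follow the rules document verbatim (bilirubin in µmol/L, albumin in
  g/L, CEA in ng/L — the CEA unit is carried as configured even though
  clinical practice usually uses ng/mL; deployments can re-map the unit
  string and threshold in the config without code changes).

## Parameter registry and defaults

All 45 parameters, every threshold, the 18 procedure patterns, the
resection-risk table, the ALBI boundaries and the prognosis weights live in
one YAML document (`src/medmax/data/default_rules.yaml`). Each entry carries
a provenance note in one of three classes:

* **printed threshold** — stated numerically in the underlying evidence
  (CEA > 14.4 ng/L and CA 19-9 > 1000 U/mL staging warnings; age ≥ 75 y;
  BMI ≥ 40 kg/m²; Hb < 7 g/dL and WBC > 10,000/µL orange triggers; the
  NYHA/GOLD/Child/ASA red-yellow grades; the Child/steatosis/ICU risk
  table; ALBI grade bounds −2.60 / −1.39). Operators are applied literally:
  thresholds written with ">" or "<" are strict, "≥" is inclusive.
* **common laboratory reference limit** — the condition is named without a
  number; defaults: thrombocytopenia < 150·10⁹/L, hyperbilirubinemia
  > 21 µmol/L, prolonged PTT > 40 s, reduced GFR < 30 mL/min/1.73 m² (CKD
  stages 4–5), insufficient residual liver volume < 0.30 of total.
* **figure-derived, configurable** — the phase-1 diagnostic lab bands
  (AP/GGT/albumin/CA 19-9/CEA high-favorable; GOT/GPT/bilirubin/AFP
  low-favorable) are only depicted graphically in the source material, so the
  defaults are conventional upper/lower limits of normal arranged as three
  ordered intervals (favorable / borderline / unfavorable-but-not-
  exclusionary, never worse than yellow). They are explicitly meant to be
  swapped per site.

Band mappings use an ordered-breakpoint format: each band declares only its
upper edge and that edge's inclusivity, the next band starts at the
complementary edge, and the last band runs to the top of the valid range.
A partition of the valid range (total coverage, no overlap) therefore holds
by construction; out-of-order breakpoints are rejected at load time, as are
level maps that do not cover every enumerated level, parameters bound to no
phase, and prognosis weights naming unknown parameters.

The ALBI score is `0.66·log10(bilirubin) − 0.085·albumin`; the printed grade
bounds are garbled in the source text, so the standard convention is used
(grade 1 ≤ −2.60; grade 2 in (−2.60, −1.39]; grade 3 > −1.39), with both
boundaries exposed as config constants.

## Resection planner

The 18 location-permutation rules pair each of 9 procedures (9
segmentectomies share one name; bisegmentectomy VI/VII and II/III; right and
left hemihepatectomy; right, left and central mesohepatectomy; extended
right and left hepatectomy) with a pattern clause: a conjunction of
required-involvement disjunction groups plus "all other segments are free",
interpreted as containment (every involved unit lies inside the procedure's
resected set). IVa and IVb are distinct planning units but collapse onto
classical Couinaud segment IV for segment counts; both extended procedures
resect ≥ 5 classical segments. The left mesohepatectomy resects {IVa, IVb}
(the source text prints "IVa and IV", presumed a typo, noted here rather
than silently corrected). Caudate (segment I) membership follows the printed
"(IVa or IVb or I)" clauses; classical texts vary.

The traffic-light model is modified in this phase: a non-fitting pattern is
not an exclusion. All 18 rules are evaluated (the full truth table is kept in
the plan and printed by `medmax explain`), and only if none fits is the
patient red. Among fitting rules the **minimal-extent** one is selected —
fewest resected units, ties broken by category (minor < intermediate <
major) then name — minimal parenchymal sacrifice being the standard surgical
principle where the source asks only for "a suitable permutation".

Two properties of these printed clauses are worth knowing:

* Resectability is *not* monotone in involvement. Required groups mean extra
  involvement can destroy a fit ({IVa, IVb} fits the left mesohepatectomy;
  {I, IVa, IVb} fits nothing) and can create one ({I, IVa} fits nothing;
  {I, IVa, II} fits the left hemihepatectomy). What always holds, and is
  tested exhaustively, is that a *selected* resection never strictly shrinks
  when involvement grows, and every selected plan satisfies containment (the
  formal R0-potential proxy).
* Combinations of procedures (e.g. hemihepatectomy plus contralateral
  segmentectomy) are not modeled, so some multifocal bilobar involvements
  that a tumor board might operate are classified inoperable — a documented
  conservatism of the underlying matrix. Atypical/non-anatomical resections
  are excluded for the same reason.

The risk layer gates the selected category: Child C is red for any
resection; Child B is green for minor, yellow for intermediate and — a
conservative completion of the printed escalation, logged into the trace's
assumptions whenever triggered — red for major. Steatosis grade 3 (≥ 66 %
fat) is red for major/intermediate and yellow for minor; grade 2 (33–66 %)
yellow for major/intermediate; grade 1 green. Without adequate ICU, minor is
green, intermediate yellow, major red.

The Child grade is deliberately evaluated **twice** with different
stringency: the planning layer tolerates Child B for minor resections while
the feasibility phase marks Child B red. A Child B patient with a minor plan
therefore passes phase 2b and is excluded at phase 3; the trace surfaces
this as a documented inconsistency of the source rules rather than silently
harmonizing them. Similarly, Child A is green at planning but yellow at
feasibility — read as intentional escalation of caution.

## Feasibility and prognosis

Phase 3 screens condition grades (NYHA IV / GOLD IV / Child B–C / ASA V red;
NYHA III / GOLD III / Child A / ASA IV yellow; acute cholangitis orange),
labs (anemia and leukocytosis orange; thrombocytopenia, hyperbilirubinemia,
prolonged PTT, reduced GFR yellow), baseline (age, BMI yellow only), imaging
(ascites, steatosis ≥ 2, portal hypertension, insufficient RLV yellow), and
a combined surgeon rule: when major vascular involvement requires
reconstruction, infeasibility or a surgeon lacking the expertise is red; a
qualified surgeon with a feasible reconstruction leaves a yellow
heightened-risk flag. Lack of ICU support is a yellow facility flag. Orange
arises from exactly three sources (cholangitis, Hb < 7, WBC > 10,000) —
verified by sweeping everything else to its worst band.

Phase 4 is a transparent, fully configuration-driven scorer and **not** the
original tumor board's calibrated survival model (those factor cut-offs are
not recoverable): score = 1.0 × (yellow flags from phases 1–3) + weighted
contributions from the prognosis-bound factors (CA 19-9 > 500 U/mL, nodal
involvement, multifocality, size > 5 cm, vascular involvement, ALBI grade
≥ 2 at weight 1.0; CRP > 10 mg/L and direct bilirubin > 8 µmol/L at 0.5; sex
carried at weight 0). Two boundaries (1.0, 4.0) map the score onto
favorable / intermediate / unfavorable strata. The interface (trace + record
→ stratum) is fixed so a calibrated table can be dropped in via config; the
prognosis never alters the treatment recommendation fixed upstream.

## Synthetic cohort generator

Real tumor-board records are not distributable, so the generator emulates
them with eight outcome archetypes (clean pass, yellow pass, and red/orange
terminations at each phase), each forcing exactly the triggers of its
outcome while sampling every other parameter **strictly inside the interior
of its favorable band** (open intervals; the `noise` setting shrinks the
sampled interior further but never widens it). Truth labels are therefore
correct by construction: boundary behavior is never sampled, only tested by
deterministic sweeps. Resectable involvement patterns come from a
hand-verified table pairing each pattern with the procedure the
minimal-extent rule must select; unresectable patterns from a hand-verified
uncoverable list. Cohorts are reproducible byte-for-byte under a seed
(largest-remainder apportionment of the archetype mix, per-record seeds
drawn from one seeded generator).

What the generator does **not** emulate: population-calibrated ihCC
epidemiology (marginals are test-oriented), correlated laboratory physiology
(e.g. a low GFR may coexist with a low CKD stage), missing-data patterns, or
free-text findings. Passing cohort tests therefore demonstrates that the
engine recovers constructed labels under the stated rules — the synthetic
analogue of a tumor-board concordance study — not clinical accuracy on real
patients.

## Numerical and design choices

* Empty light collections combine to green; light combination is max-severity
  (idempotent, commutative, monotone).
* Structural unreadability (wrong types, malformed files) is a distinct
  error from out-of-range values; range/level violations are aggregated per
  file as validation findings naming field, value and violated bound. A
  record with no involved segment is a validation finding (the planner's
  precondition), not a crash.
* CT "unclear" maps to yellow, mirroring the histopathology convention for
  ambiguous findings (the source specifies only green and red CT outcomes).
* Categorical record fields are plain strings validated against the
  registry's enumerated levels, so an invalid level (Child "D") is reported
  as a finding naming the allowed levels rather than a parse failure.
* CSV projections write floats with `%.17g` and read with round-trip
  precision, so record → CSV → record is exact; JSON trace reports use
  sorted keys and contain no timestamps, so identical inputs give
  byte-identical reports.
* Problem sizes in the test suite: all 511 non-empty involvement patterns
  against an independently re-derived brute-force oracle; 10,000 seeded
  record pairs for severity monotonicity under single-parameter degradation
  (bases drawn from the pass archetypes, where monotonicity is well-defined;
  see the planner note above); a 1,000-record uniform-mix cohort for label
  recovery; boundary sweeps on 0.1-unit (CEA, Hb) and integer (CA 19-9, WBC)
  grids.

## Known limitations

* Phase-1 diagnostic lab bands are site defaults, not evidence-derived
  cut-offs; diagnosis-phase behavior between the favorable and borderline
  bands is configuration, not science.
* The prognosis scorer is uncalibrated by design (see above).
* No multi-procedure plans, no volumetric R0/remnant simulation, no
  portal-vein embolization or two-stage strategies, no TNM T-substaging
  (only the N/M components the rules consume), no HL7/FHIR ingestion.
* The matrix models one indication (ihCC); red exits record a destination
  ("another matrix", "palliative matrix") as text only — no routing exists.
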