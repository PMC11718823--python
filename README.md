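# medmax — a multiphasic traffic-light decision matrix for ihCC surgery

`medmax` is a declarative, auditable rule engine for preoperative
decision-making in **intrahepatic cholangiocarcinoma (ihCC)**, a primary
liver cancer for which resection is the only curative option. It re-creates,
as testable software, the kind of multiphasic evidential decision matrix a
hepatobiliary tumor board works through: every clinical factor is screened
against externalized thresholds under a four-level traffic-light semantics,
and the full reasoning path is preserved as an audit trace.

It is written for surgical-oncology researchers and clinical-informatics
engineers who need a transparent (non-black-box) baseline decision model
that can be recalibrated per site by editing a single rules document — not
for clinical use.

## The model

A patient record (45 preoperative factors: demographics, comorbidity grades,
laboratory values, tumor markers, imaging, histopathology, a 9-way Couinaud
segment-involvement vector, surgeon/facility context) passes through four
sequential phases:

1. **Diagnosis** — confirm or rule out suspected ihCC from history, nine
   diagnostic labs and three procedures (histopathology, endoscopy, CT).
   Only a procedure finding of a *different* tumor entity is exclusionary.
2. **Staging / modality (phase 2a)** — distant or peritoneal metastases are
   red (systemic/palliative pathway); very high markers (CEA > 14.4 ng/L,
   CA 19-9 > 1000 U/mL) or nodal involvement are yellow warnings.
3. **Resection planning (phase 2b)** — the involvement vector is matched
   against 18 location-permutation rules over 9 anatomical procedures
   (segmentectomy … extended hepatectomy, 3 extent categories); the
   minimal-extent fitting resection is selected, then gated on Child–Pugh
   grade, steatosis grade and ICU availability. No fitting permutation means
   no R0 potential: red.
4. **Feasibility (phase 3)** — patient condition (NYHA, GOLD, Child, ASA,
   CKD), labs, age/BMI, imaging, surgeon capability and facility are
   screened; **phase 4** then emits a configurable prognosis stratum for
   completed evaluations.

Lights are totally ordered `green < yellow < orange < red`: yellow flags
accumulate in a cumulative ledger, red permanently excludes (with a
destination note), and **orange parks** the patient — a temporary exclusion
(acute cholangitis, Hb < 7 g/dL, leukocytosis > 10,000/µL) after which the
matrix must be restarted from phase 1 on a fresh record. The liver-function
screen uses the albumin–bilirubin score

```
ALBI = 0.66 · log10(bilirubin [µmol/L]) − 0.085 · albumin [g/L]
```

with grade 1 ≤ −2.60 < grade 2 ≤ −1.39 < grade 3.

Every threshold lives in `src/medmax/data/default_rules.yaml` with a
provenance note; `medmax dump-rules` prints the effective configuration.

## Worked example

```python
from medmax import default_registry, generate_patient, run_matrix
from medmax.io import render_trace_table

registry = default_registry()
record, expected = generate_patient("yellow_pass", 11)  # synthetic patient
trace = run_matrix(record, registry)
print(render_trace_table(trace))
```

prints (abridged):

```
patient: yellow_pass-11
run 1:
  phase1: green
  phase2a: green
  phase2b: green
    -> procedure: bisegmentectomy (minor)
  phase3: yellow
    ! yellow: nyha — NYHA heart failure stage = 3 is yellow in phase3
    ! yellow: gold — GOLD COPD stage = 3 is yellow in phase3
  phase4: yellow
    ! yellow: ca19_9 — CA 19-9 = 634.2083224619802 U/mL is yellow in phase4
final state: completed at phase4 (run 1)
recommendation: {"category": "minor", "kind": "surgery",
                 "procedure": "bisegmentectomy",
                 "prognosis_stratum": "intermediate",
                 "rule_id": "bisegmentectomy_II_III"}
prognosis: intermediate (score 3)
```

The synthetic patient's tumor involves Couinaud segments II and III only, so
the planner selects the smallest resection whose pattern fits
(bisegmentectomy II/III). Moderate heart failure (NYHA III) and COPD
(GOLD III) warn but do not exclude, and together with the elevated CA 19-9
they push the default prognosis score to 3 — the intermediate stratum.
Replace the record with a metastatic one and the trace ends red at phase 2a;
give it Hb 6.5 g/dL and it parks orange at phase 3 until re-entry via
`resolve_and_reenter`.

The same is available from the shell:

```bash
medmax cohort --n 100 --seed 1          # synthetic cohort + truth table
medmax evaluate -i cohort_records.csv -o reports/ --format table
medmax explain -i patient.json          # planner pattern truth table
medmax dump-rules                       # effective thresholds for audit
```

Exit codes encode the outcome (0 completed, 3 red exclusion, 4 orange park,
5 validation failure).

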