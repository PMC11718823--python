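"""Per-phase rule behavior: diagnosis, staging, feasibility, prognosis."""

import itertools

import pytest

from medmax import (
    IncompleteWorkupError,
    SequencingError,
    TrafficLight,
    assess_baseline,
    assess_condition,
    assess_history,
    assess_labs_phase1,
    assess_labs_phase3,
    assess_metastasis,
    assess_procedures,
    assess_surgeon_facility,
    assess_tumor_burden,
    predict_prognosis,
    run_phase1,
    run_phase2a,
    run_phase3,
)
from medmax.phase1 import PHASE1_LABS

G, Y, O, R = (TrafficLight.GREEN, TrafficLight.YELLOW, TrafficLight.ORANGE,
              TrafficLight.RED)


class TestPhase1:
    def test_negative_history_is_green(self, registry):
        lights = assess_history(False, False, "none", registry)
        assert set(lights.values()) == {G}

    def test_present_conditions_are_yellow_never_red(self, registry):
        lights = assess_history(True, True, "A", registry)
        assert set(lights.values()) == {Y}
        assert assess_history(True, False, "none", registry)["hepatitis_b"] == Y

    def test_lab_directionality(self, registry, favorable_record):
        values = {p: getattr(favorable_record, p) for p in PHASE1_LABS}
        assert set(assess_labs_phase1(values, registry).values()) == {G}
        # low AFP favors the diagnosis; borderline CA 19-9 warns
        assert assess_labs_phase1({**values, "afp": 2}, registry)["afp"] == G
        assert assess_labs_phase1({**values, "ca19_9": 50},
                                  registry)["ca19_9"] == Y

    def test_missing_lab_signals_incomplete_workup(self, registry,
                                                   favorable_record):
        values = {p: getattr(favorable_record, p) for p in PHASE1_LABS[:-1]}
        with pytest.raises(IncompleteWorkupError):
            assess_labs_phase1(values, registry)

    @pytest.mark.parametrize("histo,endo,ct,expected", [
        ("ihcc", False, "ihcc_consistent", {"histopathology": G,
         "endoscopy_primary_tumor_found": G, "ct_category": G}),
        ("unclear_or_mixed", False, "ihcc_consistent",
         {"histopathology": Y}),
        ("ihcc", True, "ihcc_consistent",
         {"endoscopy_primary_tumor_found": R}),
        ("ihcc", False, "other_tumor", {"ct_category": R}),
        ("ihcc", False, "unclear", {"ct_category": Y}),
    ])
    def test_procedure_rules(self, registry, histo, endo, ct, expected):
        lights = assess_procedures(histo, endo, ct, registry)
        for key, light in expected.items():
            assert lights[key] == light

    def test_ct_not_done_is_insufficient_workup(self, registry):
        with pytest.raises(IncompleteWorkupError):
            assess_procedures("ihcc", False, "not_done", registry)
        with pytest.raises(IncompleteWorkupError):
            assess_procedures("not_done", "not_done", "not_done", registry)

    def test_red_only_from_procedures_never_history_or_labs(
            self, registry, make_record):
        # push every history item and lab to its worst band: still passes
        record = make_record(
            hepatitis_b=True, hepatitis_c=True, child="C",
            ap=1, ggt=1, albumin=6, ca19_9=1, cea=0.1,
            got=2000, gpt=2000, total_bilirubin=500, afp=500000)
        result = run_phase1(record, registry)
        assert result.overall_light == Y
        assert len(result.flags) == 12  # 3 history + 9 labs

    def test_red_exit_records_destination(self, registry, make_record):
        result = run_phase1(make_record(ct_category="other_tumor"), registry)
        assert result.overall_light == R
        assert "another matrix" in result.payload["destination"]

    def test_history_flip_never_lowers_severity(self, registry, make_record):
        base = run_phase1(make_record(), registry).overall_light
        for field in ("hepatitis_b", "hepatitis_c"):
            flipped = run_phase1(make_record(**{field: True}), registry)
            assert flipped.overall_light >= base


class TestPhase2a:
    @pytest.mark.parametrize("distant,peritoneal,expected", [
        (False, False, G), (True, False, R), (False, True, R), (True, True, R),
    ])
    def test_metastasis_rule(self, registry, distant, peritoneal, expected):
        assert assess_metastasis(distant, peritoneal, registry) == expected

    @pytest.mark.parametrize("cea,ca199,nodes,expected", [
        (14.4, 1000, False, {"cea": G, "ca19_9": G, "regional_lymph_nodes": G}),
        (14.5, 999, True, {"cea": Y, "ca19_9": G, "regional_lymph_nodes": Y}),
        (0, 0, False, {"cea": G, "ca19_9": G, "regional_lymph_nodes": G}),
        (0, 1001, False, {"cea": G, "ca19_9": Y, "regional_lymph_nodes": G}),
    ])
    def test_tumor_burden_independent_flags(self, registry, cea, ca199, nodes,
                                            expected):
        assert assess_tumor_burden(cea, ca199, nodes, registry) == expected

    def test_marker_grid_around_thresholds(self, registry):
        """2-D sweep: flags partition exactly at (14.4, 1000)."""
        for cea in (14.2, 14.3, 14.4, 14.5, 14.6):
            for ca in (998, 999, 1000, 1001, 1002):
                lights = assess_tumor_burden(cea, ca, False, registry)
                assert lights["cea"] == (Y if cea > 14.4 else G)
                assert lights["ca19_9"] == (Y if ca > 1000 else G)

    def test_red_terminal_vs_yellow_proceeds(self, registry, make_record):
        red = run_phase2a(make_record(distant_metastasis=True), registry)
        assert red.overall_light == R
        assert "palliative" in red.payload["destination"]
        node = run_phase2a(make_record(regional_lymph_nodes=True), registry)
        assert node.overall_light == Y
        assert node.payload["modality"] == "surgery candidate"

    def test_phase2a_never_emits_orange(self, registry, make_record):
        for distant, peritoneal, nodes in itertools.product([False, True],
                                                            repeat=3):
            for cea, ca in ((0, 0), (100, 5000)):
                result = run_phase2a(make_record(
                    distant_metastasis=distant,
                    peritoneal_metastasis=peritoneal,
                    regional_lymph_nodes=nodes, cea=cea, ca19_9=ca), registry)
                assert O not in result.lights.values()


class TestPhase3:
    @pytest.mark.parametrize("field,value,expected", [
        ("asa_class", 5, R), ("asa_class", 4, Y),
        ("nyha", 4, R), ("nyha", 3, Y),
        ("gold", 4, R), ("gold", 3, Y),
        ("child", "B", R), ("child", "C", R), ("child", "A", Y),
        ("ckd_stage", 4, Y), ("acute_cholangitis", True, O),
    ])
    def test_condition_rules(self, registry, favorable_record, field, value,
                             expected):
        args = {f: getattr(favorable_record, f)
                for f in ("nyha", "gold", "child", "asa_class", "ckd_stage",
                          "acute_cholangitis")}
        args[field] = value
        lights = assess_condition(registry=registry, **args)
        assert lights[field] == expected

    @pytest.mark.parametrize("field,value,expected", [
        ("hemoglobin", 6.9, O), ("hemoglobin", 7.0, G),
        ("wbc", 12000, O), ("wbc", 10000, G),
        ("platelets", 149, Y), ("total_bilirubin", 22, Y),
        ("ptt", 41, Y), ("gfr", 25, Y), ("gfr", 30, G),
    ])
    def test_lab_rules(self, registry, favorable_record, field, value,
                       expected):
        args = {f: getattr(favorable_record, f)
                for f in ("hemoglobin", "platelets", "wbc", "total_bilirubin",
                          "ptt", "gfr")}
        args[field] = value
        assert assess_labs_phase3(registry=registry, **args)[field] == expected

    @pytest.mark.parametrize("age,bmi,expected", [
        (75, 25, {"age": Y, "bmi": G}),
        (74, 39.9, {"age": G, "bmi": G}),
        (80, 45, {"age": Y, "bmi": Y}),
    ])
    def test_baseline_rules_never_exceed_yellow(self, registry, age, bmi,
                                                expected):
        assert assess_baseline(age, bmi, registry) == expected

    @pytest.mark.parametrize("vascular,feasible,capable,icu,surgeon,facility", [
        (True, False, True, True, R, G),
        (True, True, False, True, R, G),
        (True, True, True, True, Y, G),
        (False, True, True, False, G, Y),
        (False, False, False, True, G, G),  # no reconstruction needed
    ])
    def test_surgeon_facility_rules(self, registry, vascular, feasible,
                                    capable, icu, surgeon, facility):
        got = assess_surgeon_facility(vascular, feasible, capable, icu,
                                      registry)
        assert got == (surgeon, facility)

    def test_orange_arises_only_from_cholangitis_anemia_leukocytosis(
            self, registry, make_record):
        degradations = dict(
            nyha=4, gold=4, child="C", asa_class=5, ckd_stage=5,
            platelets=50, total_bilirubin=100, ptt=80, gfr=10,
            age=90, bmi=60, ascites_grade=3, steatosis_grade=3,
            portal_hypertension=True, rlv_fraction=0.1,
            vascular_involvement=True, reconstruction_feasible=False,
            surgeon_reconstruction_capable=False, icu_available=False)
        result = run_phase3(make_record(**degradations), registry)
        assert O not in result.lights.values()
        assert run_phase3(make_record(acute_cholangitis=True),
                          registry).overall_light == O
        assert run_phase3(make_record(hemoglobin=5), registry).overall_light == O
        assert run_phase3(make_record(wbc=15000), registry).overall_light == O

    def test_red_dominates_orange(self, registry, make_record):
        result = run_phase3(make_record(acute_cholangitis=True, asa_class=5),
                            registry)
        assert result.overall_light == R
        assert "palliative" in result.payload["destination"]

    def test_orange_park_lists_pending_issues(self, registry, make_record):
        result = run_phase3(make_record(acute_cholangitis=True, age=80),
                            registry)
        assert result.overall_light == O
        assert result.payload["pending_issues"] == ["acute_cholangitis"]

    def test_degrading_one_parameter_never_lowers_severity(
            self, registry, make_record):
        base = run_phase3(make_record(), registry).overall_light
        for field, value in [("nyha", 3), ("asa_class", 4), ("age", 80),
                             ("hemoglobin", 5), ("portal_hypertension", True),
                             ("rlv_fraction", 0.2), ("icu_available", False)]:
            assert run_phase3(make_record(**{field: value}),
                              registry).overall_light >= base


class TestPhase4:
    def _results(self, registry, record):
        from medmax import run_phase2a, run_phase2b
        return [run_phase1(record, registry), run_phase2a(record, registry),
                run_phase2b(record, registry), run_phase3(record, registry)]

    def test_zero_flags_scores_zero_lowest_stratum(self, registry,
                                                   favorable_record):
        prognosis = predict_prognosis(
            self._results(registry, favorable_record), favorable_record,
            registry)
        assert prognosis.score == 0
        assert prognosis.stratum == registry.prognosis.strata[0]
        assert prognosis.contributing_flags == []

    def test_yellow_flags_strictly_increase_score(self, registry, make_record):
        base = predict_prognosis(self._results(registry, make_record()),
                                 make_record(), registry)
        record = make_record(hepatitis_b=True)
        bumped = predict_prognosis(self._results(registry, record), record,
                                   registry)
        assert bumped.score > base.score

    def test_monotone_strata_with_equal_weights(self, registry, make_record):
        yellow_fields = [{"hepatitis_b": True}, {"hepatitis_c": True},
                         {"age": 80}, {"bmi": 45}, {"portal_hypertension": True},
                         {"ascites_grade": 1}]
        strata_order = {s: i for i, s in enumerate(registry.prognosis.strata)}
        previous = -1
        for k in range(len(yellow_fields) + 1):
            updates = {}
            for d in yellow_fields[:k]:
                updates.update(d)
            record = make_record(**updates)
            prognosis = predict_prognosis(self._results(registry, record),
                                          record, registry)
            assert strata_order[prognosis.stratum] >= previous <= 2
            previous = strata_order[prognosis.stratum]

    def test_zero_weights_always_lowest_stratum(self, registry, make_record):
        from medmax.registry import PrognosisConfig
        config = PrognosisConfig(
            yellow_flag_weight=0.0,
            factor_weights={k: 0.0 for k in registry.prognosis.factor_weights},
            strata_boundaries=registry.prognosis.strata_boundaries,
            strata=registry.prognosis.strata)
        record = make_record(hepatitis_b=True, age=80, bmi=45)
        prognosis = predict_prognosis(self._results(registry, record), record,
                                      registry, config)
        assert prognosis.score == 0
        assert prognosis.stratum == registry.prognosis.strata[0]

    def test_incomplete_or_stopped_trace_is_a_sequencing_violation(
            self, registry, make_record):
        record = make_record()
        partial = self._results(registry, record)[:2]
        with pytest.raises(SequencingError):
            predict_prognosis(partial, record, registry)
        red_record = make_record(asa_class=5)
        results = self._results(registry, red_record)
        with pytest.raises(SequencingError):
            predict_prognosis(results, red_record, registry)
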