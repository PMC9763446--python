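import math

import numpy as np
import pytest

from causaltext.causal import CausalRecord, CausalTable
from causaltext.tree import (
    ACG_CATEGORIES,
    CHOLESTATIC,
    HEPATOCELLULAR,
    MIXED,
    PatientRecord,
    RScoreRules,
    build_tree,
    classify_pattern,
    concordance,
    exclude_drug_entities,
    load_patients,
    r_score,
    reference_category_assignments,
    reference_causal_table,
    reference_clinical_lexicon,
    reference_clinical_tree,
    save_patients,
    stratify_patient,
)


def make_record(eid, z=3.0, category="disease", adjusted_p=0.001):
    return CausalRecord(
        entity_id=eid, category=category, z=z, p_value=adjusted_p / 2,
        adjusted_p=adjusted_p, mean_do=0.4, mean_not_do=0.25, n_do=60, n_not_do=400,
    )


class TestBuildTree:
    def test_reference_terms_populate_seven_categories(self):
        tree = reference_clinical_tree()
        counts = {c: len(tree.category_map[c]) for c in ACG_CATEGORIES}
        assert counts == {
            "Liver Enzymes": 2,
            "Concomitant diseases": 2,
            "History of other liver disorder": 2,
            "Physical findings": 2,
            "Laboratory results": 1,
            "Symptoms and signs": 4,
            "Clinical outcome": 5,
        }
        # per-category lists ranked by z descending
        assert tree.category_map["Clinical outcome"][0] == "hepatic failure"

    def test_empty_table_empty_tree(self):
        tree = build_tree(CausalTable(records=()), {})
        assert tree.terms() == set()

    def test_unassigned_retained_in_audit_list(self):
        table = CausalTable(records=(make_record("mystery"),))
        tree = build_tree(table, {"mystery": "unassigned"})
        assert tree.terms() == set()
        assert tree.unassigned == ("mystery",)

    def test_unknown_category_error(self):
        table = CausalTable(records=(make_record("fever"),))
        with pytest.raises(ValueError):
            build_tree(table, {"fever": "Vital signs"})

    def test_missing_assignment_error(self):
        table = CausalTable(records=(make_record("fever"),))
        with pytest.raises(ValueError):
            build_tree(table, {})

    def test_conserves_terms(self):
        table = CausalTable(records=(make_record("a"), make_record("b"), make_record("c")))
        tree = build_tree(
            table, {"a": "Physical findings", "b": "unassigned", "c": "Clinical outcome"}
        )
        assert len(tree.terms()) + len(tree.unassigned) == len(table.enriched)


class TestExcludeDrugs:
    @staticmethod
    def table_with_drugs():
        records = tuple(make_record(f"term{k}") for k in range(20)) + tuple(
            make_record(d, category="drug") for d in ("iron", "isoniazid", "rifampin", "acetaminophen")
        )
        return CausalTable(records=records)

    def test_twenty_of_twenty_four_retained(self):
        table = self.table_with_drugs()
        assert len(table.enriched) == 24
        filtered = exclude_drug_entities(table, {"iron", "isoniazid", "rifampin", "acetaminophen"})
        assert len(filtered.enriched) == 20
        assert len(filtered.records) == 24  # records kept, with reasons

    def test_empty_exclusion_identity(self):
        table = self.table_with_drugs()
        assert exclude_drug_entities(table, set()).enriched_ids() == table.enriched_ids()

    def test_non_enriched_id_warns_noop(self):
        table = self.table_with_drugs()
        with pytest.warns(UserWarning):
            filtered = exclude_drug_entities(table, {"not-a-term"})
        assert filtered.enriched_ids() == table.enriched_ids()


class TestRScore:
    @pytest.mark.parametrize("alt, ast, expected", [(300, 50, 6.0), (100, 100, 1.0), (120, 40, 3.0)])
    def test_arithmetic(self, alt, ast, expected):
        assert r_score(alt, ast) == expected

    def test_nonpositive_ast_error(self):
        with pytest.raises(ValueError):
            r_score(100, 0)


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (6.0, HEPATOCELLULAR),
            (5.1, HEPATOCELLULAR),
            (1.0, CHOLESTATIC),
            (3.0, MIXED),
            (2.0, MIXED),  # boundary folded into mixed
            (5.0, MIXED),
        ],
    )
    def test_rules(self, r, expected):
        assert classify_pattern(r) == expected

    def test_negative_error(self):
        with pytest.raises(ValueError):
            classify_pattern(-0.1)

    def test_agrees_with_brute_force_on_random_labs(self):
        rng = np.random.default_rng(42)
        alt = rng.uniform(1.0, 2000.0, size=10000)
        ast = rng.uniform(1.0, 500.0, size=10000)
        for a, s in zip(alt, ast):
            r = a / s
            expected = HEPATOCELLULAR if r > 5 else (CHOLESTATIC if r < 2 else MIXED)
            assert classify_pattern(r_score(a, s)) == expected


class TestStratifyPatient:
    def test_direct_rule_application(self):
        tree = reference_clinical_tree()
        lexicon = reference_clinical_lexicon()
        patient = PatientRecord(
            id="p1",
            report_text="The patient progressed to acute liver failure within a week.",
            alt=400.0,
            ast=50.0,
        )
        result = stratify_patient(patient, tree, lexicon)
        assert result.pattern == HEPATOCELLULAR
        assert result.matched_terms["Clinical outcome"] == ("acute liver failure",)
        assert result.severity_bucket == 5

    def test_no_tree_terms_lowest_bucket(self):
        tree = reference_clinical_tree()
        lexicon = reference_clinical_lexicon()
        patient = PatientRecord(id="p2", report_text="Uneventful visit.", alt=100.0, ast=100.0)
        result = stratify_patient(patient, tree, lexicon)
        assert result.matched_terms == {}
        assert result.severity_bucket == 1

    def test_missing_labs_pattern_omitted(self):
        tree = reference_clinical_tree()
        lexicon = reference_clinical_lexicon()
        patient = PatientRecord(id="p3", report_text="Marked jaundice was noted.")
        result = stratify_patient(patient, tree, lexicon)
        assert result.pattern is None and result.r is None
        assert result.severity_bucket == 2

    def test_custom_boundary_rules(self):
        rules = RScoreRules(hepatocellular_above=4.0, cholestatic_below=1.0)
        assert classify_pattern(4.5, rules) == HEPATOCELLULAR
        assert classify_pattern(1.5, rules) == MIXED


class TestConcordance:
    def test_identity(self):
        assert concordance([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_antithetic(self):
        assert concordance([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        # r = cov / (sd_x sd_y) for x=(1,2,3), y=(1,2,4)
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        mx, my = 2.0, 7.0 / 3.0
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / 3
        expected = cov / (math.sqrt(2.0 / 3.0) * math.sqrt(sum((b - my) ** 2 for b in y) / 3))
        assert concordance(x, y) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9820, abs=5e-5)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            concordance([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            concordance([1, 2, 3], [1, 2])


class TestPatientIO:
    def test_jsonl_roundtrip(self, tmp_path):
        patients = [
            PatientRecord(id="p0", report_text="jaundice", alt=120.0, ast=60.0,
                          expert_pattern=MIXED, expert_severity=2),
            PatientRecord(id="p1", report_text="no labs drawn"),
        ]
        path = tmp_path / "patients.jsonl"
        save_patients(patients, path)
        loaded = load_patients(path)
        assert loaded == patients

    def test_nonpositive_lab_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord(id="p", report_text="x", alt=-1.0, ast=10.0)
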