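"""SOP rule engine: evidence, variant, and assertion validation."""

import itertools

import pytest

from varkb.corpus import Corpus
from varkb.models import (
    Assertion,
    EvidenceItem,
    GenomicCoordinates,
    ModerationRecord,
    VariantRecord,
)
from varkb.rules import RULE_CATALOGUE, validate_assertion, validate_evidence_item, validate_variant
from varkb.vocab import DEFAULT_VOCABULARY, EVIDENCE_SIGNIFICANCE, REQUIRED_EVIDENCE_FIELDS

from conftest import make_evidence_item


def rule_ids(violations):
    return [v.rule_id for v in violations]


class TestEvidenceValidation:
    def test_compliant_item_is_clean(self, compliant_item, registries):
        assert validate_evidence_item(compliant_item, registries) == []

    def test_two_drugs_without_interaction_type(self, registries):
        item = make_evidence_item(drugs=["Gefitinib", "Erlotinib"])
        assert rule_ids(validate_evidence_item(item, registries)) == [
            "EID_DRUG_INTERACTION_REQUIRED"
        ]
        item = make_evidence_item(
            drugs=["Gefitinib", "Erlotinib"], drug_interaction_type="Substitutes"
        )
        assert validate_evidence_item(item, registries) == []

    def test_predisposing_significance_must_be_na(self, registries):
        item = make_evidence_item(
            evidence_type="Predisposing",
            clinical_significance="Positive",
            variant_origin="Rare Germline",
            drugs=[],
        )
        assert rule_ids(validate_evidence_item(item, registries)) == [
            "EID_PREDISPOSING_SIGNIFICANCE_NA"
        ]

    @pytest.mark.parametrize("field_name", REQUIRED_EVIDENCE_FIELDS)
    def test_each_required_field_ablation_yields_one_violation(
        self, field_name, registries
    ):
        item = make_evidence_item()
        if field_name == "source_type":
            item.source.source_type = None
        elif field_name == "source_id":
            item.source.source_id = None
        elif field_name == "disease":
            item.disease_doid = None
        else:
            setattr(item, field_name, None)
        missing = [
            v for v in validate_evidence_item(item, registries)
            if v.rule_id == "EID_REQUIRED_FIELD_MISSING"
        ]
        assert len(missing) == 1
        assert field_name in missing[0].message

    def test_removing_k_fields_yields_k_violations(self, registries):
        item = make_evidence_item()
        item.source.source_id = None
        item.variant_origin = None
        item.evidence_rating = None
        missing = [
            v for v in validate_evidence_item(item, registries)
            if v.rule_id == "EID_REQUIRED_FIELD_MISSING"
        ]
        assert len(missing) == 3

    @pytest.mark.parametrize("rating,ok", [(1, True), (5, True), (0, False), (6, False)])
    def test_rating_bounds(self, rating, ok, registries):
        item = make_evidence_item(evidence_rating=rating)
        violations = rule_ids(validate_evidence_item(item, registries))
        assert ("EID_RATING_RANGE" in violations) is not ok

    def test_drugs_on_non_predictive(self, registries):
        item = make_evidence_item(
            evidence_type="Prognostic",
            clinical_significance="Poor Outcome",
        )
        assert rule_ids(validate_evidence_item(item, registries)) == [
            "EID_DRUGS_ON_NON_PREDICTIVE"
        ]

    def test_trade_name_drug_warned(self, registries):
        item = make_evidence_item(drugs=["Iressa"])
        report = validate_evidence_item(item, registries)
        assert rule_ids(report) == ["EID_DRUG_TRADE_NAME"]
        assert report[0].severity == "warning"
        assert "Gefitinib" in report[0].message

    def test_unresolved_disease_and_freetext_fallback(self, registries):
        item = make_evidence_item(disease_doid="DOID:9999999")
        assert rule_ids(validate_evidence_item(item, registries)) == [
            "EID_DISEASE_UNRESOLVED"
        ]
        item = make_evidence_item(
            disease_doid="DOID:9999999", could_not_find_disease=True
        )
        report = validate_evidence_item(item, registries)
        assert rule_ids(report) == ["EID_DISEASE_FREETEXT"]
        assert report[0].severity == "warning"

    def test_multiple_diseases_rejected(self, registries):
        item = make_evidence_item(disease_doid=["DOID:3910", "DOID:1324"])
        assert "EID_MULTI_DISEASE" in rule_ids(validate_evidence_item(item, registries))

    def test_unknown_acmg_code_in_predisposing_statement(self, registries):
        item = make_evidence_item(
            evidence_type="Predisposing",
            clinical_significance="N/A",
            variant_origin="Rare Germline",
            drugs=[],
            evidence_statement="Cosegregation supported PP1 and PS9 in this family.",
        )
        assert rule_ids(validate_evidence_item(item, registries)) == [
            "EID_ACMG_CODE_UNKNOWN"
        ]

    def test_long_statement_is_warning_only(self, registries):
        item = make_evidence_item(
            evidence_statement="One. Two. Three. Four. Five sentences here."
        )
        report = validate_evidence_item(item, registries)
        assert rule_ids(report) == ["EID_STATEMENT_LENGTH"]
        assert report[0].severity == "warning"

    def test_vocabulary_closure_all_and_only(self, registries):
        """Every vocabulary member passes; every outsider is flagged."""
        for etype, options in EVIDENCE_SIGNIFICANCE.items():
            for significance in options:
                item = make_evidence_item(
                    evidence_type=etype,
                    clinical_significance=significance,
                    drugs=["Gefitinib"] if etype == "Predictive" else [],
                    variant_origin="Rare Germline" if etype == "Predisposing" else "Somatic",
                )
                bad = [
                    r for r in rule_ids(validate_evidence_item(item, registries))
                    if r in ("EID_SIGNIFICANCE_VOCAB", "EID_PREDISPOSING_SIGNIFICANCE_NA")
                ]
                assert bad == [], (etype, significance)
            item = make_evidence_item(
                evidence_type=etype,
                clinical_significance="Not A Real Option",
                drugs=["Gefitinib"] if etype == "Predictive" else [],
            )
            report = rule_ids(validate_evidence_item(item, registries))
            assert (
                "EID_SIGNIFICANCE_VOCAB" in report
                or "EID_PREDISPOSING_SIGNIFICANCE_NA" in report
            )

    def test_report_is_deterministic(self, registries):
        item = make_evidence_item(
            drugs=["Iressa", "Unobtainib"], evidence_rating=9, disease_doid="DOID:0"
        )
        first = validate_evidence_item(item, registries)
        second = validate_evidence_item(item, registries)
        assert first == second
        assert first == sorted(first)


def make_variant(**overrides) -> VariantRecord:
    base = dict(
        gene_symbol="EGFR",
        variant_name="L858R",
        variant_types=["SO:0001583"],
        hgvs_expressions=["ENST00000275493.2:c.2573T>G"],
        primary_coordinates=GenomicCoordinates(
            chromosome="7", start=55259515, stop=55259515,
            reference_base="T", variant_base="G",
            representative_transcript="ENST00000275493.2",
        ),
    )
    base.update(overrides)
    return VariantRecord(**base)


class TestVariantValidation:
    def test_single_leaf_type_clean(self, registries):
        assert validate_variant(make_variant(), registries) == []

    def test_ancestor_descendant_types_flagged(self, registries):
        variant = make_variant(variant_types=["SO:0001583", "SO:0001060"])
        assert "VAR_SO_ANCESTRY" in rule_ids(validate_variant(variant, registries))

    def test_sibling_types_allowed(self, registries):
        variant = make_variant(variant_types=["SO:0001583", "SO:0001587"])
        assert validate_variant(variant, registries) == []

    def test_ancestry_detection_matches_transitive_closure_oracle(self, registries):
        so = registries.sequence
        edges = {t: so.get(t).parent_ids for t in so}

        def reachable(start, target):
            stack, seen = list(edges[start]), set()
            while stack:
                node = stack.pop()
                if node == target:
                    return True
                if node not in seen:
                    seen.add(node)
                    stack.extend(edges[node])
            return False

        for a, b in itertools.combinations(sorted(so), 2):
            variant = make_variant(variant_types=[a, b])
            flagged = "VAR_SO_ANCESTRY" in rule_ids(validate_variant(variant, registries))
            assert flagged == (reachable(a, b) or reachable(b, a)), (a, b)

    def test_unversioned_transcript_flagged(self, registries):
        variant = make_variant()
        variant.primary_coordinates.representative_transcript = "ENST00000078429"
        assert rule_ids(validate_variant(variant, registries)) == ["VAR_TX_UNVERSIONED"]
        variant.primary_coordinates.representative_transcript = "ENST00000078429.1"
        assert validate_variant(variant, registries) == []

    def test_secondary_coordinates_require_two_locus_type(self, registries):
        secondary = GenomicCoordinates(chromosome="2", start=100, stop=100,
                                       reference_base="A", variant_base="C")
        variant = make_variant(secondary_coordinates=secondary)
        assert "VAR_SECONDARY_COORDS" in rule_ids(validate_variant(variant, registries))
        fusion = make_variant(
            variant_types=["SO:0001565"], secondary_coordinates=secondary,
            hgvs_expressions=[],
        )
        assert validate_variant(fusion, registries) == []

    def test_malformed_hgvs_warned(self, registries):
        variant = make_variant(hgvs_expressions=["not-hgvs"])
        report = validate_variant(variant, registries)
        assert rule_ids(report) == ["VAR_HGVS_MALFORMED"]
        assert report[0].severity == "warning"


def small_corpus(compliant_item) -> Corpus:
    corpus = Corpus()
    corpus.variants["EGFR:L858R"] = make_variant()
    corpus.evidence_items["EID1"] = compliant_item
    return corpus


def make_assertion(**overrides) -> Assertion:
    base = dict(
        aid="AID1",
        gene_symbol="EGFR",
        variant_name="L858R",
        variant_origin="Somatic",
        disease_doid="DOID:3910",
        assertion_type="Predictive",
        assertion_direction="Supports",
        clinical_significance="Sensitivity/Response",
        drugs=["Gefitinib"],
        amp_tier="I",
        amp_level="A",
        supporting_eids=["EID1"],
        summary="EGFR L858R predicts gefitinib sensitivity in lung adenocarcinoma.",
        moderation=ModerationRecord(state="accepted", submitter_id="curator2",
                                    decided_by="editor1"),
    )
    base.update(overrides)
    return Assertion(**base)


class TestAssertionValidation:
    def test_compliant_assertion_clean(self, compliant_item, registries):
        corpus = small_corpus(compliant_item)
        assert validate_assertion(make_assertion(), corpus, registries) == []

    def test_amp_fields_forbidden_on_predisposing(self, compliant_item, registries):
        corpus = small_corpus(compliant_item)
        assertion = make_assertion(
            assertion_type="Predisposing",
            clinical_significance="Pathogenic",
            drugs=[],
        )
        assert "ASRT_AMP_ON_PREDISPOSING" in rule_ids(
            validate_assertion(assertion, corpus, registries)
        )

    def test_acmg_classification_forbidden_on_somatic(self, compliant_item, registries):
        corpus = small_corpus(compliant_item)
        assertion = make_assertion(acmg_classification="Pathogenic")
        assert "ASRT_ACMG_ON_SOMATIC" in rule_ids(
            validate_assertion(assertion, corpus, registries)
        )

    def test_assertion_without_evidence_flagged(self, registries):
        corpus = Corpus()
        corpus.variants["EGFR:L858R"] = make_variant()
        assertion = make_assertion(supporting_eids=[], moderation=ModerationRecord())
        report = rule_ids(validate_assertion(assertion, corpus, registries))
        assert "ASRT_NO_EVIDENCE" in report

    def test_dangling_evidence_reference_is_violation_not_exception(
        self, compliant_item, registries
    ):
        corpus = small_corpus(compliant_item)
        assertion = make_assertion(supporting_eids=["EID1", "EID404"])
        assert "ASRT_EID_DANGLING" in rule_ids(
            validate_assertion(assertion, corpus, registries)
        )

    def test_accepted_assertion_needs_accepted_evidence(self, registries):
        corpus = Corpus()
        corpus.variants["EGFR:L858R"] = make_variant()
        pending = make_evidence_item(moderation=ModerationRecord(state="submitted"))
        corpus.evidence_items["EID1"] = pending
        assertion = make_assertion()
        assert "ASRT_ACCEPT_GATE" in rule_ids(
            validate_assertion(assertion, corpus, registries)
        )

    def test_tier_level_consistency(self, compliant_item, registries):
        corpus = small_corpus(compliant_item)
        assertion = make_assertion(amp_tier="II", amp_level="A")
        assert "ASRT_AMP_LEVEL_TIER" in rule_ids(
            validate_assertion(assertion, corpus, registries)
        )


def test_rule_catalogue_severities_are_valid():
    assert all(sev in ("error", "warning") for sev, _ in RULE_CATALOGUE.values())
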