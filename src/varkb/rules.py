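"""The SOP validation rule engine.

Validators never raise on bad content: every problem is returned as a
:class:`~varkb.models.Violation` drawn from the documented rule catalogue, so
whole corpora can be triaged in one pass. Reports are deterministic — sorted
by (entity_ref, rule_id).
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

from .models import Assertion, EvidenceItem, VariantRecord, Violation
from .ontology import Registries, SEQUENCE_VARIANT_ROOT
from .vocab import DEFAULT_VOCABULARY, Vocabulary

#: rule_id -> (severity, description). The CLI ``rules`` subcommand dumps this.
RULE_CATALOGUE: dict[str, tuple[str, str]] = {
    "EID_REQUIRED_FIELD_MISSING": ("error", "A universally required evidence-item field is empty."),
    "EID_RATING_RANGE": ("error", "Evidence rating must be an integer from 1 to 5 stars."),
    "EID_TYPE_VOCAB": ("error", "Evidence type is not one of the five supported types."),
    "EID_LEVEL_VOCAB": ("error", "Evidence level is not one of A-E."),
    "EID_DIRECTION_VOCAB": ("error", "Evidence direction must be Supports or Does not support."),
    "EID_ORIGIN_VOCAB": ("error", "Variant origin is not a vocabulary member."),
    "EID_SOURCE_TYPE_VOCAB": ("error", "Source type must be PubMed or ASCO."),
    "EID_SIGNIFICANCE_VOCAB": ("error", "Clinical significance is not valid for the evidence type."),
    "EID_PREDISPOSING_SIGNIFICANCE_NA": ("error", "Predisposing evidence items carry clinical significance N/A."),
    "EID_DRUGS_REQUIRED": ("error", "Predictive evidence items require at least one drug."),
    "EID_DRUGS_ON_NON_PREDICTIVE": ("error", "Only Predictive evidence items may list drugs."),
    "EID_DRUG_INTERACTION_REQUIRED": ("error", "More than one drug requires a drug interaction type."),
    "EID_DRUG_INTERACTION_UNEXPECTED": ("error", "Drug interaction type is only meaningful with multiple drugs."),
    "EID_DRUG_INTERACTION_VOCAB": ("error", "Drug interaction type must be Combination, Sequential, or Substitutes."),
    "EID_DRUG_TRADE_NAME": ("warning", "Trade names should not be used for drugs; use the generic name."),
    "EID_DRUG_UNKNOWN": ("warning", "Drug name not found in the drug term table."),
    "EID_MULTI_DISEASE": ("error", "Exactly one disease may be associated with an evidence item."),
    "EID_DISEASE_UNRESOLVED": ("error", "Disease term does not resolve in the disease ontology."),
    "EID_DISEASE_FREETEXT": ("warning", "Disease recorded as free text (could-not-find-disease fallback)."),
    "EID_PHENOTYPE_UNKNOWN": ("warning", "Associated phenotype not found in the phenotype ontology."),
    "EID_STATEMENT_LENGTH": ("warning", "Evidence statements are typically 1 to 3 sentences."),
    "EID_ACMG_CODE_UNKNOWN": ("error", "Unrecognized ACMG evidence code cited in a Predisposing statement."),
    "VAR_NAME_EMPTY": ("error", "Variant name must be non-empty."),
    "VAR_SO_UNKNOWN": ("error", "Variant type does not resolve in the sequence ontology."),
    "VAR_SO_ANCESTRY": ("error", "Variant types must not be ancestors or descendants of one another."),
    "VAR_SO_NOT_SEQUENCE_VARIANT": ("warning", "Variant type does not descend from the sequence_variant root."),
    "VAR_TX_UNVERSIONED": ("error", "Representative transcript accession must carry a version suffix."),
    "VAR_SECONDARY_COORDS": ("error", "Secondary coordinates are reserved for two-locus structural variants."),
    "VAR_HGVS_MALFORMED": ("warning", "HGVS expression is not well-formed (reference:prefix.change)."),
    "COORD_REF_MISMATCH": ("error", "Reference base does not match the reference sequence."),
    "COORD_INSERTION_SPAN": ("error", "Insertions must span the two flanking bases (stop = start + 1)."),
    "ASRT_NO_EVIDENCE": ("error", "Assertions require a variant with at least one evidence item."),
    "ASRT_EID_DANGLING": ("error", "Supporting evidence reference does not resolve."),
    "ASRT_TYPE_VOCAB": ("error", "Assertion type must be Predictive, Diagnostic, Prognostic, or Predisposing."),
    "ASRT_SIGNIFICANCE_VOCAB": ("error", "Clinical significance is not valid for the assertion type."),
    "ASRT_AMP_ON_PREDISPOSING": ("error", "AMP tier/level apply only to Predictive, Prognostic, or Diagnostic assertions."),
    "ASRT_ACMG_ON_SOMATIC": ("error", "ACMG classification applies only to Predisposing assertions."),
    "ASRT_AMP_LEVEL_TIER": ("error", "AMP level must agree with tier (I: A/B; II: C/D; III/IV: none)."),
    "ASRT_MULTI_DISEASE": ("error", "Exactly one disease may be associated with an assertion."),
    "ASRT_DISEASE_UNRESOLVED": ("warning", "Assertion disease does not resolve in the disease ontology."),
    "ASRT_ACCEPT_GATE": ("error", "An accepted assertion requires at least one accepted supporting evidence item."),
    "ASRT_DRUG_INTERACTION_REQUIRED": ("error", "More than one drug requires a drug interaction type."),
    "GENE_NO_VARIANT": ("error", "A gene record must be associated with at least one variant."),
    "CORPUS_DANGLING_REF": ("error", "Record references an entity absent from the corpus."),
    "CORPUS_DUPLICATE_ID": ("error", "Identifier is not unique within its collection."),
}

ACMG_TOKEN_RE = re.compile(r"\b(?:PVS|PS|PM|PP|BA|BS|BP)\d+\b")
HGVS_RE = re.compile(r"^[^:\s]+:[cgnmpr]\.\S+$")
VERSIONED_TX_RE = re.compile(r"^\S+\.\d+$")

_SENTENCE_LIMIT = 3


def make_violation(rule_id: str, entity_ref: str, message: str = "") -> Violation:
    severity, description = RULE_CATALOGUE[rule_id]
    return Violation(
        entity_ref=entity_ref,
        rule_id=rule_id,
        severity=severity,
        message=message or description,
    )


def _is_missing(value) -> bool:
    return value is None or value == "" or value == []


def sort_report(violations: Iterable[Violation]) -> list[Violation]:
    return sorted(violations)


def _required_field_values(item: EvidenceItem) -> dict[str, object]:
    source = item.source
    disease = item.disease_doid
    if _is_missing(disease) and item.could_not_find_disease:
        disease = item.disease_name or None
    return {
        "gene_symbol": item.gene_symbol,
        "variant_name": item.variant_name,
        "source_type": source.source_type if source else None,
        "source_id": source.source_id if source else None,
        "variant_origin": item.variant_origin,
        "disease": disease,
        "evidence_statement": item.evidence_statement,
        "evidence_type": item.evidence_type,
        "evidence_level": item.evidence_level,
        "evidence_direction": item.evidence_direction,
        "clinical_significance": item.clinical_significance,
        "evidence_rating": item.evidence_rating,
    }


def validate_evidence_item(
    item: EvidenceItem,
    registries: Registries,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
) -> list[Violation]:
    """Return every violated SOP rule for one evidence item."""
    out: list[Violation] = []
    ref = item.eid or item.variant_id

    required = _required_field_values(item)
    for name in vocab.required_evidence_fields:
        if _is_missing(required.get(name)):
            out.append(
                make_violation(
                    "EID_REQUIRED_FIELD_MISSING", ref,
                    f"missing required field: {name}",
                )
            )

    rating = item.evidence_rating
    if rating is not None and (not isinstance(rating, int) or not 1 <= rating <= 5):
        out.append(make_violation("EID_RATING_RANGE", ref, f"rating {rating!r} outside 1-5"))

    etype = item.evidence_type
    type_known = etype in vocab.evidence_types
    if etype is not None and not type_known:
        out.append(make_violation("EID_TYPE_VOCAB", ref, f"unknown evidence type {etype!r}"))
    if item.evidence_level is not None and item.evidence_level not in vocab.evidence_levels:
        out.append(make_violation("EID_LEVEL_VOCAB", ref, f"unknown level {item.evidence_level!r}"))
    if item.evidence_direction is not None and item.evidence_direction not in vocab.evidence_directions:
        out.append(make_violation("EID_DIRECTION_VOCAB", ref, f"unknown direction {item.evidence_direction!r}"))
    if item.variant_origin is not None and item.variant_origin not in vocab.variant_origins:
        out.append(make_violation("EID_ORIGIN_VOCAB", ref, f"unknown origin {item.variant_origin!r}"))
    if item.source and item.source.source_type is not None:
        if item.source.source_type not in vocab.source_types:
            out.append(make_violation("EID_SOURCE_TYPE_VOCAB", ref, f"unknown source type {item.source.source_type!r}"))

    significance = item.clinical_significance
    if type_known and significance is not None:
        allowed = vocab.evidence_significance.get(etype, ())
        if etype == "Predisposing":
            if significance != "N/A":
                out.append(
                    make_violation(
                        "EID_PREDISPOSING_SIGNIFICANCE_NA", ref,
                        f"Predisposing significance must be N/A, got {significance!r}",
                    )
                )
        elif significance not in allowed:
            out.append(
                make_violation(
                    "EID_SIGNIFICANCE_VOCAB", ref,
                    f"{significance!r} not valid for {etype} items",
                )
            )

    if type_known:
        if etype == "Predictive":
            if not item.drugs:
                out.append(make_violation("EID_DRUGS_REQUIRED", ref))
        elif item.drugs:
            out.append(make_violation("EID_DRUGS_ON_NON_PREDICTIVE", ref))
    if len(item.drugs) > 1 and item.drug_interaction_type is None:
        out.append(make_violation("EID_DRUG_INTERACTION_REQUIRED", ref))
    if len(item.drugs) <= 1 and item.drug_interaction_type is not None:
        out.append(make_violation("EID_DRUG_INTERACTION_UNEXPECTED", ref))
    if item.drug_interaction_type is not None and item.drug_interaction_type not in vocab.drug_interaction_types:
        out.append(make_violation("EID_DRUG_INTERACTION_VOCAB", ref, f"unknown interaction type {item.drug_interaction_type!r}"))

    for drug in item.drugs:
        if drug in registries.drug_aliases:
            out.append(
                make_violation(
                    "EID_DRUG_TRADE_NAME", ref,
                    f"{drug!r} is a trade name for {registries.drug_aliases[drug]!r}",
                )
            )
        elif registries.drug.lookup_name(drug) is None and drug not in registries.drug:
            out.append(make_violation("EID_DRUG_UNKNOWN", ref, f"drug {drug!r} not in term table"))

    doid = item.disease_doid
    if isinstance(doid, (list, tuple)):
        if len(doid) > 1:
            out.append(make_violation("EID_MULTI_DISEASE", ref, f"{len(doid)} diseases given"))
        doid = doid[0] if doid else None
    if doid is not None and doid not in registries.disease:
        if item.could_not_find_disease:
            out.append(make_violation("EID_DISEASE_FREETEXT", ref, f"unresolved disease {doid!r} (free-text fallback)"))
        else:
            out.append(make_violation("EID_DISEASE_UNRESOLVED", ref, f"unresolved disease {doid!r}"))
    elif doid is None and item.could_not_find_disease and item.disease_name:
        out.append(make_violation("EID_DISEASE_FREETEXT", ref, f"free-text disease {item.disease_name!r}"))

    for hpo in item.phenotypes:
        if hpo not in registries.phenotype:
            out.append(make_violation("EID_PHENOTYPE_UNKNOWN", ref, f"unknown phenotype {hpo!r}"))

    statement = item.evidence_statement or ""
    sentences = len([s for s in re.split(r"[.!?]+\s*", statement) if s.strip()])
    if sentences > _SENTENCE_LIMIT:
        out.append(make_violation("EID_STATEMENT_LENGTH", ref, f"{sentences} sentences"))
    if etype == "Predisposing":
        from .classification import ACMG_TOKENS

        for token in ACMG_TOKEN_RE.findall(statement):
            if token not in ACMG_TOKENS:
                out.append(make_violation("EID_ACMG_CODE_UNKNOWN", ref, f"unrecognized code {token}"))

    return sort_report(out)


def validate_variant(
    variant: VariantRecord,
    registries: Registries,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
) -> list[Violation]:
    """Return every violated SOP rule for one variant record."""
    out: list[Violation] = []
    ref = variant.variant_id

    if not variant.variant_name:
        out.append(make_violation("VAR_NAME_EMPTY", ref))

    so = registries.sequence
    resolved = [t for t in variant.variant_types if t in so]
    for term in variant.variant_types:
        if term not in so:
            out.append(make_violation("VAR_SO_UNKNOWN", ref, f"unknown type {term!r}"))
        elif term != SEQUENCE_VARIANT_ROOT and SEQUENCE_VARIANT_ROOT in so:
            if not so.is_descendant(term, SEQUENCE_VARIANT_ROOT):
                out.append(make_violation("VAR_SO_NOT_SEQUENCE_VARIANT", ref, f"{term} outside sequence_variant"))
    for i, a in enumerate(resolved):
        for b in resolved[i + 1:]:
            if so.related(a, b):
                out.append(
                    make_violation("VAR_SO_ANCESTRY", ref, f"{a} and {b} are ancestor/descendant")
                )

    for coords in (variant.primary_coordinates, variant.secondary_coordinates):
        if coords and coords.representative_transcript:
            if not VERSIONED_TX_RE.match(coords.representative_transcript):
                out.append(
                    make_violation(
                        "VAR_TX_UNVERSIONED", ref,
                        f"transcript {coords.representative_transcript!r} lacks a version",
                    )
                )

    if variant.secondary_coordinates is not None:
        if not any(t in vocab.two_locus_variant_types for t in variant.variant_types):
            out.append(make_violation("VAR_SECONDARY_COORDS", ref))

    for hgvs in variant.hgvs_expressions:
        if not HGVS_RE.match(hgvs):
            out.append(make_violation("VAR_HGVS_MALFORMED", ref, f"{hgvs!r}"))

    return sort_report(out)


def validate_assertion(
    assertion: Assertion,
    corpus,
    registries: Registries,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
) -> list[Violation]:
    """Return every violated SOP rule for one assertion against its corpus."""
    out: list[Violation] = []
    ref = assertion.aid or assertion.variant_id

    atype = assertion.assertion_type
    type_known = atype in vocab.assertion_types
    if atype is not None and not type_known:
        out.append(make_violation("ASRT_TYPE_VOCAB", ref, f"unknown assertion type {atype!r}"))

    variant = corpus.variants.get(assertion.variant_id) if corpus else None
    evidence_for_variant = (
        corpus.evidence_for_variant(assertion.variant_id) if corpus else []
    )
    if variant is None or not evidence_for_variant:
        out.append(make_violation("ASRT_NO_EVIDENCE", ref))

    accepted_support = 0
    for eid in assertion.supporting_eids:
        item = corpus.evidence_items.get(eid) if corpus else None
        if item is None:
            out.append(make_violation("ASRT_EID_DANGLING", ref, f"unknown evidence item {eid!r}"))
        elif item.moderation.state == "accepted":
            accepted_support += 1

    if type_known and assertion.clinical_significance is not None:
        allowed = vocab.assertion_significance.get(atype, ())
        if assertion.clinical_significance not in allowed:
            out.append(
                make_violation(
                    "ASRT_SIGNIFICANCE_VOCAB", ref,
                    f"{assertion.clinical_significance!r} not valid for {atype} assertions",
                )
            )

    somatic = atype in ("Predictive", "Prognostic", "Diagnostic")
    if atype == "Predisposing" and (assertion.amp_tier or assertion.amp_level):
        out.append(make_violation("ASRT_AMP_ON_PREDISPOSING", ref))
    if somatic and assertion.acmg_classification is not None:
        out.append(make_violation("ASRT_ACMG_ON_SOMATIC", ref))

    tier, level = assertion.amp_tier, assertion.amp_level
    if tier is not None or level is not None:
        ok = (
            (tier == "I" and level in ("A", "B"))
            or (tier == "II" and level in ("C", "D"))
            or (tier in ("III", "IV") and level is None)
        )
        if not ok:
            out.append(make_violation("ASRT_AMP_LEVEL_TIER", ref, f"tier {tier!r} with level {level!r}"))

    doid = assertion.disease_doid
    if isinstance(doid, (list, tuple)):
        if len(doid) > 1:
            out.append(make_violation("ASRT_MULTI_DISEASE", ref, f"{len(doid)} diseases given"))
        doid = doid[0] if doid else None
    if doid is not None and doid not in registries.disease:
        out.append(make_violation("ASRT_DISEASE_UNRESOLVED", ref, f"unresolved disease {doid!r}"))

    if len(assertion.drugs) > 1 and assertion.drug_interaction_type is None:
        out.append(make_violation("ASRT_DRUG_INTERACTION_REQUIRED", ref))

    if assertion.moderation.state == "accepted" and accepted_support == 0:
        out.append(make_violation("ASRT_ACCEPT_GATE", ref))

    return sort_report(out)
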