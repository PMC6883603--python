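"""Controlled vocabularies of the curation knowledge model.

Every enumerated field in the model draws its legal values from here. The
defaults reproduce the published SOP option lists; a deployment can override
any of them from a YAML config so a corrected vocabulary table drops in
without a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

EVIDENCE_TYPES: tuple[str, ...] = (
    "Predictive",
    "Diagnostic",
    "Prognostic",
    "Predisposing",
    "Functional",
)

#: Study-robustness scale: Validated, Clinical, Case study, Preclinical, Inferential.
EVIDENCE_LEVELS: tuple[str, ...] = ("A", "B", "C", "D", "E")

EVIDENCE_DIRECTIONS: tuple[str, ...] = ("Supports", "Does not support")

VARIANT_ORIGINS: tuple[str, ...] = (
    "Somatic",
    "Rare Germline",
    "Common Germline",
    "Unknown",
    "N/A",
)

SOURCE_TYPES: tuple[str, ...] = ("PubMed", "ASCO")

DRUG_INTERACTION_TYPES: tuple[str, ...] = ("Combination", "Sequential", "Substitutes")

#: Clinical-significance options depend on the evidence type. Predisposing
#: evidence defaults to N/A: single studies rarely establish predisposition,
#: which is settled at the assertion level instead.
EVIDENCE_SIGNIFICANCE: dict[str, tuple[str, ...]] = {
    "Predictive": (
        "Sensitivity/Response",
        "Resistance",
        "Reduced Sensitivity",
        "Adverse Response",
        "N/A",
    ),
    "Diagnostic": ("Positive", "Negative"),
    "Prognostic": ("Better Outcome", "Poor Outcome", "N/A"),
    "Predisposing": ("N/A",),
    "Functional": (
        "Gain of Function",
        "Loss of Function",
        "Unaltered Function",
        "Neomorphic",
        "Dominant Negative",
        "Unknown",
    ),
}

ASSERTION_TYPES: tuple[str, ...] = (
    "Predictive",
    "Diagnostic",
    "Prognostic",
    "Predisposing",
)

ACMG_CLASSIFICATIONS: tuple[str, ...] = (
    "Pathogenic",
    "Likely Pathogenic",
    "VUS",
    "Likely Benign",
    "Benign",
)

#: Assertion-level significance. Somatic types reuse the evidence vocabularies
#: extended with benign-side calls (the AMP scheme's Tier IV covers variants
#: judged benign/likely benign, which no evidence-level option expresses);
#: Predisposing assertions carry the germline 5-tier call.
ASSERTION_SIGNIFICANCE: dict[str, tuple[str, ...]] = {
    "Predictive": EVIDENCE_SIGNIFICANCE["Predictive"] + ("Benign", "Likely Benign"),
    "Diagnostic": EVIDENCE_SIGNIFICANCE["Diagnostic"] + ("Benign", "Likely Benign"),
    "Prognostic": EVIDENCE_SIGNIFICANCE["Prognostic"] + ("Benign", "Likely Benign"),
    "Predisposing": ACMG_CLASSIFICATIONS + ("N/A",),
}

BENIGN_SIDE_SIGNIFICANCE: tuple[str, ...] = ("Benign", "Likely Benign")

AMP_TIERS: tuple[str, ...] = ("I", "II", "III", "IV")
AMP_LEVELS: tuple[str, ...] = ("A", "B", "C", "D")

ACTOR_ROLES: tuple[str, ...] = ("Curator", "Editor", "Admin")

MODERATION_STATES: tuple[str, ...] = ("submitted", "accepted", "rejected")

#: The 12 universally required evidence-item fields: the 11 enumerated in the
#: SOP's model figure plus Source ID, without which the claim is uncitable.
REQUIRED_EVIDENCE_FIELDS: tuple[str, ...] = (
    "gene_symbol",
    "variant_name",
    "source_type",
    "source_id",
    "variant_origin",
    "disease",
    "evidence_statement",
    "evidence_type",
    "evidence_level",
    "evidence_direction",
    "clinical_significance",
    "evidence_rating",
)

#: Sequence Ontology terms describing two-locus structural events; only these
#: justify secondary (partner-locus) coordinates on a variant.
TWO_LOCUS_VARIANT_TYPES: tuple[str, ...] = (
    "SO:0001565",  # gene_fusion
    "SO:0001886",  # transcript_fusion
    "SO:0000199",  # translocation
)


@dataclass(frozen=True)
class Vocabulary:
    """Bundle of the controlled option lists, overridable from YAML."""

    evidence_types: Sequence[str] = EVIDENCE_TYPES
    evidence_levels: Sequence[str] = EVIDENCE_LEVELS
    evidence_directions: Sequence[str] = EVIDENCE_DIRECTIONS
    variant_origins: Sequence[str] = VARIANT_ORIGINS
    source_types: Sequence[str] = SOURCE_TYPES
    drug_interaction_types: Sequence[str] = DRUG_INTERACTION_TYPES
    evidence_significance: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(EVIDENCE_SIGNIFICANCE)
    )
    assertion_types: Sequence[str] = ASSERTION_TYPES
    assertion_significance: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(ASSERTION_SIGNIFICANCE)
    )
    acmg_classifications: Sequence[str] = ACMG_CLASSIFICATIONS
    amp_tiers: Sequence[str] = AMP_TIERS
    amp_levels: Sequence[str] = AMP_LEVELS
    required_evidence_fields: Sequence[str] = REQUIRED_EVIDENCE_FIELDS
    two_locus_variant_types: Sequence[str] = TWO_LOCUS_VARIANT_TYPES

    def with_overrides(self, overrides: Mapping[str, object]) -> "Vocabulary":
        known = {f for f in self.__dataclass_fields__}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown vocabulary keys: {sorted(bad)}")
        return replace(self, **{k: v for k, v in overrides.items()})


DEFAULT_VOCABULARY = Vocabulary()


def load_vocabulary(path: str) -> Vocabulary:
    """Load vocabulary overrides from a YAML file (top-level key ``vocabulary``)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    overrides = doc.get("vocabulary", doc)
    return DEFAULT_VOCABULARY.with_overrides(overrides)
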