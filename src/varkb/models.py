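"""Typed records of the four-level curation hierarchy.

Genes have Variants; Variants collect Evidence Items (single literature-derived
clinical claims); accepted Evidence Items are synthesized into disease-specific
Assertions. Records are permissive containers: a field may be missing or
malformed, and the rule engine (:mod:`varkb.rules`) reports every problem as a
:class:`Violation` instead of refusing to construct the record. Unknown input
keys are preserved in ``extras`` for forward compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Optional

NONE_FOUND = "NONE_FOUND"


def _pick(data: dict, known: set[str]) -> dict:
    return {k: v for k, v in data.items() if k not in known}


@dataclass
class SourceRef:
    """A citable evidence source: a PubMed article or an ASCO abstract."""

    source_type: Optional[str] = None
    source_id: Optional[str] = None
    citation: str = ""
    clinical_trial_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "source_type": self.source_type,
            "source_id": self.source_id,
            "citation": self.citation,
            "clinical_trial_ids": list(self.clinical_trial_ids),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SourceRef":
        return cls(
            source_type=data.get("source_type"),
            source_id=data.get("source_id"),
            citation=data.get("citation", ""),
            clinical_trial_ids=list(data.get("clinical_trial_ids", [])),
        )


@dataclass
class GenomicCoordinates:
    """1-based, build-tagged representative coordinates.

    ``reference_base``/``variant_base`` hold trimmed alleles with ``"-"`` for
    the empty side; insertions span the two flanking bases (stop = start + 1).
    """

    chromosome: str = ""
    start: int = 0
    stop: int = 0
    reference_base: str = "-"
    variant_base: str = "-"
    reference_build: str = "GRCh37"
    representative_transcript: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "start": self.start,
            "stop": self.stop,
            "reference_base": self.reference_base,
            "variant_base": self.variant_base,
            "reference_build": self.reference_build,
            "representative_transcript": self.representative_transcript,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GenomicCoordinates":
        return cls(
            chromosome=data.get("chromosome", ""),
            start=int(data.get("start", 0)),
            stop=int(data.get("stop", 0)),
            reference_base=data.get("reference_base", "-"),
            variant_base=data.get("variant_base", "-"),
            reference_build=data.get("reference_build", "GRCh37"),
            representative_transcript=data.get("representative_transcript"),
        )


@dataclass
class Revision:
    """A proposed field change; requires a rationale comment."""

    field_name: str
    old_value: Any
    new_value: Any
    comment: str
    state: str = "submitted"
    proposer_id: str = ""

    def to_dict(self) -> dict:
        return {
            "field_name": self.field_name,
            "old_value": self.old_value,
            "new_value": self.new_value,
            "comment": self.comment,
            "state": self.state,
            "proposer_id": self.proposer_id,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Revision":
        return cls(
            field_name=data.get("field_name", ""),
            old_value=data.get("old_value"),
            new_value=data.get("new_value"),
            comment=data.get("comment", ""),
            state=data.get("state", "submitted"),
            proposer_id=data.get("proposer_id", ""),
        )


@dataclass
class ModerationRecord:
    """Lifecycle state of a curatable entity plus its audit trail."""

    state: str = "submitted"
    flagged: bool = False
    submitter_id: str = ""
    decided_by: Optional[str] = None
    comments: list[dict] = field(default_factory=list)
    revisions: list[Revision] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "state": self.state,
            "flagged": self.flagged,
            "submitter_id": self.submitter_id,
            "decided_by": self.decided_by,
            "comments": [dict(c) for c in self.comments],
            "revisions": [r.to_dict() for r in self.revisions],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModerationRecord":
        return cls(
            state=data.get("state", "submitted"),
            flagged=bool(data.get("flagged", False)),
            submitter_id=data.get("submitter_id", ""),
            decided_by=data.get("decided_by"),
            comments=[dict(c) for c in data.get("comments", [])],
            revisions=[Revision.from_dict(r) for r in data.get("revisions", [])],
        )


@dataclass
class GeneRecord:
    gene_symbol: str = ""
    entrez_id: Optional[int] = None
    summary: str = ""
    summary_sources: list[SourceRef] = field(default_factory=list)
    aliases: list[str] = field(default_factory=list)
    linkouts: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    _KNOWN = {
        "gene_symbol", "entrez_id", "summary", "summary_sources",
        "aliases", "linkouts",
    }

    def to_dict(self) -> dict:
        out = {
            "gene_symbol": self.gene_symbol,
            "entrez_id": self.entrez_id,
            "summary": self.summary,
            "summary_sources": [s.to_dict() for s in self.summary_sources],
            "aliases": list(self.aliases),
            "linkouts": list(self.linkouts),
        }
        out.update(self.extras)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GeneRecord":
        return cls(
            gene_symbol=data.get("gene_symbol", ""),
            entrez_id=data.get("entrez_id"),
            summary=data.get("summary", ""),
            summary_sources=[
                SourceRef.from_dict(s) for s in data.get("summary_sources", [])
            ],
            aliases=list(data.get("aliases", [])),
            linkouts=list(data.get("linkouts", [])),
            extras=_pick(data, cls._KNOWN),
        )


@dataclass
class VariantRecord:
    """A broadly defined variant: a specific allele or a named category."""

    gene_symbol: str = ""
    variant_name: str = ""
    aliases: list[str] = field(default_factory=list)
    summary: str = ""
    summary_sources: list[SourceRef] = field(default_factory=list)
    variant_types: list[str] = field(default_factory=list)
    hgvs_expressions: list[str] = field(default_factory=list)
    clinvar_ids: list = field(default_factory=list)
    primary_coordinates: Optional[GenomicCoordinates] = None
    secondary_coordinates: Optional[GenomicCoordinates] = None
    variant_group_ids: list[str] = field(default_factory=list)
    allele_registry_key: Optional[str] = None
    extras: dict = field(default_factory=dict)

    _KNOWN = {
        "gene_symbol", "variant_name", "aliases", "summary", "summary_sources",
        "variant_types", "hgvs_expressions", "clinvar_ids",
        "primary_coordinates", "secondary_coordinates", "variant_group_ids",
        "allele_registry_key",
    }

    @property
    def variant_id(self) -> str:
        return f"{self.gene_symbol}:{self.variant_name}"

    def to_dict(self) -> dict:
        out = {
            "gene_symbol": self.gene_symbol,
            "variant_name": self.variant_name,
            "aliases": list(self.aliases),
            "summary": self.summary,
            "summary_sources": [s.to_dict() for s in self.summary_sources],
            "variant_types": list(self.variant_types),
            "hgvs_expressions": list(self.hgvs_expressions),
            "clinvar_ids": list(self.clinvar_ids),
            "primary_coordinates": (
                self.primary_coordinates.to_dict() if self.primary_coordinates else None
            ),
            "secondary_coordinates": (
                self.secondary_coordinates.to_dict()
                if self.secondary_coordinates
                else None
            ),
            "variant_group_ids": list(self.variant_group_ids),
            "allele_registry_key": self.allele_registry_key,
        }
        out.update(self.extras)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "VariantRecord":
        primary = data.get("primary_coordinates")
        secondary = data.get("secondary_coordinates")
        return cls(
            gene_symbol=data.get("gene_symbol", ""),
            variant_name=data.get("variant_name", ""),
            aliases=list(data.get("aliases", [])),
            summary=data.get("summary", ""),
            summary_sources=[
                SourceRef.from_dict(s) for s in data.get("summary_sources", [])
            ],
            variant_types=list(data.get("variant_types", [])),
            hgvs_expressions=list(data.get("hgvs_expressions", [])),
            clinvar_ids=list(data.get("clinvar_ids", [])),
            primary_coordinates=(
                GenomicCoordinates.from_dict(primary) if primary else None
            ),
            secondary_coordinates=(
                GenomicCoordinates.from_dict(secondary) if secondary else None
            ),
            variant_group_ids=list(data.get("variant_group_ids", [])),
            allele_registry_key=data.get("allele_registry_key"),
            extras=_pick(data, cls._KNOWN),
        )


@dataclass
class EvidenceItem:
    """One literature-derived clinical claim about a variant.

    Twelve fields are universally required (gene, variant, source type and id,
    variant origin, disease, statement, type, level, direction, significance,
    rating); Predictive items additionally require drugs, and a drug
    interaction type whenever more than one drug is involved.
    """

    eid: str = ""
    gene_symbol: Optional[str] = None
    variant_name: Optional[str] = None
    source: Optional[SourceRef] = None
    variant_origin: Optional[str] = None
    disease_doid: Optional[str] = None
    disease_name: str = ""
    could_not_find_disease: bool = False
    evidence_statement: Optional[str] = None
    evidence_type: Optional[str] = None
    evidence_level: Optional[str] = None
    evidence_direction: Optional[str] = None
    clinical_significance: Optional[str] = None
    evidence_rating: Optional[int] = None
    drugs: list[str] = field(default_factory=list)
    drug_interaction_type: Optional[str] = None
    phenotypes: list[str] = field(default_factory=list)
    submission_comment: str = ""
    moderation: ModerationRecord = field(default_factory=ModerationRecord)
    extras: dict = field(default_factory=dict)

    _KNOWN = {
        "eid", "gene_symbol", "variant_name", "source", "variant_origin",
        "disease_doid", "disease_name", "could_not_find_disease",
        "evidence_statement", "evidence_type", "evidence_level",
        "evidence_direction", "clinical_significance", "evidence_rating",
        "drugs", "drug_interaction_type", "phenotypes", "submission_comment",
        "moderation",
    }

    @property
    def variant_id(self) -> str:
        return f"{self.gene_symbol}:{self.variant_name}"

    def to_dict(self) -> dict:
        out = {
            "eid": self.eid,
            "gene_symbol": self.gene_symbol,
            "variant_name": self.variant_name,
            "source": self.source.to_dict() if self.source else None,
            "variant_origin": self.variant_origin,
            "disease_doid": self.disease_doid,
            "disease_name": self.disease_name,
            "could_not_find_disease": self.could_not_find_disease,
            "evidence_statement": self.evidence_statement,
            "evidence_type": self.evidence_type,
            "evidence_level": self.evidence_level,
            "evidence_direction": self.evidence_direction,
            "clinical_significance": self.clinical_significance,
            "evidence_rating": self.evidence_rating,
            "drugs": list(self.drugs),
            "drug_interaction_type": self.drug_interaction_type,
            "phenotypes": list(self.phenotypes),
            "submission_comment": self.submission_comment,
            "moderation": self.moderation.to_dict(),
        }
        out.update(self.extras)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "EvidenceItem":
        source = data.get("source")
        rating = data.get("evidence_rating")
        moderation = data.get("moderation")
        return cls(
            eid=data.get("eid", ""),
            gene_symbol=data.get("gene_symbol"),
            variant_name=data.get("variant_name"),
            source=SourceRef.from_dict(source) if source else None,
            variant_origin=data.get("variant_origin"),
            disease_doid=data.get("disease_doid"),
            disease_name=data.get("disease_name", ""),
            could_not_find_disease=bool(data.get("could_not_find_disease", False)),
            evidence_statement=data.get("evidence_statement"),
            evidence_type=data.get("evidence_type"),
            evidence_level=data.get("evidence_level"),
            evidence_direction=data.get("evidence_direction"),
            clinical_significance=data.get("clinical_significance"),
            evidence_rating=rating if rating is None else int(rating),
            drugs=list(data.get("drugs", [])),
            drug_interaction_type=data.get("drug_interaction_type"),
            phenotypes=list(data.get("phenotypes", [])),
            submission_comment=data.get("submission_comment", ""),
            moderation=(
                ModerationRecord.from_dict(moderation)
                if moderation
                else ModerationRecord()
            ),
            extras=_pick(data, cls._KNOWN),
        )


@dataclass
class AcmgCode:
    """A germline pathogenicity evidence token, optionally strength-adjusted."""

    token: str
    strength_override: Optional[str] = None

    def to_dict(self) -> dict:
        return {"token": self.token, "strength_override": self.strength_override}

    @classmethod
    def from_dict(cls, data) -> "AcmgCode":
        if isinstance(data, str):
            return cls(token=data)
        return cls(
            token=data.get("token", ""),
            strength_override=data.get("strength_override"),
        )


@dataclass
class Assertion:
    """A disease-specific synthesis of evidence items with a formal call."""

    aid: str = ""
    gene_symbol: Optional[str] = None
    variant_name: Optional[str] = None
    variant_origin: Optional[str] = None
    disease_doid: Optional[str] = None
    assertion_type: Optional[str] = None
    assertion_direction: Optional[str] = None
    clinical_significance: Optional[str] = None
    drugs: list[str] = field(default_factory=list)
    drug_interaction_type: Optional[str] = None
    phenotypes: list[str] = field(default_factory=list)
    amp_tier: Optional[str] = None
    amp_level: Optional[str] = None
    acmg_codes: list[AcmgCode] = field(default_factory=list)
    acmg_classification: Optional[str] = None
    nccn_guideline: Optional[str] = None
    fda_regulatory_approval: bool = False
    fda_companion_test: bool = False
    summary: str = ""
    description: str = ""
    supporting_eids: list[str] = field(default_factory=list)
    moderation: ModerationRecord = field(default_factory=ModerationRecord)
    extras: dict = field(default_factory=dict)

    _KNOWN = {
        "aid", "gene_symbol", "variant_name", "variant_origin", "disease_doid",
        "assertion_type", "assertion_direction", "clinical_significance",
        "drugs", "drug_interaction_type", "phenotypes", "amp_tier", "amp_level",
        "acmg_codes", "acmg_classification", "nccn_guideline",
        "fda_regulatory_approval", "fda_companion_test", "summary",
        "description", "supporting_eids", "moderation",
    }

    @property
    def variant_id(self) -> str:
        return f"{self.gene_symbol}:{self.variant_name}"

    def to_dict(self) -> dict:
        out = {
            "aid": self.aid,
            "gene_symbol": self.gene_symbol,
            "variant_name": self.variant_name,
            "variant_origin": self.variant_origin,
            "disease_doid": self.disease_doid,
            "assertion_type": self.assertion_type,
            "assertion_direction": self.assertion_direction,
            "clinical_significance": self.clinical_significance,
            "drugs": list(self.drugs),
            "drug_interaction_type": self.drug_interaction_type,
            "phenotypes": list(self.phenotypes),
            "amp_tier": self.amp_tier,
            "amp_level": self.amp_level,
            "acmg_codes": [c.to_dict() for c in self.acmg_codes],
            "acmg_classification": self.acmg_classification,
            "nccn_guideline": self.nccn_guideline,
            "fda_regulatory_approval": self.fda_regulatory_approval,
            "fda_companion_test": self.fda_companion_test,
            "summary": self.summary,
            "description": self.description,
            "supporting_eids": list(self.supporting_eids),
            "moderation": self.moderation.to_dict(),
        }
        out.update(self.extras)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "Assertion":
        moderation = data.get("moderation")
        return cls(
            aid=data.get("aid", ""),
            gene_symbol=data.get("gene_symbol"),
            variant_name=data.get("variant_name"),
            variant_origin=data.get("variant_origin"),
            disease_doid=data.get("disease_doid"),
            assertion_type=data.get("assertion_type"),
            assertion_direction=data.get("assertion_direction"),
            clinical_significance=data.get("clinical_significance"),
            drugs=list(data.get("drugs", [])),
            drug_interaction_type=data.get("drug_interaction_type"),
            phenotypes=list(data.get("phenotypes", [])),
            amp_tier=data.get("amp_tier"),
            amp_level=data.get("amp_level"),
            acmg_codes=[AcmgCode.from_dict(c) for c in data.get("acmg_codes", [])],
            acmg_classification=data.get("acmg_classification"),
            nccn_guideline=data.get("nccn_guideline"),
            fda_regulatory_approval=bool(data.get("fda_regulatory_approval", False)),
            fda_companion_test=bool(data.get("fda_companion_test", False)),
            summary=data.get("summary", ""),
            description=data.get("description", ""),
            supporting_eids=list(data.get("supporting_eids", [])),
            moderation=(
                ModerationRecord.from_dict(moderation)
                if moderation
                else ModerationRecord()
            ),
            extras=_pick(data, cls._KNOWN),
        )


@dataclass(frozen=True, order=True)
class Violation:
    """One violated SOP rule on one entity; reports sort by (entity, rule)."""

    entity_ref: str
    rule_id: str
    severity: str = "error"
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "entity_ref": self.entity_ref,
            "rule_id": self.rule_id,
            "severity": self.severity,
            "message": self.message,
        }
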