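import pytest

from varkb.models import EvidenceItem, ModerationRecord, SourceRef
from varkb.coordinates import ReferenceContig
from varkb.ontology import bundled_registries


@pytest.fixture(scope="session")
def registries():
    return bundled_registries()


def make_evidence_item(**overrides) -> EvidenceItem:
    """A fully compliant Predictive evidence item; override fields to break it."""
    base = dict(
        eid="EID1",
        gene_symbol="EGFR",
        variant_name="L858R",
        source=SourceRef(
            source_type="PubMed", source_id="23456789",
            citation="Example et al., 2014",
        ),
        variant_origin="Somatic",
        disease_doid="DOID:3910",
        evidence_statement=(
            "EGFR L858R was associated with sensitivity to gefitinib in a "
            "phase III trial of 230 lung adenocarcinoma patients."
        ),
        evidence_type="Predictive",
        evidence_level="B",
        evidence_direction="Supports",
        clinical_significance="Sensitivity/Response",
        evidence_rating=4,
        drugs=["Gefitinib"],
        drug_interaction_type=None,
        phenotypes=[],
        moderation=ModerationRecord(state="accepted", submitter_id="curator1",
                                    decided_by="editor1"),
    )
    base.update(overrides)
    return EvidenceItem(**base)


@pytest.fixture
def compliant_item() -> EvidenceItem:
    return make_evidence_item()


@pytest.fixture
def homopolymer_contig() -> ReferenceContig:
    # 1-based: G C A T T T A C — the T homopolymer spans positions 4-6
    return ReferenceContig("chr1", "GCATTTAC")
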