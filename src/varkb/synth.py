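"""Seeded synthetic-corpus generation.

The generator emits a referentially intact corpus spanning the whole model —
all five evidence types and levels, both directions, per-type significance
values, multi-drug predictive items, somatic assertions across AMP tiers, and
germline assertions across ACMG outcomes — plus, on request, a controlled
fraction of records carrying exactly one labeled, detectable rule defect each
(ground truth stored on the corpus) for validator recall testing. All
randomness flows from the config seed; repeated runs are identical.

It also provides small random reference contigs and indel fixtures for
exercising coordinate normalization, including homopolymer/dinucleotide
repeats where left-shifting is non-trivial.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classification import assign_amp, combine_acmg
from .coordinates import ReferenceContig
from .corpus import Corpus
from .models import (
    AcmgCode,
    Assertion,
    EvidenceItem,
    GeneRecord,
    GenomicCoordinates,
    ModerationRecord,
    SourceRef,
    VariantRecord,
)
from .ontology import Registries, bundled_registries
from .vocab import DEFAULT_VOCABULARY, Vocabulary

_GENE_POOL = (
    "EGFR", "BRAF", "KRAS", "TP53", "ALK", "ERBB2", "BRCA1", "BRCA2",
    "PIK3CA", "KIT", "ABL1", "MET", "RET", "PTEN", "NRAS", "FLT3",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Leaf-level SO terms safe to combine (no ancestor/descendant pairs among them).
_LEAF_SO_TYPES = (
    "SO:0001583",  # missense_variant
    "SO:0001587",  # stop_gained
    "SO:0001589",  # frameshift_variant
    "SO:0001821",  # inframe_insertion
    "SO:0001822",  # inframe_deletion
)

_CATEGORICAL_NAMES = ("Mutation", "Amplification", "Exon 20 Insertion", "Exon 19 Deletion")

#: ACMG code sets cycled across germline assertions; spans every outcome.
_ACMG_SETS: tuple[tuple[str, ...], ...] = (
    ("PVS1", "PS1"),            # Pathogenic
    ("PS1", "PM1", "PM2"),      # Likely Pathogenic
    ("PM2",),                   # VUS (insufficient)
    ("BS1", "BP1"),             # Likely Benign
    ("BA1",),                   # Benign
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 7
    n_genes: int = 8
    n_variants: int = 25
    n_eids: int = 100
    n_assertions: int = 8
    violation_rate: float = 0.0
    violation_mix: Optional[dict[str, float]] = None
    level_distribution: Optional[dict[str, float]] = None
    rating_distribution: Optional[dict[int, float]] = None

    def __post_init__(self):
        if min(self.n_genes, self.n_variants, self.n_eids, self.n_assertions) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.violation_rate <= 1.0:
            raise ValueError("violation_rate must lie in [0, 1]")


def _weighted_choice(rng: random.Random, dist: dict, default: Sequence):
    if not dist:
        return rng.choice(list(default))
    keys = sorted(dist, key=str)
    return rng.choices(keys, weights=[dist[k] for k in keys], k=1)[0]


def _variant_name(rng: random.Random) -> str:
    if rng.random() < 0.2:
        return rng.choice(_CATEGORICAL_NAMES)
    return f"{rng.choice(_AA)}{rng.randint(10, 990)}{rng.choice(_AA)}"


def _transcript(rng: random.Random) -> str:
    return f"ENST{rng.randint(0, 999999):011d}.{rng.randint(1, 9)}"


def _coordinates(rng: random.Random, transcript: str) -> GenomicCoordinates:
    start = rng.randint(1_000, 200_000_000)
    ref, var = rng.sample("ACGT", 2)
    return GenomicCoordinates(
        chromosome=rng.choice([str(c) for c in range(1, 23)] + ["X"]),
        start=start,
        stop=start,
        reference_base=ref,
        variant_base=var,
        representative_transcript=transcript,
    )


def _statement(rng: random.Random, item: EvidenceItem, disease_label: str) -> str:
    n = rng.randint(8, 120)
    if item.evidence_type == "Predictive" and item.drugs:
        return (
            f"{item.gene_symbol} {item.variant_name} was associated with "
            f"{item.clinical_significance} to {' plus '.join(item.drugs)} in "
            f"{n} patients with {disease_label}."
        )
    if item.evidence_type == "Predisposing":
        codes = rng.sample(["PM2", "PP3", "PS4", "PM1", "PP1"], k=2)
        return (
            f"A {disease_label} pedigree study of {item.gene_symbol} "
            f"{item.variant_name} supported {codes[0]} and {codes[1]}."
        )
    return (
        f"{item.gene_symbol} {item.variant_name} showed "
        f"{item.clinical_significance or 'an effect'} in a cohort of {n} "
        f"{disease_label} cases."
    )


def generate_corpus(
    config: GeneratorConfig,
    registries: Optional[Registries] = None,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
) -> Corpus:
    """Generate a seeded corpus; see the module docstring for coverage."""
    rng = random.Random(config.seed)
    registries = registries or bundled_registries()
    corpus = Corpus()

    diseases = sorted(t for t in registries.disease if t != "DOID:162")
    drugs = sorted(
        registries.drug.get(t).name for t in registries.drug
    )
    phenotypes = sorted(registries.phenotype)

    gene_symbols = list(_GENE_POOL[: config.n_genes])
    for i, symbol in enumerate(gene_symbols):
        corpus.genes[symbol] = GeneRecord(
            gene_symbol=symbol,
            entrez_id=1000 + i,
            summary=f"{symbol} alterations are recurrent drivers in solid and hematologic cancers.",
            aliases=[f"{symbol}-ALT{i}"],
        )

    variant_ids: list[str] = []
    for i in range(config.n_variants):
        gene = gene_symbols[i % len(gene_symbols)] if gene_symbols else f"GENE{i}"
        name = _variant_name(rng)
        vid = f"{gene}:{name}"
        while vid in corpus.variants:
            name = _variant_name(rng)
            vid = f"{gene}:{name}"
        transcript = _transcript(rng)
        fusion = i == 1 and config.n_variants > 1  # one two-locus structural variant
        if fusion:
            name, vid = f"{gene} Fusion", f"{gene}:{gene} Fusion"
            if vid in corpus.variants:
                continue
        types = (
            ["SO:0001565"]
            if fusion
            else sorted(rng.sample(_LEAF_SO_TYPES, k=rng.randint(1, 2)))
        )
        variant = VariantRecord(
            gene_symbol=gene,
            variant_name=name,
            aliases=[f"rs{rng.randint(10**6, 10**8)}"],
            summary=f"{gene} {name} has recurrent clinical evidence in cancer.",
            variant_types=types,
            hgvs_expressions=[f"{transcript}:c.{rng.randint(1, 5000)}{rng.choice('ACGT')}>{rng.choice('ACGT')}"],
            clinvar_ids=[rng.randint(10000, 999999)],
            primary_coordinates=_coordinates(rng, transcript),
            secondary_coordinates=_coordinates(rng, _transcript(rng)) if fusion else None,
        )
        corpus.variants[vid] = variant
        variant_ids.append(vid)

    level_default = vocab.evidence_levels
    rating_default = (1, 2, 3, 4, 5)
    for i in range(config.n_eids):
        vid = variant_ids[i % len(variant_ids)] if variant_ids else "GENE0:X1Y"
        variant = corpus.variants.get(vid)
        gene = variant.gene_symbol if variant else vid.split(":")[0]
        name = variant.variant_name if variant else vid.split(":", 1)[1]
        etype = vocab.evidence_types[i % len(vocab.evidence_types)]
        level = _weighted_choice(rng, config.level_distribution or {}, level_default)
        rating = _weighted_choice(rng, config.rating_distribution or {}, rating_default)
        direction = "Supports" if rng.random() < 0.8 else "Does not support"
        significance = (
            "N/A"
            if etype == "Predisposing"
            else rng.choice(
                [s for s in vocab.evidence_significance[etype] if s != "N/A"]
            )
        )
        doid = rng.choice(diseases)
        item_drugs: list[str] = []
        interaction = None
        if etype == "Predictive":
            item_drugs = sorted(rng.sample(drugs, k=(i // 5) % 3 + 1))
            if len(item_drugs) > 1:
                interaction = rng.choice(list(vocab.drug_interaction_types))
        state = rng.choices(
            ("accepted", "submitted", "rejected"), weights=(0.7, 0.2, 0.1), k=1
        )[0]
        submitter = f"curator{rng.randint(1, 6)}"
        item = EvidenceItem(
            eid=f"EID{i + 1}",
            gene_symbol=gene,
            variant_name=name,
            source=SourceRef(
                source_type="PubMed" if rng.random() < 0.85 else "ASCO",
                source_id=str(rng.randint(10**7, 10**8 - 1)),
                citation=f"Synthetic et al., J Clin Synth {2008 + i % 12}",
            ),
            variant_origin="Rare Germline" if etype == "Predisposing" else "Somatic",
            disease_doid=doid,
            evidence_type=etype,
            evidence_level=level,
            evidence_direction=direction,
            clinical_significance=significance,
            evidence_rating=rating,
            drugs=item_drugs,
            drug_interaction_type=interaction,
            phenotypes=sorted(rng.sample(phenotypes, k=rng.choice((0, 1, 2)))),
            moderation=ModerationRecord(
                state=state,
                submitter_id=submitter,
                decided_by="editor1" if state in ("accepted", "rejected") else None,
            ),
        )
        item.evidence_statement = _statement(
            rng, item, registries.disease.get(doid).name
        )
        corpus.evidence_items[item.eid] = item

    _generate_assertions(rng, corpus, config, vocab)
    if config.violation_rate > 0:
        _inject_defects(rng, corpus, config, registries)
    return corpus


def _generate_assertions(
    rng: random.Random, corpus: Corpus, config: GeneratorConfig, vocab: Vocabulary
) -> None:
    candidates = [
        vid
        for vid in corpus.variants
        if any(
            i.moderation.state == "accepted"
            for i in corpus.evidence_for_variant(vid)
        )
    ]
    for i in range(config.n_assertions):
        if not candidates:
            break
        vid = candidates[i % len(candidates)]
        variant = corpus.variants[vid]
        atype = vocab.assertion_types[i % len(vocab.assertion_types)]
        accepted = [
            e
            for e in corpus.evidence_for_variant(vid)
            if e.moderation.state == "accepted"
        ]
        supporting = [e.eid for e in accepted]
        assertion = Assertion(
            aid=f"AID{i + 1}",
            gene_symbol=variant.gene_symbol,
            variant_name=variant.variant_name,
            variant_origin="Rare Germline" if atype == "Predisposing" else "Somatic",
            disease_doid=accepted[0].disease_doid if accepted else "DOID:162",
            assertion_type=atype,
            assertion_direction="Supports",
            supporting_eids=supporting,
            summary=f"{variant.gene_symbol} {variant.variant_name} is clinically relevant in this disease.",
            description="Synthesis of the accepted evidence items listed in the supporting grid.",
            moderation=ModerationRecord(
                state="accepted" if accepted else "submitted",
                submitter_id=f"curator{rng.randint(1, 6)}",
                decided_by="editor1" if accepted else None,
            ),
        )
        if atype == "Predisposing":
            codes = _ACMG_SETS[i % len(_ACMG_SETS)]
            assertion.acmg_codes = [AcmgCode(t) for t in codes]
            assertion.acmg_classification = combine_acmg(codes).value
            assertion.clinical_significance = assertion.acmg_classification
        else:
            sig_pool = [
                e.clinical_significance
                for e in accepted
                if e.evidence_direction == "Supports"
                and e.clinical_significance not in (None, "N/A")
                and e.clinical_significance
                in vocab.assertion_significance.get(atype, ())
            ]
            assertion.clinical_significance = (
                sig_pool[0] if sig_pool else vocab.assertion_significance[atype][0]
            )
            if atype == "Predictive":
                donor = next(
                    (e for e in accepted if e.evidence_type == "Predictive" and e.drugs),
                    None,
                )
                if donor:
                    assertion.drugs = list(donor.drugs)
                    assertion.drug_interaction_type = donor.drug_interaction_type
            if rng.random() < 0.3:
                assertion.fda_regulatory_approval = True
            amp = assign_amp(assertion, corpus)
            assertion.amp_tier, assertion.amp_level = amp.tier, amp.level
        corpus.assertions[assertion.aid] = assertion


# ---------------------------------------------------------------------------
# labeled defect injection
# ---------------------------------------------------------------------------


def _inject_defects(
    rng: random.Random,
    corpus: Corpus,
    config: GeneratorConfig,
    registries: Registries,
) -> None:
    """Apply single-rule, non-overlapping defects; store ground truth labels."""
    n_defects = round(config.violation_rate * config.n_eids)
    eids = sorted(corpus.evidence_items)
    used_eids: set[str] = set()
    used_variants: set[str] = set()
    trade_names = sorted(registries.drug_aliases)

    def fresh_eid(predicate) -> Optional[EvidenceItem]:
        pool = [
            corpus.evidence_items[e]
            for e in eids
            if e not in used_eids
            and corpus.evidence_items[e].variant_id not in used_variants
            and predicate(corpus.evidence_items[e])
        ]
        return rng.choice(pool) if pool else None

    def fresh_variant() -> Optional[VariantRecord]:
        pool = [
            corpus.variants[v]
            for v in sorted(corpus.variants)
            if v not in used_variants
            and corpus.variants[v].secondary_coordinates is None
        ]
        return rng.choice(pool) if pool else None

    missing_fields = (
        "source_type", "source_id", "variant_origin", "disease",
        "evidence_statement", "evidence_level", "evidence_direction",
        "clinical_significance", "evidence_rating",
    )

    def inject_missing() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: True)
        if item is None:
            return None
        target = rng.choice(missing_fields)
        if target == "source_type":
            item.source.source_type = None
        elif target == "source_id":
            item.source.source_id = None
        elif target == "disease":
            item.disease_doid = None
            item.disease_name = ""
            item.could_not_find_disease = False
        else:
            setattr(item, target, None)
        return ("evidence", item.eid, "EID_REQUIRED_FIELD_MISSING")

    def inject_rating() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: True)
        if item is None:
            return None
        item.evidence_rating = rng.choice((0, 6, 9))
        return ("evidence", item.eid, "EID_RATING_RANGE")

    def inject_predisposing_sig() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: e.evidence_type == "Predisposing")
        if item is None:
            return None
        item.clinical_significance = "Positive"
        return ("evidence", item.eid, "EID_PREDISPOSING_SIGNIFICANCE_NA")

    def inject_interaction() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: e.evidence_type == "Predictive" and len(e.drugs) > 1)
        if item is None:
            return None
        item.drug_interaction_type = None
        return ("evidence", item.eid, "EID_DRUG_INTERACTION_REQUIRED")

    def inject_drug_on_non_predictive() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: e.evidence_type in ("Prognostic", "Diagnostic") and not e.drugs)
        if item is None:
            return None
        item.drugs = ["Imatinib"]
        return ("evidence", item.eid, "EID_DRUGS_ON_NON_PREDICTIVE")

    def inject_trade_name() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: e.evidence_type == "Predictive" and len(e.drugs) == 1)
        if item is None:
            return None
        item.drugs = [rng.choice(trade_names)]
        return ("evidence", item.eid, "EID_DRUG_TRADE_NAME")

    def inject_significance() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: e.evidence_type in ("Prognostic", "Diagnostic", "Functional"))
        if item is None:
            return None
        item.clinical_significance = "Miraculous Response"
        return ("evidence", item.eid, "EID_SIGNIFICANCE_VOCAB")

    def inject_disease() -> Optional[tuple[str, str, str]]:
        item = fresh_eid(lambda e: not e.could_not_find_disease)
        if item is None:
            return None
        item.disease_doid = "DOID:9999999"
        return ("evidence", item.eid, "EID_DISEASE_UNRESOLVED")

    def inject_unversioned_tx() -> Optional[tuple[str, str, str]]:
        variant = fresh_variant()
        if variant is None or variant.primary_coordinates is None:
            return None
        tx = variant.primary_coordinates.representative_transcript
        if not tx:
            return None
        variant.primary_coordinates.representative_transcript = tx.rsplit(".", 1)[0]
        return ("variant", variant.variant_id, "VAR_TX_UNVERSIONED")

    def inject_so_ancestry() -> Optional[tuple[str, str, str]]:
        variant = fresh_variant()
        if variant is None:
            return None
        variant.variant_types = ["SO:0001583", "SO:0001818"]  # missense + its ancestor
        return ("variant", variant.variant_id, "VAR_SO_ANCESTRY")

    injectors = {
        "EID_REQUIRED_FIELD_MISSING": inject_missing,
        "EID_RATING_RANGE": inject_rating,
        "EID_PREDISPOSING_SIGNIFICANCE_NA": inject_predisposing_sig,
        "EID_DRUG_INTERACTION_REQUIRED": inject_interaction,
        "EID_DRUGS_ON_NON_PREDICTIVE": inject_drug_on_non_predictive,
        "EID_DRUG_TRADE_NAME": inject_trade_name,
        "EID_SIGNIFICANCE_VOCAB": inject_significance,
        "EID_DISEASE_UNRESOLVED": inject_disease,
        "VAR_TX_UNVERSIONED": inject_unversioned_tx,
        "VAR_SO_ANCESTRY": inject_so_ancestry,
    }
    mix = config.violation_mix or {k: 1.0 for k in injectors}
    kinds = sorted(k for k in mix if mix[k] > 0)
    weights = [mix[k] for k in kinds]

    attempts = 0
    while len(corpus.injected_defects) < n_defects and attempts < n_defects * 20:
        attempts += 1
        kind = rng.choices(kinds, weights=weights, k=1)[0]
        result = injectors[kind]()
        if result is None:
            continue
        entity_kind, entity_ref, rule_id = result
        if entity_kind == "evidence":
            used_eids.add(entity_ref)
            used_variants.add(corpus.evidence_items[entity_ref].variant_id)
        else:
            used_variants.add(entity_ref)
        corpus.injected_defects.append(
            {"entity_kind": entity_kind, "entity_ref": entity_ref, "rule_id": rule_id}
        )


# ---------------------------------------------------------------------------
# reference-sequence fixtures for normalization testing
# ---------------------------------------------------------------------------


def random_contig(rng: random.Random, length: int = 60, name: str = "ctg") -> ReferenceContig:
    """Random contig biased toward repeats (homopolymers / dinucleotide runs)."""
    bases: list[str] = []
    while len(bases) < length:
        roll = rng.random()
        if roll < 0.35:
            bases.extend(rng.choice("ACGT") * rng.randint(2, 6))
        elif roll < 0.5:
            unit = rng.choice(("AT", "CA", "GT", "CG"))
            bases.extend(unit * rng.randint(2, 4))
        else:
            bases.append(rng.choice("ACGT"))
    return ReferenceContig(name, "".join(bases[:length]))


def random_indel(rng: random.Random, contig: ReferenceContig) -> GenomicCoordinates:
    """A random trimmed-dialect deletion or insertion within the contig."""
    n = len(contig)
    if rng.random() < 0.5 and n >= 4:  # deletion of 1-3 bases
        size = rng.randint(1, min(3, n - 1))
        start = rng.randint(1, n - size)
        return GenomicCoordinates(
            chromosome=contig.name,
            start=start,
            stop=start + size - 1,
            reference_base=contig.slice(start, start + size - 1),
            variant_base="-",
        )
    start = rng.randint(1, n - 1)  # insertion between start and start+1
    inserted = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
    return GenomicCoordinates(
        chromosome=contig.name,
        start=start,
        stop=start + 1,
        reference_base="-",
        variant_base=inserted,
    )
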