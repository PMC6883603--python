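r"""Corpus container and the canonical JSON / flat TSV dialects.

A corpus holds the four identifier-keyed collections (genes, variants,
evidence items, assertions) plus optional generator ground truth. The JSON
dialect nests full records and preserves unknown fields; the TSV dialect is a
flat export — one row per record with a ``record_type`` discriminator and a
fixed, documented column order. Multi-valued cells are comma-joined with
backslash escaping (``\\`` then ``\,``). Both writers are deterministic:
identical corpora produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import (
    Assertion,
    AcmgCode,
    EvidenceItem,
    GeneRecord,
    GenomicCoordinates,
    SourceRef,
    VariantRecord,
    Violation,
)
from .ontology import Registries
from .rules import (
    make_violation,
    sort_report,
    validate_assertion,
    validate_evidence_item,
    validate_variant,
)
from .vocab import DEFAULT_VOCABULARY, Vocabulary

FORMAT_VERSION = 1


class CorpusParseError(ValueError):
    """Malformed corpus file; message carries a record locator."""


@dataclass
class Corpus:
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    variants: dict[str, VariantRecord] = field(default_factory=dict)
    evidence_items: dict[str, EvidenceItem] = field(default_factory=dict)
    assertions: dict[str, Assertion] = field(default_factory=dict)
    #: generator ground truth: list of {entity_kind, entity_ref, rule_id}
    injected_defects: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def evidence_for_variant(self, variant_id: str) -> list[EvidenceItem]:
        return [
            item
            for item in self.evidence_items.values()
            if item.variant_id == variant_id
        ]

    def integrity_report(self) -> list[Violation]:
        """Referential-integrity violations: dangling gene/variant/EID refs."""
        out: list[Violation] = []
        for vid, variant in self.variants.items():
            if variant.gene_symbol not in self.genes:
                out.append(
                    make_violation(
                        "CORPUS_DANGLING_REF", vid,
                        f"variant references unknown gene {variant.gene_symbol!r}",
                    )
                )
        for eid, item in self.evidence_items.items():
            if item.variant_id not in self.variants:
                out.append(
                    make_violation(
                        "CORPUS_DANGLING_REF", eid,
                        f"evidence item references unknown variant {item.variant_id!r}",
                    )
                )
        for aid, assertion in self.assertions.items():
            if assertion.variant_id not in self.variants:
                out.append(
                    make_violation(
                        "CORPUS_DANGLING_REF", aid,
                        f"assertion references unknown variant {assertion.variant_id!r}",
                    )
                )
            for eid in assertion.supporting_eids:
                if eid not in self.evidence_items:
                    out.append(
                        make_violation(
                            "CORPUS_DANGLING_REF", aid,
                            f"assertion references unknown evidence item {eid!r}",
                        )
                    )
        for symbol, gene in self.genes.items():
            if not any(v.gene_symbol == symbol for v in self.variants.values()):
                out.append(make_violation("GENE_NO_VARIANT", symbol))
        return sort_report(out)

    def validate(
        self,
        registries: Registries,
        vocab: Vocabulary = DEFAULT_VOCABULARY,
    ) -> list[Violation]:
        """Run the SOP rule engine over every record; deterministic report."""
        out: list[Violation] = []
        for variant in self.variants.values():
            out.extend(validate_variant(variant, registries, vocab))
        for item in self.evidence_items.values():
            out.extend(validate_evidence_item(item, registries, vocab))
        for assertion in self.assertions.values():
            out.extend(validate_assertion(assertion, self, registries, vocab))
        return sort_report(out)

    def to_dict(self) -> dict:
        out = {
            "format_version": FORMAT_VERSION,
            "genes": {k: g.to_dict() for k, g in sorted(self.genes.items())},
            "variants": {k: v.to_dict() for k, v in sorted(self.variants.items())},
            "evidence_items": {
                k: e.to_dict() for k, e in sorted(self.evidence_items.items())
            },
            "assertions": {k: a.to_dict() for k, a in sorted(self.assertions.items())},
        }
        if self.injected_defects:
            out["injected_defects"] = list(self.injected_defects)
        out.update(self.extras)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "Corpus":
        known = {
            "format_version", "genes", "variants", "evidence_items",
            "assertions", "injected_defects",
        }
        return cls(
            genes={k: GeneRecord.from_dict(v) for k, v in data.get("genes", {}).items()},
            variants={
                k: VariantRecord.from_dict(v)
                for k, v in data.get("variants", {}).items()
            },
            evidence_items={
                k: EvidenceItem.from_dict(v)
                for k, v in data.get("evidence_items", {}).items()
            },
            assertions={
                k: Assertion.from_dict(v) for k, v in data.get("assertions", {}).items()
            },
            injected_defects=list(data.get("injected_defects", [])),
            extras={k: v for k, v in data.items() if k not in known},
        )


# ---------------------------------------------------------------------------
# list-cell escaping for the TSV dialect
# ---------------------------------------------------------------------------


def join_list(values: Iterable) -> str:
    parts = []
    for v in values:
        s = str(v)
        parts.append(s.replace("\\", "\\\\").replace(",", "\\,"))
    return ",".join(parts)


def split_list(cell: str) -> list[str]:
    if cell == "":
        return []
    out, current, i = [], [], 0
    while i < len(cell):
        ch = cell[i]
        if ch == "\\" and i + 1 < len(cell):
            current.append(cell[i + 1])
            i += 2
        elif ch == ",":
            out.append("".join(current))
            current = []
            i += 1
        else:
            current.append(ch)
            i += 1
    out.append("".join(current))
    return out


#: Fixed TSV column order — the dialect's documented column registry.
TSV_COLUMNS = [
    "record_type", "id", "gene_symbol", "variant_name", "entrez_id",
    "aliases", "summary", "variant_types", "hgvs_expressions", "clinvar_ids",
    "chromosome", "start", "stop", "reference_base", "variant_base",
    "reference_build", "representative_transcript",
    "chromosome_2", "start_2", "stop_2", "reference_base_2", "variant_base_2",
    "source_type", "source_id", "citation", "clinical_trial_ids",
    "variant_origin", "disease_doid", "disease_name", "could_not_find_disease",
    "evidence_statement", "evidence_type", "evidence_level",
    "evidence_direction", "clinical_significance", "evidence_rating",
    "drugs", "drug_interaction_type", "phenotypes",
    "assertion_type", "assertion_direction", "amp_tier", "amp_level",
    "acmg_codes", "acmg_classification", "nccn_guideline",
    "fda_regulatory_approval", "fda_companion_test", "description",
    "supporting_eids", "state", "flagged", "submitter_id", "decided_by",
    "variant_evidence_score",
]


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _coords_cells(prefix: str, coords: Optional[GenomicCoordinates]) -> dict:
    if coords is None:
        return {}
    suffix = "_2" if prefix == "secondary" else ""
    return {
        f"chromosome{suffix}": coords.chromosome,
        f"start{suffix}": coords.start,
        f"stop{suffix}": coords.stop,
        f"reference_base{suffix}": coords.reference_base,
        f"variant_base{suffix}": coords.variant_base,
        **({"reference_build": coords.reference_build,
            "representative_transcript": coords.representative_transcript}
           if not suffix else {}),
    }


def _tsv_rows(corpus: Corpus, with_scores: bool) -> list[dict]:
    from .scoring import format_score, variant_evidence_score

    rows: list[dict] = []
    for symbol, gene in sorted(corpus.genes.items()):
        rows.append(
            {
                "record_type": "gene",
                "id": symbol,
                "gene_symbol": gene.gene_symbol,
                "entrez_id": gene.entrez_id,
                "aliases": join_list(gene.aliases),
                "summary": gene.summary,
            }
        )
    for vid, variant in sorted(corpus.variants.items()):
        row = {
            "record_type": "variant",
            "id": vid,
            "gene_symbol": variant.gene_symbol,
            "variant_name": variant.variant_name,
            "aliases": join_list(variant.aliases),
            "summary": variant.summary,
            "variant_types": join_list(variant.variant_types),
            "hgvs_expressions": join_list(variant.hgvs_expressions),
            "clinvar_ids": join_list(variant.clinvar_ids),
        }
        row.update(_coords_cells("primary", variant.primary_coordinates))
        row.update(_coords_cells("secondary", variant.secondary_coordinates))
        if with_scores:
            report = variant_evidence_score(vid, corpus.evidence_for_variant(vid))
            row["variant_evidence_score"] = format_score(report.variant_score)
        rows.append(row)
    for eid, item in sorted(corpus.evidence_items.items()):
        source = item.source or SourceRef()
        rows.append(
            {
                "record_type": "evidence",
                "id": eid,
                "gene_symbol": item.gene_symbol,
                "variant_name": item.variant_name,
                "source_type": source.source_type,
                "source_id": source.source_id,
                "citation": source.citation,
                "clinical_trial_ids": join_list(source.clinical_trial_ids),
                "variant_origin": item.variant_origin,
                "disease_doid": item.disease_doid,
                "disease_name": item.disease_name,
                "could_not_find_disease": item.could_not_find_disease,
                "evidence_statement": item.evidence_statement,
                "evidence_type": item.evidence_type,
                "evidence_level": item.evidence_level,
                "evidence_direction": item.evidence_direction,
                "clinical_significance": item.clinical_significance,
                "evidence_rating": item.evidence_rating,
                "drugs": join_list(item.drugs),
                "drug_interaction_type": item.drug_interaction_type,
                "phenotypes": join_list(item.phenotypes),
                "state": item.moderation.state,
                "flagged": item.moderation.flagged,
                "submitter_id": item.moderation.submitter_id,
                "decided_by": item.moderation.decided_by,
            }
        )
    for aid, assertion in sorted(corpus.assertions.items()):
        rows.append(
            {
                "record_type": "assertion",
                "id": aid,
                "gene_symbol": assertion.gene_symbol,
                "variant_name": assertion.variant_name,
                "variant_origin": assertion.variant_origin,
                "disease_doid": assertion.disease_doid,
                "assertion_type": assertion.assertion_type,
                "assertion_direction": assertion.assertion_direction,
                "clinical_significance": assertion.clinical_significance,
                "drugs": join_list(assertion.drugs),
                "drug_interaction_type": assertion.drug_interaction_type,
                "phenotypes": join_list(assertion.phenotypes),
                "amp_tier": assertion.amp_tier,
                "amp_level": assertion.amp_level,
                "acmg_codes": join_list(
                    c.token
                    + (f"|{c.strength_override}" if c.strength_override else "")
                    for c in assertion.acmg_codes
                ),
                "acmg_classification": assertion.acmg_classification,
                "nccn_guideline": assertion.nccn_guideline,
                "fda_regulatory_approval": assertion.fda_regulatory_approval,
                "fda_companion_test": assertion.fda_companion_test,
                "summary": assertion.summary,
                "description": assertion.description,
                "supporting_eids": join_list(assertion.supporting_eids),
                "state": assertion.moderation.state,
                "flagged": assertion.moderation.flagged,
                "submitter_id": assertion.moderation.submitter_id,
                "decided_by": assertion.moderation.decided_by,
            }
        )
    return rows


def _atomic_write(path: str, text: str) -> None:
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_corpus(
    corpus: Corpus, path: str, format: str = "json", with_scores: bool = False
) -> None:
    """Serialize deterministically; writes are atomic (temp file + rename)."""
    if format == "json":
        text = json.dumps(corpus.to_dict(), sort_keys=True, indent=1) + "\n"
    elif format == "tsv":
        import io

        buffer = io.StringIO()
        writer = csv.DictWriter(
            buffer, fieldnames=TSV_COLUMNS, delimiter="\t",
            restval="", extrasaction="raise", lineterminator="\n",
        )
        writer.writeheader()
        for row in _tsv_rows(corpus, with_scores):
            writer.writerow({k: _cell(v) for k, v in row.items()})
        text = buffer.getvalue()
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    _atomic_write(path, text)


def _coords_from_row(row: dict, suffix: str = "") -> Optional[GenomicCoordinates]:
    if not row.get(f"chromosome{suffix}"):
        return None
    return GenomicCoordinates(
        chromosome=row[f"chromosome{suffix}"],
        start=int(row[f"start{suffix}"] or 0),
        stop=int(row[f"stop{suffix}"] or 0),
        reference_base=row[f"reference_base{suffix}"] or "-",
        variant_base=row[f"variant_base{suffix}"] or "-",
        reference_build=row.get("reference_build") or "GRCh37",
        representative_transcript=(row.get("representative_transcript") or None)
        if not suffix
        else None,
    )


def _read_tsv(path: str) -> Corpus:
    corpus = Corpus()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            kind = row.get("record_type")
            try:
                if kind == "gene":
                    corpus.genes[row["id"]] = GeneRecord(
                        gene_symbol=row["gene_symbol"],
                        entrez_id=int(row["entrez_id"]) if row["entrez_id"] else None,
                        summary=row["summary"],
                        aliases=split_list(row["aliases"]),
                    )
                elif kind == "variant":
                    corpus.variants[row["id"]] = VariantRecord(
                        gene_symbol=row["gene_symbol"],
                        variant_name=row["variant_name"],
                        aliases=split_list(row["aliases"]),
                        summary=row["summary"],
                        variant_types=split_list(row["variant_types"]),
                        hgvs_expressions=split_list(row["hgvs_expressions"]),
                        clinvar_ids=split_list(row["clinvar_ids"]),
                        primary_coordinates=_coords_from_row(row),
                        secondary_coordinates=_coords_from_row(row, "_2"),
                    )
                elif kind == "evidence":
                    item = EvidenceItem.from_dict(
                        {
                            "eid": row["id"],
                            "gene_symbol": row["gene_symbol"] or None,
                            "variant_name": row["variant_name"] or None,
                            "source": {
                                "source_type": row["source_type"] or None,
                                "source_id": row["source_id"] or None,
                                "citation": row["citation"],
                                "clinical_trial_ids": split_list(row["clinical_trial_ids"]),
                            },
                            "variant_origin": row["variant_origin"] or None,
                            "disease_doid": row["disease_doid"] or None,
                            "disease_name": row["disease_name"],
                            "could_not_find_disease": row["could_not_find_disease"] == "true",
                            "evidence_statement": row["evidence_statement"] or None,
                            "evidence_type": row["evidence_type"] or None,
                            "evidence_level": row["evidence_level"] or None,
                            "evidence_direction": row["evidence_direction"] or None,
                            "clinical_significance": row["clinical_significance"] or None,
                            "evidence_rating": int(row["evidence_rating"]) if row["evidence_rating"] else None,
                            "drugs": split_list(row["drugs"]),
                            "drug_interaction_type": row["drug_interaction_type"] or None,
                            "phenotypes": split_list(row["phenotypes"]),
                            "moderation": {
                                "state": row["state"] or "submitted",
                                "flagged": row["flagged"] == "true",
                                "submitter_id": row["submitter_id"],
                                "decided_by": row["decided_by"] or None,
                            },
                        }
                    )
                    corpus.evidence_items[row["id"]] = item
                elif kind == "assertion":
                    codes = []
                    for token in split_list(row["acmg_codes"]):
                        if "|" in token:
                            t, override = token.split("|", 1)
                            codes.append({"token": t, "strength_override": override})
                        else:
                            codes.append({"token": token})
                    corpus.assertions[row["id"]] = Assertion.from_dict(
                        {
                            "aid": row["id"],
                            "gene_symbol": row["gene_symbol"] or None,
                            "variant_name": row["variant_name"] or None,
                            "variant_origin": row["variant_origin"] or None,
                            "disease_doid": row["disease_doid"] or None,
                            "assertion_type": row["assertion_type"] or None,
                            "assertion_direction": row["assertion_direction"] or None,
                            "clinical_significance": row["clinical_significance"] or None,
                            "drugs": split_list(row["drugs"]),
                            "drug_interaction_type": row["drug_interaction_type"] or None,
                            "phenotypes": split_list(row["phenotypes"]),
                            "amp_tier": row["amp_tier"] or None,
                            "amp_level": row["amp_level"] or None,
                            "acmg_codes": codes,
                            "acmg_classification": row["acmg_classification"] or None,
                            "nccn_guideline": row["nccn_guideline"] or None,
                            "fda_regulatory_approval": row["fda_regulatory_approval"] == "true",
                            "fda_companion_test": row["fda_companion_test"] == "true",
                            "summary": row["summary"],
                            "description": row["description"],
                            "supporting_eids": split_list(row["supporting_eids"]),
                            "moderation": {
                                "state": row["state"] or "submitted",
                                "flagged": row["flagged"] == "true",
                                "submitter_id": row["submitter_id"],
                                "decided_by": row["decided_by"] or None,
                            },
                        }
                    )
                else:
                    raise CorpusParseError(
                        f"{path}:{lineno}: unknown record_type {kind!r}"
                    )
            except (KeyError, ValueError, TypeError) as exc:
                if isinstance(exc, CorpusParseError):
                    raise
                raise CorpusParseError(f"{path}:{lineno}: {exc}") from exc
    return corpus


def read_corpus(path: str, format: str = "json") -> Corpus:
    """Parse a corpus file; raises CorpusParseError with a record locator."""
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"{path}:{exc.lineno}: {exc.msg}") from exc
        if not isinstance(data, dict):
            raise CorpusParseError(f"{path}: top level must be an object")
        return Corpus.from_dict(data)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown corpus format {format!r}")
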