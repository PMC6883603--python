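"""Ontology term registries with ancestor/descendant queries.

The curation model leans on four external ontologies: the Disease Ontology
cancer branch (diseases), the Sequence Ontology ``sequence_variant`` subtree
(variant types), the Human Phenotype Ontology (associated phenotypes), and the
NCI Thesaurus (drugs). Registries are plug-in term tables — a 4-column TSV or
an OBO file — so the toolkit runs fully offline on bundled miniature subsets.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional

import networkx as nx

CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\S+$")

ONTOLOGY_KEYS = ("disease", "sequence", "phenotype", "drug")

SEQUENCE_VARIANT_ROOT = "SO:0001060"


class OntologyError(ValueError):
    """Malformed term table: bad CURIE, duplicate id, dangling parent, or cycle."""


class UnknownTermError(KeyError):
    """Lookup of a term id absent from the registry."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    parent_ids: tuple[str, ...] = ()
    ontology_key: str = "disease"


@dataclass
class OntologyRegistry:
    """A validated DAG of terms supporting id/name lookup and ancestry queries."""

    ontology_key: str
    _terms: dict[str, OntologyTerm] = field(default_factory=dict)
    _by_name: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(default_factory=dict)

    def add_term(self, term: OntologyTerm) -> None:
        if not CURIE_RE.match(term.term_id):
            raise OntologyError(f"term id is not a CURIE: {term.term_id!r}")
        if term.term_id in self._terms:
            raise OntologyError(f"duplicate term id: {term.term_id}")
        self._terms[term.term_id] = term
        self._by_name.setdefault(term.name, term.term_id)
        self._ancestor_cache.clear()

    def validate(self) -> None:
        """Check parent existence and acyclicity; raise OntologyError on failure."""
        graph = nx.DiGraph()
        graph.add_nodes_from(self._terms)
        for term in self._terms.values():
            for parent in term.parent_ids:
                if parent not in self._terms:
                    raise OntologyError(
                        f"{term.term_id} references unknown parent {parent}"
                    )
                graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"cyclic parentage: {cycle}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    def get(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def lookup_name(self, name: str) -> Optional[OntologyTerm]:
        term_id = self._by_name.get(name)
        return self._terms[term_id] if term_id else None

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable via parent links, excluding the term itself."""
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        seen: set[str] = set()
        stack = list(self.get(term_id).parent_ids)
        while stack:
            current = stack.pop()
            if current in seen:
                continue
            seen.add(current)
            stack.extend(self.get(current).parent_ids)
        result = frozenset(seen)
        self._ancestor_cache[term_id] = result
        return result

    def is_descendant(self, term_a: str, term_b: str) -> bool:
        """True iff ``term_b`` is a strict ancestor of ``term_a`` (irreflexive)."""
        if term_b not in self._terms:
            raise UnknownTermError(term_b)
        return term_b in self.ancestors(term_a)

    def related(self, term_a: str, term_b: str) -> bool:
        """True iff one term is an ancestor or descendant of the other."""
        return self.is_descendant(term_a, term_b) or self.is_descendant(term_b, term_a)


def _from_rows(
    rows: Iterable[tuple[str, str, str, str]], ontology_key: str
) -> OntologyRegistry:
    registry = OntologyRegistry(ontology_key=ontology_key)
    for term_id, name, parents, row_key in rows:
        if row_key and row_key != ontology_key:
            raise OntologyError(
                f"term {term_id} declares ontology {row_key!r}, expected {ontology_key!r}"
            )
        parent_ids = tuple(p for p in parents.split("|") if p)
        registry.add_term(
            OntologyTerm(term_id, name, parent_ids, ontology_key=ontology_key)
        )
    registry.validate()
    return registry


def load_term_table(path: str, ontology_key: str) -> OntologyRegistry:
    """Load a 4-column TSV: term_id, name, parent_ids (pipe-joined), ontology_key."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = []
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 4:
                raise OntologyError(f"expected 4 columns, got {len(row)}: {row!r}")
            rows.append((row[0], row[1], row[2], row[3]))
    return _from_rows(rows, ontology_key)


def load_obo(path: str, ontology_key: str) -> OntologyRegistry:
    """Load an OBO-format ontology file (is_a edges only)."""
    import obonet

    graph = obonet.read_obo(path)
    registry = OntologyRegistry(ontology_key=ontology_key)
    for node, data in sorted(graph.nodes(data=True)):
        parents = tuple(sorted(graph.successors(node)))
        registry.add_term(
            OntologyTerm(node, data.get("name", node), parents, ontology_key)
        )
    registry.validate()
    return registry


def load_ontology(path: str, ontology_key: str) -> OntologyRegistry:
    if ontology_key not in ONTOLOGY_KEYS:
        raise OntologyError(f"unknown ontology key {ontology_key!r}")
    if str(path).endswith(".obo"):
        return load_obo(path, ontology_key)
    return load_term_table(path, ontology_key)


@dataclass
class Registries:
    """The four ontology registries plus the drug trade-name alias table."""

    disease: OntologyRegistry
    sequence: OntologyRegistry
    phenotype: OntologyRegistry
    drug: OntologyRegistry
    drug_aliases: dict[str, str] = field(default_factory=dict)

    def for_key(self, ontology_key: str) -> OntologyRegistry:
        return getattr(self, ontology_key)


def _bundled_path(filename: str):
    return resources.files("varkb.data").joinpath(filename)


def load_trade_name_table(path) -> dict[str, str]:
    """Two-column TSV mapping drug trade name -> generic name."""
    aliases: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            aliases[row[0]] = row[1]
    return aliases


def bundled_registries() -> Registries:
    """Load the packaged miniature ontology subsets (offline fixtures)."""
    with resources.as_file(_bundled_path("disease_terms.tsv")) as p:
        disease = load_term_table(str(p), "disease")
    with resources.as_file(_bundled_path("sequence_terms.tsv")) as p:
        sequence = load_term_table(str(p), "sequence")
    with resources.as_file(_bundled_path("phenotype_terms.tsv")) as p:
        phenotype = load_term_table(str(p), "phenotype")
    with resources.as_file(_bundled_path("drug_terms.tsv")) as p:
        drug = load_term_table(str(p), "drug")
    with resources.as_file(_bundled_path("drug_trade_names.tsv")) as p:
        aliases = load_trade_name_table(str(p))
    return Registries(disease, sequence, phenotype, drug, aliases)
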