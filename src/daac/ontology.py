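"""Gene Ontology graph and annotation handling.

Reads the GO graph from OBO 1.2 (via ``obonet``), GO annotations from GAF
2.x, filters annotations to experimental evidence codes, and propagates
each annotation up the DAG to all ancestors reachable through ``is_a`` and
``part_of`` edges — excluding the three namespace roots, which carry no
functional information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Mapping, TextIO, Union

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: GO evidence codes marked "experimental"; only these back training classes.
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

#: Relations followed during ancestor propagation.
PROPAGATION_RELATIONS = ("is_a", "part_of")

AnnotationRecord = tuple[str, str, str]  # (protein_id, term_id, evidence_code)


@dataclass(frozen=True)
class OntologyGraph:
    """GO terms with child-to-parent edges over is_a / part_of.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point from child to
    parent; ``roots`` holds the namespace root term ids (terms with no
    parent); ``alt_ids`` maps secondary ids to primary ones.
    """

    graph: nx.DiGraph
    roots: FrozenSet[str]
    namespaces: Mapping[str, str]
    alt_ids: Mapping[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary id (primary ids pass through)."""
        if term_id in self.graph:
            return term_id
        return self.alt_ids.get(term_id, term_id)

    def __contains__(self, term_id: str) -> bool:
        return self.resolve(term_id) in self.graph


def parse_obo(
    source: Union[str, TextIO],
    include_part_of: bool = True,
) -> OntologyGraph:
    """Parse an OBO 1.2 ontology into an :class:`OntologyGraph`.

    Obsolete terms are dropped; ``is_a`` edges (and ``part_of``, unless
    disabled) are retained child->parent; other relationship types (e.g.
    regulates) are ignored for propagation.  A cyclic graph or a term
    without a namespace is an error.
    """
    multigraph = obonet.read_obo(source, ignore_obsolete=True)
    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    graph = nx.DiGraph()
    namespaces: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            raise ValueError(f"term {node} has no namespace")
        graph.add_node(node)
        namespaces[node] = ns
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, rel in multigraph.edges(keys=True):
        if rel in relations and parent in graph:
            graph.add_edge(child, parent, relation=rel)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ontology contains a cycle over is_a/part_of edges")
    roots = frozenset(n for n in graph.nodes if graph.out_degree(n) == 0)
    return OntologyGraph(
        graph=graph, roots=roots, namespaces=namespaces, alt_ids=alt_ids
    )


def ancestors(ontology: OntologyGraph, term_id: str) -> set[str]:
    """All terms reachable from ``term_id`` via parent edges, minus the
    namespace roots and the term itself."""
    term = ontology.resolve(term_id)
    if term not in ontology.graph:
        raise KeyError(f"unknown GO term {term_id}")
    return nx.descendants(ontology.graph, term) - set(ontology.roots)


@dataclass(frozen=True)
class AnnotationSet:
    """A set of (protein, GO term, evidence) records.

    ``propagated`` marks sets that are closed under non-root ancestors.
    """

    records: FrozenSet[AnnotationRecord]
    propagated: bool = False

    def proteins(self) -> set[str]:
        return {p for p, _, _ in self.records}

    def terms_for(self, protein_id: str) -> set[str]:
        return {t for p, t, _ in self.records if p == protein_id}

    def by_protein(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, t, _ in self.records:
            out.setdefault(p, set()).add(t)
        return out

    def __len__(self) -> int:
        return len(self.records)


def parse_gaf(stream: Union[TextIO, Iterable[str]]) -> AnnotationSet:
    """Parse GAF 2.x annotation rows.

    Uses columns 2 (object id), 4 (qualifier), 5 (GO id) and 7 (evidence
    code).  Rows whose qualifier contains ``NOT`` are dropped (a negated
    annotation is not an annotation); ``!`` comment lines are skipped.
    """
    records: set[AnnotationRecord] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        parts = line.split("\t")
        if len(parts) != 17:
            raise ValueError(
                f"line {lineno}: GAF rows have 17 tab-separated columns, "
                f"got {len(parts)}"
            )
        qualifier = parts[3]
        if "NOT" in qualifier.split("|"):
            continue
        records.add((parts[1], parts[4], parts[6]))
    return AnnotationSet(records=frozenset(records), propagated=False)


def filter_experimental(
    anns: AnnotationSet,
    codes: FrozenSet[str] = EXPERIMENTAL_CODES,
) -> AnnotationSet:
    """Keep only records whose evidence code is in ``codes``."""
    kept = frozenset(r for r in anns.records if r[2] in codes)
    return replace(anns, records=kept)


def propagate(anns: AnnotationSet, ontology: OntologyGraph) -> AnnotationSet:
    """Extend annotations to all non-root ancestors of each annotated term.

    Records naming unknown or obsolete terms are dropped with a warning;
    direct annotations to namespace roots are likewise dropped (roots carry
    no information).  Idempotent: propagating an already-closed set returns
    an equal set.
    """
    out: set[AnnotationRecord] = set()
    n_dropped = 0
    for protein, term, evidence in anns.records:
        resolved = ontology.resolve(term)
        if resolved not in ontology.graph:
            n_dropped += 1
            continue
        if resolved in ontology.roots:
            n_dropped += 1
            continue
        out.add((protein, resolved, evidence))
        for parent in ancestors(ontology, resolved):
            out.add((protein, parent, evidence))
    if n_dropped:
        logger.warning(
            "%d annotation record(s) dropped (unknown/obsolete/root terms)",
            n_dropped,
        )
    return AnnotationSet(records=frozenset(out), propagated=True)


def write_annotations(anns: AnnotationSet, stream: TextIO) -> None:
    """Two-column TSV (protein_id, term_id), deduplicated and sorted."""
    for protein, term in sorted({(p, t) for p, t, _ in anns.records}):
        stream.write(f"{protein}\t{term}\n")
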