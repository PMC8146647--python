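"""The Gene Ontology DAG: parsing, validation, ancestor closure, propagation.

The ontology is the backbone of every downstream metric: annotations obey the
true-path rule (annotating a term implies all of its ancestors), so coverage,
specificity, and the CAFA evaluation all start from the transitive closure of
``is_a``/``part_of`` edges computed here.

Terms live in exactly one of the three GO aspects (namespaces): cellular
component (CC), molecular function (MF), biological process (BP). Closure
never crosses aspects, obsolete terms never participate in closure, and the
graph restricted to closure relations must be acyclic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

from .errors import (
    ObsoleteTermError,
    OntologyValidationError,
    ParseError,
    UnknownTermError,
)

#: Relations that imply annotation inheritance (the true-path rule).
DEFAULT_RELATIONS: frozenset[str] = frozenset({"is_a", "part_of"})

NAMESPACES = ("cellular_component", "molecular_function", "biological_process")

#: Aspect short codes keyed by namespace, in GAF column-9 convention.
NAMESPACE_TO_ASPECT: Mapping[str, str] = {
    "cellular_component": "CC",
    "molecular_function": "MF",
    "biological_process": "BP",
}
ASPECT_TO_NAMESPACE: Mapping[str, str] = {v: k for k, v in NAMESPACE_TO_ASPECT.items()}
ASPECT_LETTER = {"cellular_component": "C", "molecular_function": "F", "biological_process": "P"}
LETTER_TO_NAMESPACE = {v: k for k, v in ASPECT_LETTER.items()}


@dataclass(frozen=True)
class GoTerm:
    """One GO term as read from an OBO ``[Term]`` stanza."""

    id: str
    name: str
    namespace: str
    parents: tuple[tuple[str, str], ...] = ()  # (parent id, relation)
    is_obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


class OntologyGraph:
    """A validated GO DAG with ancestor-closure queries.

    Parameters
    ----------
    terms:
        All terms, including obsolete ones. Obsolete terms are recorded but
        contribute no closure edges.
    relations:
        Edge labels that participate in closure (default ``is_a`` + ``part_of``).
    """

    def __init__(self, terms: Iterable[GoTerm], relations: Iterable[str] = DEFAULT_RELATIONS):
        self.relations = frozenset(relations)
        self.terms: dict[str, GoTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyValidationError(f"duplicate term id {t.id}")
            self.terms[t.id] = t

        self.alt_map: dict[str, str] = {}
        for t in self.terms.values():
            if t.is_obsolete:
                continue
            for alt in t.alt_ids:
                self.alt_map[alt] = t.id

        # child -> parent digraph over closure relations, live terms only
        g = nx.DiGraph()
        for t in self.terms.values():
            if t.is_obsolete:
                continue
            g.add_node(t.id)
            for parent, rel in t.parents:
                if rel not in self.relations:
                    continue
                pt = self.terms.get(parent)
                if pt is None:
                    raise OntologyValidationError(
                        f"term {t.id} has unknown parent {parent}"
                    )
                if pt.is_obsolete:
                    continue
                if pt.namespace != t.namespace:
                    # closure never crosses aspects
                    continue
                g.add_edge(t.id, parent, relation=rel)
        self._graph = g

        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyValidationError(f"ontology contains a cycle: {path}")

        # roots: live terms with no outgoing closure edge, one per namespace
        self.roots: dict[str, str] = {}
        for t in self.terms.values():
            if t.is_obsolete:
                continue
            if g.out_degree(t.id) == 0:
                if t.namespace in self.roots:
                    raise OntologyValidationError(
                        f"namespace {t.namespace} has multiple roots: "
                        f"{self.roots[t.namespace]}, {t.id}"
                    )
                self.roots[t.namespace] = t.id

        # every live non-root term must reach its namespace root
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        for t in self.terms.values():
            if t.is_obsolete or t.id == self.roots.get(t.namespace):
                continue
            root = self.roots.get(t.namespace)
            if root is None or root not in self.ancestors(t.id):
                raise OntologyValidationError(
                    f"term {t.id} cannot reach the {t.namespace} root"
                )

    # -- queries ----------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_map

    def __len__(self) -> int:
        return sum(1 for t in self.terms.values() if not t.is_obsolete)

    @property
    def root_ids(self) -> frozenset[str]:
        return frozenset(self.roots.values())

    def resolve(self, term_id: str) -> str:
        """Map ``term_id`` (canonical or alt_id) to its canonical accession."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_map:
            return self.alt_map[term_id]
        raise UnknownTermError(f"unknown GO id: {term_id}")

    def namespace(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def aspect(self, term_id: str) -> str:
        """Aspect short code (CC/MF/BP) for a term."""
        return NAMESPACE_TO_ASPECT[self.namespace(term_id)]

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All ancestors of a term over the closure relations.

        Excludes the term itself, includes the namespace root; never crosses
        namespaces. Obsolete terms have no closure and are rejected.
        """
        tid = self.resolve(term_id)
        term = self.terms[tid]
        if term.is_obsolete:
            raise ObsoleteTermError(f"term {tid} is obsolete and has no closure")
        cached = self._ancestor_cache.get(tid)
        if cached is None:
            # edges run child -> parent, so graph-descendants are ancestors
            cached = frozenset(nx.descendants(self._graph, tid))
            self._ancestor_cache[tid] = cached
        return cached

    def is_root(self, term_id: str) -> bool:
        tid = self.resolve(term_id)
        return tid in self.root_ids

    def edges(self) -> list[tuple[str, str, str]]:
        """Closure edges as (child, parent, relation) triples."""
        return [(u, v, d["relation"]) for u, v, d in self._graph.edges(data=True)]


def parse_obo(stream: IO[str] | str, relations: Iterable[str] = DEFAULT_RELATIONS) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into a validated :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are consumed; ``[Typedef]`` stanzas are skipped.
    Relationships other than the requested closure relations are ignored.
    Obsolete terms are recorded (so GAF references to them fail loudly) but
    excluded from closure.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        g = obonet.read_obo(stream, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise ParseError(f"malformed OBO input: {exc}") from exc

    terms = []
    for node, data in g.nodes(data=True):
        namespace = data.get("namespace")
        if namespace is None:
            raise ParseError(f"[Term] stanza {node} is missing a namespace")
        if namespace not in NAMESPACES:
            raise ParseError(f"[Term] stanza {node} has unknown namespace {namespace!r}")
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: list[tuple[str, str]] = []
        if not obsolete:
            for parent in data.get("is_a", []):
                parents.append((parent, "is_a"))
            for rel_line in data.get("relationship", []):
                rel, _, target = rel_line.partition(" ")
                target = target.strip()
                if rel and target:
                    parents.append((target, rel))
        terms.append(
            GoTerm(
                id=node,
                name=data.get("name", ""),
                namespace=namespace,
                parents=tuple(parents),
                is_obsolete=obsolete,
                alt_ids=tuple(data.get("alt_id", [])),
            )
        )
    return OntologyGraph(terms, relations=relations)


def propagate(graph: OntologyGraph, annotations, include_roots: bool = False):
    """Expand an annotation set to its ancestral closure (true-path rule).

    For each record (gene, term, score) every ancestor of the term receives
    the annotation as well. Where several records for a gene reach the same
    term, the maximum score is kept and sources are unioned. Namespace roots
    are dropped unless ``include_roots`` — a root annotation carries no
    information and would make any predictor trivially correct there.

    Returns a new annotation set; warns (does not fail) if root removal
    empties a nonempty input.
    """
    import warnings

    from .annotations import Annotation, AnnotationSet, merge_records

    expanded = []
    for rec in annotations.records:
        tid = graph.resolve(rec.term)
        closure = {tid} | set(graph.ancestors(tid))
        if not include_roots:
            closure -= graph.root_ids
        for anc in closure:
            expanded.append(
                Annotation(rec.gene, anc, rec.score, rec.source, rec.evidence)
            )
    merged = merge_records(expanded)
    if annotations.records and not merged:
        warnings.warn(
            "propagation produced an empty set after root removal "
            f"(input had {len(annotations.records)} records)",
            stacklevel=2,
        )
    return AnnotationSet(merged, label=annotations.label, universe=annotations.universe)


def write_obo(graph: OntologyGraph) -> str:
    """Serialize an :class:`OntologyGraph` back to OBO 1.2 text.

    Deterministic (terms sorted by id); used by the fixture generator so toy
    ontologies round-trip through :func:`parse_obo`.
    """
    out = ["format-version: 1.2", "ontology: gofannot-toy", ""]
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        out.append("[Term]")
        out.append(f"id: {t.id}")
        out.append(f"name: {t.name}")
        out.append(f"namespace: {t.namespace}")
        for alt in t.alt_ids:
            out.append(f"alt_id: {alt}")
        if t.is_obsolete:
            out.append("is_obsolete: true")
        else:
            for parent, rel in t.parents:
                if rel == "is_a":
                    out.append(f"is_a: {parent}")
                else:
                    out.append(f"relationship: {rel} {parent}")
        out.append("")
    return "\n".join(out) + "\n"
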