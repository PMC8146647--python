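"""Shared fixtures: tiny hand-built DAGs and independent brute-force oracles.

The oracles here deliberately avoid the package's graph machinery: ancestor
closure is a plain BFS over an explicit edge list, and redundancy removal is
an O(n^2) pairwise scan, so they can arbitrate the real implementations.
"""

from __future__ import annotations

import random

import pytest

from gofannot import Annotation, AnnotationSet, GoTerm, OntologyGraph

BP = "biological_process"
MF = "molecular_function"
CC = "cellular_component"


def build_graph(edges: dict[str, list[tuple[str, str]]], namespaces: dict[str, str]):
    """OntologyGraph from {child: [(parent, relation), ...]} + namespaces."""
    terms = [
        GoTerm(tid, tid, ns, parents=tuple(edges.get(tid, ())))
        for tid, ns in namespaces.items()
    ]
    return OntologyGraph(terms)


@pytest.fixture
def chain_graph():
    """R <- A <- B, all biological_process. Ids GO:0000001..3."""
    return build_graph(
        {
            "GO:0000002": [("GO:0000001", "is_a")],
            "GO:0000003": [("GO:0000002", "is_a")],
        },
        {f"GO:000000{i}": BP for i in (1, 2, 3)},
    )


R, A, B = "GO:0000001", "GO:0000002", "GO:0000003"


@pytest.fixture
def diamond_graph():
    """B is_a A1, B is_a A2; A1, A2 is_a R (single BP aspect)."""
    return build_graph(
        {
            "GO:0000002": [("GO:0000001", "is_a")],
            "GO:0000003": [("GO:0000001", "is_a")],
            "GO:0000004": [("GO:0000002", "is_a"), ("GO:0000003", "is_a")],
        },
        {f"GO:000000{i}": BP for i in (1, 2, 3, 4)},
    )


@pytest.fixture
def sibling_graph():
    """R <- A; A <- B, A <- C (B, C siblings)."""
    return build_graph(
        {
            "GO:0000002": [("GO:0000001", "is_a")],
            "GO:0000003": [("GO:0000002", "is_a")],
            "GO:0000004": [("GO:0000002", "is_a")],
        },
        {f"GO:000000{i}": BP for i in (1, 2, 3, 4)},
    )


def aset(*pairs, label="t", universe=None):
    """Terse AnnotationSet builder from (gene, term[, score[, source]])."""
    recs = []
    for p in pairs:
        gene, term = p[0], p[1]
        score = p[2] if len(p) > 2 else 1.0
        source = p[3] if len(p) > 3 else "s"
        recs.append(Annotation(gene, term, score, source))
    return AnnotationSet(recs, label=label, universe=universe)


# -- independent oracles ----------------------------------------------------


def bf_ancestors(edge_list: list[tuple[str, str]], term: str) -> set[str]:
    """Brute-force BFS over (child, parent) pairs; excludes the term itself."""
    out: set[str] = set()
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for child, parent in edge_list:
            if child == node and parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def bf_remove_redundancy(records, edge_list):
    """O(n^2): drop a record iff another same-gene record's term descends
    from it (per the BFS oracle)."""
    kept = []
    for r in records:
        redundant = any(
            o.gene == r.gene
            and o.term != r.term
            and r.term in bf_ancestors(edge_list, o.term)
            for o in records
        )
        if not redundant:
            kept.append(r)
    return kept


def random_dag(rng: random.Random, n_terms: int, n_aspects: int = 1):
    """A random multi-aspect DAG (parents precede children => acyclic).

    Independent of the package's fixture generator: plain random.Random and
    uniform parent choice. Returns (OntologyGraph, edge list).
    """
    spaces = [CC, MF, BP][:n_aspects]
    terms, edges = [], []
    counter = 0
    for ns in spaces:
        counter += 1
        root = f"GO:{counter:07d}"
        terms.append(GoTerm(root, root, ns))
        ids = [root]
        for _ in range(n_terms - 1):
            counter += 1
            tid = f"GO:{counter:07d}"
            k = min(len(ids), 1 + (rng.random() < 0.35))
            parents = rng.sample(ids, k)
            rel = lambda: "part_of" if rng.random() < 0.25 else "is_a"
            plist = tuple((p, rel()) for p in parents)
            terms.append(GoTerm(tid, tid, ns, parents=plist))
            edges.extend((tid, p) for p, _ in plist)
            ids.append(tid)
    return OntologyGraph(terms), edges


def random_annotations(rng: random.Random, graph: OntologyGraph, n_genes: int,
                       max_records: int, label="rand"):
    """Uniform random (gene, term) records over non-root live terms."""
    pool = [t.id for t in graph.terms.values()
            if not t.is_obsolete and t.id not in graph.root_ids]
    genes = [f"g{i}" for i in range(1, n_genes + 1)]
    n = rng.randint(1, max_records)
    recs = {}
    for _ in range(n):
        g = rng.choice(genes)
        t = rng.choice(pool)
        recs[(g, t)] = Annotation(g, t, round(rng.uniform(0.05, 1.0), 3), label)
    return AnnotationSet(recs.values(), label=label, universe=genes)
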