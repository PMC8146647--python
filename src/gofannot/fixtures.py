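"""Deterministic synthetic fixtures: toy ontologies, gold standards,
predictions with controlled precision/recall, FASTA files and hit tables.

Real GO releases and curated annotation sets are large and external; this
module generates miniature stand-ins with the structural properties the rest
of the package relies on (a rooted DAG per aspect, leaf-biased curated
annotations, predictions whose measured precision and recall match stated
targets), so every pipeline stage is testable offline and every run is
reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotations import Annotation, AnnotationSet, merge_records
from .errors import UsageError
from .ontology import NAMESPACES, GoTerm, OntologyGraph, propagate

_GENE_WIDTH = 5  # g00001 ...


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic world.

    Defaults describe a small but non-trivial study: 40 terms per aspect in a
    DAG of depth <= 6, 200 genes, and a predictor targeted at precision 0.8 /
    recall 0.6 with mild score jitter — enough structure for every metric to
    be exercised without trivial saturation.
    """

    seed: int = 42
    n_terms_per_aspect: int = 40
    max_depth: int = 6
    branching: float = 2.0
    n_genes: int = 200
    target_precision: float = 0.8
    target_recall: float = 0.6
    score_noise: float = 0.05

    def __post_init__(self):
        if min(self.n_terms_per_aspect, self.max_depth, self.n_genes) < 1:
            raise UsageError("counts in FixtureSpec must be >= 1")
        for v in (self.target_precision, self.target_recall):
            if not 0.0 <= v <= 1.0:
                raise UsageError(f"targets must be in [0, 1], got {v}")
        if self.score_noise < 0:
            raise UsageError("score_noise must be >= 0")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # one independent stream per generator op, all derived from spec.seed
    return np.random.default_rng([spec.seed % (2**31), stream])


def make_toy_ontology(spec: FixtureSpec) -> OntologyGraph:
    """A random rooted DAG per aspect; deterministic for a fixed seed.

    Each non-root term gets one or two parents among already-created terms of
    depth < max_depth, with parent choice weighted toward deeper terms so the
    DAG actually reaches the requested depth. Acyclicity holds by
    construction (parents always precede children).
    """
    if spec.max_depth > spec.n_terms_per_aspect:
        raise UsageError(
            f"max_depth {spec.max_depth} infeasible with "
            f"{spec.n_terms_per_aspect} terms per aspect"
        )
    rng = _rng(spec, 0)
    terms: list[GoTerm] = []
    counter = 0
    for namespace in NAMESPACES:
        counter += 1
        root_id = f"GO:{counter:07d}"
        terms.append(GoTerm(root_id, f"{namespace} root", namespace))
        ids = [root_id]
        depth = {root_id: 0}
        for _ in range(spec.n_terms_per_aspect - 1):
            counter += 1
            tid = f"GO:{counter:07d}"
            eligible = [i for i in ids if depth[i] < spec.max_depth - 1]
            weights = np.array([1.0 + depth[i] ** 2 for i in eligible])
            n_parents = 1 if (
                len(eligible) < 2 or rng.random() >= 2.0 / spec.branching - 0.5
            ) else 2
            n_parents = min(n_parents, len(eligible))
            chosen = rng.choice(
                len(eligible), size=n_parents, replace=False, p=weights / weights.sum()
            )
            parents = tuple((eligible[int(c)], "is_a") for c in chosen)
            terms.append(GoTerm(tid, f"term {counter}", namespace, parents=parents))
            depth[tid] = 1 + max(depth[p] for p, _ in parents)
            ids.append(tid)
    return OntologyGraph(terms)


def _leaf_biased_terms(
    rng: np.random.Generator, graph: OntologyGraph, namespace: str, k: int
) -> list[str]:
    pool = [
        t.id
        for t in graph.terms.values()
        if t.namespace == namespace and not t.is_obsolete
        and t.id != graph.roots[namespace]
    ]
    if not pool:
        return []
    # weight terms by specificity so sampling clusters near the leaves
    weights = np.array([1.0 + len(graph.ancestors(t)) ** 2 for t in pool])
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False, p=weights / weights.sum())
    return [pool[int(i)] for i in idx]


def make_gold(spec: FixtureSpec, graph: OntologyGraph) -> AnnotationSet:
    """A curated-style gold standard: 1-5 leaf-biased terms per gene per
    aspect, score 1.0; the universe is the full gene set."""
    rng = _rng(spec, 1)
    genes = [f"g{i + 1:0{_GENE_WIDTH}d}" for i in range(spec.n_genes)]
    records = []
    for gene in genes:
        for namespace in NAMESPACES:
            k = int(rng.integers(1, 6))
            for term in _leaf_biased_terms(rng, graph, namespace, k):
                records.append(Annotation(gene, term, 1.0, "gold", "IDA"))
    return AnnotationSet(merge_records(records), label="gold", universe=genes)


def _stochastic_round(rng: np.random.Generator, x: float) -> int:
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def make_predictions(
    gold: AnnotationSet, graph: OntologyGraph, spec: FixtureSpec
) -> AnnotationSet:
    """Predictions whose propagated precision/recall match the FixtureSpec targets.

    Per gene and aspect, let T be the propagated gold term set (roots
    excluded). A true subset S of target size ``recall * |T|`` is formed by
    repeatedly deleting a random leaf-most element of T, so S stays closed
    under ancestors and survives propagation unchanged. False terms are then
    drawn from same-aspect terms whose own closure avoids T, greedily sized
    so the total propagated false count approaches ``|S| (1-p)/p``, which
    puts |S| / (|S| + false) at the target precision. True terms score 0.9
    and false terms 0.5, jittered by ``score_noise`` and clamped to
    [0.01, 1.0].
    """
    if spec.target_precision == 0:
        raise UsageError("target_precision = 0 cannot be realised (no true set)")
    rng = _rng(spec, 2)
    p, r = spec.target_precision, spec.target_recall
    expanded = propagate(graph, gold)
    gold_terms_by_gene: dict[str, dict[str, set[str]]] = {}
    for rec in expanded.records:
        ns = graph.namespace(rec.term)
        gold_terms_by_gene.setdefault(rec.gene, {}).setdefault(ns, set()).add(rec.term)

    records: list[Annotation] = []

    def emit(gene: str, term: str, base_score: float) -> None:
        score = base_score + (rng.normal(0.0, spec.score_noise) if spec.score_noise else 0.0)
        records.append(
            Annotation(gene, term, float(np.clip(score, 0.01, 1.0)), "synthetic", "IEA")
        )

    for gene in sorted(gold_terms_by_gene):
        for namespace in NAMESPACES:
            T = gold_terms_by_gene[gene].get(namespace)
            if not T:
                continue
            # -- true part: ancestor-closed subset of T of size ~ r|T|
            k = _stochastic_round(rng, r * len(T))
            S = set(T)
            while len(S) > k:
                leaves = [
                    t for t in S if not any(t in graph.ancestors(u) for u in S if u != t)
                ]
                S.discard(leaves[int(rng.integers(len(leaves)))])
            for t in sorted(S):
                emit(gene, t, 0.9)
            if not S:
                continue
            # -- false part: closure-disjoint terms until the propagated
            #    false count reaches |S|(1-p)/p
            f_target = _stochastic_round(rng, len(S) * (1.0 - p) / p)
            if f_target == 0:
                continue
            # usable false terms: outside T, and any gold-closure ancestors
            # they drag in are already predicted true (no hidden recall gain)
            candidates = [
                t.id
                for t in graph.terms.values()
                if t.namespace == namespace
                and not t.is_obsolete
                and t.id != graph.roots[namespace]
                and t.id not in T
                and (graph.ancestors(t.id) & T) <= S
            ]
            rng.shuffle(candidates)
            false_cover: set[str] = set()
            leftover: list[tuple[str, int]] = []
            for cand in candidates:
                if len(false_cover) >= f_target:
                    break
                contribution = (
                    ({cand} | set(graph.ancestors(cand)))
                    - graph.root_ids - T - false_cover
                )
                remaining = f_target - len(false_cover)
                if not contribution:
                    continue
                if len(contribution) <= remaining:
                    emit(gene, cand, 0.5)
                    false_cover |= contribution
                else:
                    leftover.append((cand, len(contribution)))
            remaining = f_target - len(false_cover)
            if remaining > 0 and leftover:
                # an oversized chunk, accepted with probability remaining/size
                # so the expected false count still matches the target
                cand, size = min(leftover, key=lambda x: x[1])
                if rng.random() < remaining / size:
                    emit(gene, cand, 0.5)

    return AnnotationSet(
        merge_records(records), label="synthetic-predictions", universe=gold.universe
    )


# -- sequence-side fixtures -------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def make_protein_fasta(spec: FixtureSpec, isoforms_per_gene: int = 2) -> str:
    """Random protein FASTA with several isoforms per gene (``g00001_T01``...).

    Lengths are lognormal around ~350 aa with a small-protein tail, echoing
    typical plant proteome length distributions.
    """
    rng = _rng(spec, 3)
    chunks = []
    for i in range(spec.n_genes):
        gene = f"g{i + 1:0{_GENE_WIDTH}d}"
        n_iso = 1 + int(rng.integers(isoforms_per_gene))
        for j in range(n_iso):
            length = max(10, int(rng.lognormal(np.log(350), 0.6)))
            seq = "".join(rng.choice(_AA, size=length))
            chunks.append(f">{gene}_T{j + 1:02d}\n{seq}")
    return "\n".join(chunks) + "\n"


def make_hit_tables(
    spec: FixtureSpec, n_pairs: int = 20, n_decoys: int = 10
) -> tuple[str, str, set[tuple[str, str]]]:
    """Forward/reverse BLAST-tabular text with a known planted RBH set.

    Returns (forward table, reverse table, expected pairs). Decoy queries get
    best hits that are not reciprocated.
    """
    rng = _rng(spec, 4)

    def row(q, s, bits, evalue):
        return (
            f"{q}\t{s}\t95.0\t200\t5\t0\t1\t200\t1\t200\t{evalue:.1e}\t{bits:.1f}"
        )

    fwd, rev, pairs = [], [], set()
    for i in range(n_pairs):
        a, b = f"a{i + 1:03d}", f"b{i + 1:03d}"
        bits = float(rng.uniform(150, 400))
        fwd.append(row(a, b, bits, 1e-50))
        rev.append(row(b, a, bits - float(rng.uniform(0, 20)), 1e-48))
        # weaker secondary hits that must not disturb the best
        other = f"b{(i + 2) % n_pairs + 1:03d}"
        fwd.append(row(a, other, bits - float(rng.uniform(30, 80)), 1e-20))
        pairs.add((a, b))
    for i in range(n_decoys):
        a = f"a{n_pairs + i + 1:03d}"
        b = f"b{int(rng.integers(1, n_pairs + 1)):03d}"
        fwd.append(row(a, b, float(rng.uniform(100, 140)), 1e-10))
        # reverse best of b already points at its true partner, so no pair
    return "\n".join(fwd) + "\n", "\n".join(rev) + "\n", pairs


def make_xref(spec: FixtureSpec, targets_per_gene: int = 1) -> str:
    """2-column TSV mapping each fixture gene to target-genome ids."""
    rng = _rng(spec, 5)
    lines = []
    for i in range(spec.n_genes):
        src = f"g{i + 1:0{_GENE_WIDTH}d}"
        n = 1 + int(rng.integers(targets_per_gene))
        for j in range(n):
            lines.append(f"{src}\th{i + 1:0{_GENE_WIDTH}d}_{j + 1}")
    return "\n".join(lines) + "\n"


def perturb_spec(spec: FixtureSpec, **changes) -> FixtureSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **changes)
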