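"""Gold-standard construction and three-way overlap comparison.

Curated annotations are usually tied to one genome release. A cross-reference
map between gene models of two releases (or two inbred lines) lets curated
terms be inherited onto the genome actually being evaluated
(:func:`inherit_gold`).

:func:`overlap_compare` then asks, for every gold-standard gene, term, and
annotation (gene-term pair): was it recovered by prediction method A, by
method B, by both, or by neither? All three sets are expanded to their
ancestral closures first (roots excluded), so a prediction of a descendant
term counts as recovering each of its ancestors.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from typing import IO, Mapping

from .annotations import ASPECTS, Annotation, AnnotationSet, merge_records, split_by_aspect
from .errors import ParseError, UsageError
from .ontology import OntologyGraph, propagate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossRef:
    """Gene cross-reference: source gene id -> set of target gene ids."""

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self):
        for src, targets in self.mapping.items():
            if not src:
                raise UsageError("cross-reference has an empty source id")
            if not targets or any(not t for t in targets):
                raise UsageError(f"cross-reference for {src!r} has empty targets")

    def __len__(self) -> int:
        return len(self.mapping)


def read_xref(stream: IO[str] | str) -> CrossRef:
    """Read a 2-column TSV (source gene, target gene); many rows per source."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2 or not cols[0] or not cols[1]:
            raise ParseError(f"xref line {lineno}: expected 2 nonempty columns")
        mapping.setdefault(cols[0], set()).add(cols[1])
    return CrossRef({k: frozenset(v) for k, v in mapping.items()})


def inherit_gold(gold_src: AnnotationSet, xref: CrossRef) -> AnnotationSet:
    """Project curated annotations through a cross-reference map.

    Every record (g, t) becomes (h, t) for each target h of g. Source genes
    absent from the map are dropped and their record count logged. The result
    is deduplicated (two source genes mapping onto one target can assert the
    same term).
    """
    if not xref.mapping:
        raise UsageError("cross-reference mapping is empty")
    out: list[Annotation] = []
    dropped = 0
    for rec in gold_src.records:
        targets = xref.mapping.get(rec.gene)
        if targets is None:
            dropped += 1
            continue
        for h in sorted(targets):
            out.append(Annotation(h, rec.term, rec.score, rec.source, rec.evidence))
    if dropped:
        logger.info(
            "inherit_gold: dropped %d record(s) whose gene is absent from the "
            "cross-reference",
            dropped,
        )
    return AnnotationSet(merge_records(out), label=f"{gold_src.label}-inherited")


def restrict_to_gold_genes(pred: AnnotationSet, gold: AnnotationSet) -> AnnotationSet:
    """Keep only prediction records for genes present in the gold standard."""
    genes = gold.genes()
    return AnnotationSet(
        [r for r in pred.records if r.gene in genes],
        label=pred.label,
    )


ENTITIES = ("genes", "terms", "annotations")


@dataclass(frozen=True)
class OverlapCounts:
    both: int
    only_a: int
    only_b: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.only_a + self.only_b + self.neither


@dataclass(frozen=True)
class OverlapReport:
    label_a: str
    label_b: str
    gold_label: str
    # per_aspect[aspect][entity] -> OverlapCounts
    per_aspect: dict[str, dict[str, OverlapCounts]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["aspect\tentity\tboth\tonly_a\tonly_b\tneither\ttotal"]
        for aspect in ASPECTS:
            if aspect not in self.per_aspect:
                continue
            for entity in ENTITIES:
                c = self.per_aspect[aspect][entity]
                lines.append(
                    f"{aspect}\t{entity}\t{c.both}\t{c.only_a}\t{c.only_b}"
                    f"\t{c.neither}\t{c.total}"
                )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        out = {
            aspect: {
                entity: vars(c) | {"total": c.total}
                for entity, c in entities.items()
            }
            for aspect, entities in self.per_aspect.items()
        }
        return json.dumps(
            {"a": self.label_a, "b": self.label_b, "gold": self.gold_label,
             "aspects": out},
            indent=2,
        ) + "\n"


def _classify(universe, in_a, in_b) -> OverlapCounts:
    both = only_a = only_b = neither = 0
    for x in universe:
        a, b = x in in_a, x in in_b
        if a and b:
            both += 1
        elif a:
            only_a += 1
        elif b:
            only_b += 1
        else:
            neither += 1
    return OverlapCounts(both, only_a, only_b, neither)


def overlap_compare(
    pred_a: AnnotationSet,
    pred_b: AnnotationSet,
    gold: AnnotationSet,
    graph: OntologyGraph,
    gene_mode: str = "correct",
) -> OverlapReport:
    """Classify gold entities by which prediction set recovers them.

    After ancestral expansion of all three sets (roots excluded), per aspect:

    * an **annotation** is an expanded gold pair (g, t); it is recovered by a
      method whose expanded set contains that pair;
    * a **term** is recovered if recovered as part of at least one annotation;
    * a **gene** is, under ``gene_mode="correct"`` (default), recovered when
      at least one of its gold annotations is, i.e. the method predicted
      something *true* for it; ``gene_mode="any"`` only requires the method to
      annotate the gene at all in that aspect.

    The four counts partition the gold entities exactly. Aspects with no gold
    annotation are omitted.
    """
    if not gold.records:
        raise UsageError("gold standard is empty")
    if gene_mode not in ("correct", "any"):
        raise UsageError(f"gene_mode must be 'correct' or 'any', got {gene_mode!r}")

    gold_parts = split_by_aspect(AnnotationSet(gold.records, label=gold.label), graph)
    a_parts = split_by_aspect(AnnotationSet(pred_a.records, label=pred_a.label), graph)
    b_parts = split_by_aspect(AnnotationSet(pred_b.records, label=pred_b.label), graph)

    per_aspect: dict[str, dict[str, OverlapCounts]] = {}
    for aspect in ASPECTS:
        gold_x = propagate(graph, gold_parts[aspect])
        if not gold_x.records:
            continue
        a_x = propagate(graph, a_parts[aspect])
        b_x = propagate(graph, b_parts[aspect])
        gold_pairs = gold_x.pairs()
        hit_a = gold_pairs & a_x.pairs()
        hit_b = gold_pairs & b_x.pairs()

        ann = _classify(gold_pairs, hit_a, hit_b)
        gold_terms = {t for _, t in gold_pairs}
        terms = _classify(
            gold_terms, {t for _, t in hit_a}, {t for _, t in hit_b}
        )
        gold_genes = {g for g, _ in gold_pairs}
        if gene_mode == "correct":
            genes_a = {g for g, _ in hit_a}
            genes_b = {g for g, _ in hit_b}
        else:
            genes_a = a_x.genes()
            genes_b = b_x.genes()
        genes = _classify(gold_genes, genes_a, genes_b)
        per_aspect[aspect] = {"genes": genes, "terms": terms, "annotations": ann}

    return OverlapReport(
        label_a=pred_a.label, label_b=pred_b.label, gold_label=gold.label,
        per_aspect=per_aspect,
    )
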