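"""Annotation sets: GAF / scored-TSV I/O and aggregation-stage cleaning.

An annotation is a (gene, GO term, confidence score, source, evidence) record.
Aggregating several prediction datasets introduces two kinds of noise that
this module removes:

* *duplicates* — the same gene-term pair asserted by several sources; resolved
  by keeping the maximum score and unioning the sources, and
* *redundancy* — a gene annotated both to a term and to one of that term's
  ancestors; the ancestor record adds nothing under the true-path rule and is
  removed, leaving only each gene's most specific (DAG-minimal) terms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import IO, Iterable, Mapping

from .errors import ObsoleteTermError, ParseError, UsageError
from .ontology import (
    ASPECT_LETTER,
    ASPECT_TO_NAMESPACE,
    NAMESPACE_TO_ASPECT,
    OntologyGraph,
)

ASPECTS = ("CC", "MF", "BP")


@dataclass(frozen=True)
class Annotation:
    """A single gene-to-GO-term assignment."""

    gene: str
    term: str
    score: float = 1.0
    source: str = ""
    evidence: str = "IEA"

    def __post_init__(self):
        if not 0.0 < self.score <= 1.0:
            raise ValueError(f"score must be in (0, 1], got {self.score}")
        if not self.gene:
            raise ValueError("gene id must be nonempty")


def merge_records(records: Iterable[Annotation]) -> list[Annotation]:
    """Collapse records sharing (gene, term): max score, sources unioned.

    The evidence code of the highest-scoring contributor is kept (ties break
    to the lexicographically smallest evidence code, for determinism).
    """
    best: dict[tuple[str, str], Annotation] = {}
    sources: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        key = (rec.gene, rec.term)
        sources.setdefault(key, set()).update(s for s in rec.source.split("+") if s)
        cur = best.get(key)
        if cur is None or rec.score > cur.score or (
            rec.score == cur.score and rec.evidence < cur.evidence
        ):
            best[key] = rec
    out = []
    for key, rec in best.items():
        out.append(replace(rec, source="+".join(sorted(sources[key]))))
    return out


class AnnotationSet:
    """A labelled collection of annotations with an optional gene universe.

    The universe is the full set of genes in the genome and is the coverage
    denominator; when present it must contain every annotated gene. At most
    one record exists per (gene, term, source).
    """

    def __init__(
        self,
        records: Iterable[Annotation] = (),
        label: str = "",
        universe: Iterable[str] | None = None,
    ):
        seen: dict[tuple[str, str, str], Annotation] = {}
        for rec in records:
            key = (rec.gene, rec.term, rec.source)
            if key in seen and seen[key] != rec:
                raise UsageError(
                    f"conflicting records for (gene={rec.gene}, term={rec.term}, "
                    f"source={rec.source!r})"
                )
            seen[key] = rec
        self.records: list[Annotation] = list(seen.values())
        self.label = label
        self.universe: frozenset[str] | None = (
            frozenset(universe) if universe is not None else None
        )
        if self.universe is not None:
            missing = self.genes() - self.universe
            if missing:
                raise UsageError(
                    f"universe is missing {len(missing)} annotated gene(s), "
                    f"e.g. {sorted(missing)[:3]}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return set(self.records) == set(other.records)

    def genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.records)

    def pairs(self) -> frozenset[tuple[str, str]]:
        """The (gene, term) pairs present."""
        return frozenset((r.gene, r.term) for r in self.records)

    def by_gene(self) -> dict[str, list[Annotation]]:
        out: dict[str, list[Annotation]] = {}
        for r in self.records:
            out.setdefault(r.gene, []).append(r)
        return out

    def replace(self, records: Iterable[Annotation], label: str | None = None) -> "AnnotationSet":
        return AnnotationSet(
            records, label=self.label if label is None else label, universe=self.universe
        )


# -- I/O -------------------------------------------------------------------

GAF_COLUMNS = 17


def read_gaf(stream: IO[str] | str, graph: OntologyGraph, label: str = "gaf") -> AnnotationSet:
    """Read a GAF 2.0-2.2 file into an :class:`AnnotationSet`.

    Gene id comes from column 2 (DB Object ID), the GO id from column 5
    (resolved through the ontology's alt_id map), evidence from column 7.
    The aspect letter in column 9 is cross-checked against the term's
    namespace; on contradiction the ontology wins and a warning is issued.
    Rows whose qualifier contains ``NOT`` are negative assertions and are
    dropped. GAF carries no confidence, so scores are fixed at 1.0.
    """
    import warnings

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) != GAF_COLUMNS:
            raise ParseError(
                f"GAF line {lineno}: expected {GAF_COLUMNS} columns, got {len(cols)}"
            )
        qualifier = cols[3]
        if "NOT" in qualifier.split("|"):
            continue
        gene, raw_term, evidence, aspect_letter = cols[1], cols[4], cols[6], cols[8]
        term = graph.resolve(raw_term)
        if graph.terms[term].is_obsolete:
            raise ObsoleteTermError(f"GAF line {lineno}: term {term} is obsolete")
        expected = ASPECT_LETTER[graph.namespace(term)]
        if aspect_letter and aspect_letter != expected:
            warnings.warn(
                f"GAF line {lineno}: aspect letter {aspect_letter!r} contradicts "
                f"ontology ({expected!r} for {term}); trusting the ontology",
                stacklevel=2,
            )
        records.append(Annotation(gene, term, 1.0, label, evidence or "IEA"))
    return AnnotationSet(merge_records(records), label=label)


def read_scored_tsv(
    stream: IO[str] | str, graph: OntologyGraph, label: str | None = None
) -> AnnotationSet:
    """Read a 4-column scored TSV: gene, GO term, score in (0, 1], source.

    A single optional header row is tolerated. Rows with scores outside
    (0, 1] or non-numeric are rejected with the offending line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(f"TSV line {lineno}: expected 4 columns, got {len(cols)}")
        gene, raw_term, raw_score, source = cols[0], cols[1], cols[2], cols[3]
        try:
            score = float(raw_score)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ParseError(f"TSV line {lineno}: non-numeric score {raw_score!r}") from None
        if not 0.0 < score <= 1.0:
            raise ParseError(f"TSV line {lineno}: score {score} outside (0, 1]")
        term = graph.resolve(raw_term)
        if graph.terms[term].is_obsolete:
            raise ObsoleteTermError(f"TSV line {lineno}: term {term} is obsolete")
        records.append(Annotation(gene, term, score, source))
    return AnnotationSet(
        merge_records(records), label=label if label is not None else "scored-tsv"
    )


#: Fixed metadata for deterministic GAF output (byte-identical re-runs).
_GAF_DATE = "20200101"
_GAF_TAXON = "taxon:1"
_GAF_REF = "GO_REF:0000000"


def write_gaf(aset: AnnotationSet, graph: OntologyGraph, db_label: str = "gofannot") -> str:
    """Serialize to GAF 2.0 text, sorted by (gene, term).

    Round-tripping through :func:`read_gaf` preserves the (gene, term) pair
    multiset; scores are not representable in GAF and are dropped.
    """
    lines = ["!gaf-version: 2.0"]
    for rec in sorted(aset.records, key=lambda r: (r.gene, r.term)):
        term = graph.resolve(rec.term)
        aspect = ASPECT_LETTER[graph.namespace(term)]
        cols = [
            db_label,            # 1  DB
            rec.gene,            # 2  DB Object ID
            rec.gene,            # 3  DB Object Symbol
            "",                  # 4  Qualifier
            term,                # 5  GO ID
            _GAF_REF,            # 6  DB:Reference
            rec.evidence,        # 7  Evidence Code
            "",                  # 8  With/From
            aspect,              # 9  Aspect
            "",                  # 10 DB Object Name
            "",                  # 11 Synonym
            "protein",           # 12 DB Object Type
            _GAF_TAXON,          # 13 Taxon
            _GAF_DATE,           # 14 Date
            rec.source or db_label,  # 15 Assigned By
            "",                  # 16 Annotation Extension
            "",                  # 17 Gene Product Form ID
        ]
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


# -- aggregation-stage cleaning ---------------------------------------------


def deduplicate(aset: AnnotationSet) -> AnnotationSet:
    """One record per (gene, term): max score, "+"-joined sorted source union."""
    return aset.replace(merge_records(aset.records))


def remove_redundancy(aset: AnnotationSet, graph: OntologyGraph) -> AnnotationSet:
    """Drop records whose term is an ancestor of another term of the same gene.

    After this, each gene carries only its DAG-minimal (most specific) terms;
    the removed records are recoverable by propagation, so no information is
    lost. Redundancy is strictly within-gene.
    """
    kept = []
    for gene, recs in aset.by_gene().items():
        covered: set[str] = set()
        for r in recs:
            covered |= graph.ancestors(graph.resolve(r.term))
        for r in recs:
            if graph.resolve(r.term) not in covered:
                kept.append(r)
    return aset.replace(kept)


def aggregate(sets: list[AnnotationSet], graph: OntologyGraph) -> AnnotationSet:
    """Union several datasets, then deduplicate and remove redundancy.

    The resulting aggregate covers, per aspect, at least as many genes as any
    component. The universe is the union of component universes (``None`` if
    no component defines one).
    """
    if not sets:
        raise UsageError("aggregate() needs at least one input set")
    universe: set[str] | None = None
    for s in sets:
        if s.universe is not None:
            universe = (universe or set()) | set(s.universe)
    merged = merge_records(r for s in sets for r in s.records)
    out = AnnotationSet(merged, label="aggregate", universe=universe)
    return remove_redundancy(out, graph)


def filter_blocklist(aset: AnnotationSet, blocklist: Iterable[str]) -> AnnotationSet:
    """Remove records whose term is in ``blocklist`` (exact matches only).

    To filter a branch of the DAG, pre-expand the blocklist with descendants
    before calling (see the ontology module).
    """
    block = frozenset(blocklist)
    return aset.replace([r for r in aset.records if r.term not in block])


def read_blocklist(stream: IO[str] | str) -> frozenset[str]:
    """One GO id per line; blank lines and '#' comments ignored."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = set()
    for line in stream:
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def split_by_aspect(aset: AnnotationSet, graph: OntologyGraph) -> dict[str, AnnotationSet]:
    """Partition into the three GO aspects, keyed ``CC``/``MF``/``BP``.

    The partition is exact (sizes sum to the input size) and each part
    inherits the universe.
    """
    parts: dict[str, list[Annotation]] = {a: [] for a in ASPECTS}
    for r in aset.records:
        parts[graph.aspect(r.term)].append(r)
    return {
        a: AnnotationSet(recs, label=f"{aset.label}:{a}" if aset.label else a,
                         universe=aset.universe)
        for a, recs in parts.items()
    }
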