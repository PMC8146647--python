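"""Sequence preparation and similarity-based annotation transfer.

Annotation pipelines work per gene, but protein FASTA releases list every
translated transcript. :func:`longest_isoform` keeps one representative (the
longest translation) per gene; :func:`sequence_stats` summarizes the filtered
set, flagging very short proteins (< 50 aa) that resist sequence-based
function prediction.

:func:`reciprocal_best_hits` detects RBH pairs — mutual best hits between two
proteomes in BLAST tabular output — as an orthology proxy, and
:func:`transfer_by_rbh` inherits curated GO terms across those pairs.
"""

from __future__ import annotations

import io
import re
import statistics
from dataclasses import dataclass
from typing import IO, Callable, Iterable

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .annotations import Annotation, AnnotationSet, merge_records
from .errors import ParseError, UndefinedMetricError

GeneRule = Callable[[str], str]

#: Strips one trailing transcript suffix: "_T001", "_P01", ".1", "-01", "_1".
_SUFFIX_RE = re.compile(r"(?:_[TP]?\d+|[.-]\d+)$")


def default_gene_rule(header_id: str) -> str:
    """Derive a gene id from a transcript id by stripping a trailing suffix.

    Handles the common conventions ``gene_T001``, ``gene_P01``, ``gene.1``
    and ``gene-01``. If no suffix matches, the id is returned unchanged (the
    transcript is then its own gene).
    """
    if not header_id:
        raise ParseError("empty FASTA header id")
    return _SUFFIX_RE.sub("", header_id) or header_id


def make_regex_gene_rule(pattern: str) -> GeneRule:
    """Gene rule from a user regex whose group 1 captures the gene id."""
    rx = re.compile(pattern)

    def rule(header_id: str) -> str:
        m = rx.search(header_id)
        if m is None or not m.group(1):
            raise ParseError(
                f"header {header_id!r} does not match gene regex {pattern!r}"
            )
        return m.group(1)

    return rule


@dataclass(frozen=True)
class SequenceRecordInfo:
    transcript_id: str
    gene_id: str
    length: int


def longest_isoform(
    records: Iterable[SeqRecord] | IO[str] | str,
    gene_rule: GeneRule = default_gene_rule,
) -> list[SeqRecord]:
    """Keep one record per gene: the longest translation.

    Length ties break to the lexicographically smallest transcript id. The
    output preserves the input order of first appearance of each gene.
    """
    if isinstance(records, str):
        records = io.StringIO(records)
    if hasattr(records, "read"):
        records = SeqIO.parse(records, "fasta")
    best: dict[str, SeqRecord] = {}
    order: list[str] = []
    for rec in records:
        gene = gene_rule(rec.id)
        cur = best.get(gene)
        if cur is None:
            best[gene] = rec
            order.append(gene)
        elif len(rec) > len(cur) or (len(rec) == len(cur) and rec.id < cur.id):
            best[gene] = rec
    return [best[g] for g in order]


@dataclass(frozen=True)
class SeqStats:
    """Length summary of a one-record-per-gene protein set."""

    gene_count: int
    total_length: int
    min_length: int
    mean_length: float
    median_length: float
    max_length: int
    small_pct: float  # proteins strictly shorter than 50 residues

    SMALL_THRESHOLD = 50

    def to_row(self) -> dict:
        return {
            "gene_count": self.gene_count,
            "total_length": self.total_length,
            "min": self.min_length,
            "mean": round(self.mean_length, 2),
            "median": self.median_length,
            "max": self.max_length,
            "small_pct": round(self.small_pct, 2),
        }


def sequence_stats(
    records: Iterable[SeqRecord] | IO[str] | str,
    gene_rule: GeneRule = default_gene_rule,
) -> SeqStats:
    """Length statistics over a protein FASTA (one record per gene assumed)."""
    if isinstance(records, str):
        records = io.StringIO(records)
    if hasattr(records, "read"):
        records = SeqIO.parse(records, "fasta")
    lengths = [len(r) for r in records]
    if not lengths:
        raise UndefinedMetricError("sequence statistics of an empty FASTA")
    return SeqStats(
        gene_count=len(lengths),
        total_length=sum(lengths),
        min_length=min(lengths),
        mean_length=sum(lengths) / len(lengths),
        median_length=statistics.median(lengths),
        max_length=max(lengths),
        small_pct=100.0
        * sum(1 for n in lengths if n < SeqStats.SMALL_THRESHOLD)
        / len(lengths),
    )


@dataclass(frozen=True)
class HitRow:
    """One BLAST tabular (outfmt 6) hit; only 4 of the 12 columns matter."""

    query: str
    subject: str
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.bitscore <= 0:
            raise ValueError(f"bitscore must be positive, got {self.bitscore}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")


def parse_hits(stream: IO[str] | str) -> list[HitRow]:
    """Parse BLAST outfmt-6 text (>= 12 tab-separated columns per row)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ParseError(
                f"hit table line {lineno}: expected >= 12 columns, got {len(cols)}"
            )
        try:
            rows.append(
                HitRow(cols[0], cols[1], bitscore=float(cols[11]), evalue=float(cols[10]))
            )
        except ValueError as exc:
            raise ParseError(f"hit table line {lineno}: {exc}") from None
    return rows


def _best_hits(rows: Iterable[HitRow], lexicographic_ties: bool) -> dict[str, str]:
    """Unique best subject per query: max bitscore, then min evalue.

    A residual tie (equal bitscore and evalue) disqualifies the query unless
    ``lexicographic_ties`` resolves it to the smallest subject id.
    """
    by_query: dict[str, list[HitRow]] = {}
    for row in rows:
        by_query.setdefault(row.query, []).append(row)
    best: dict[str, str] = {}
    for query, hits in by_query.items():
        ranked = sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject))
        top = ranked[0]
        tied = [
            h for h in ranked
            if h.bitscore == top.bitscore and h.evalue == top.evalue
            and h.subject != top.subject
        ]
        if tied and not lexicographic_ties:
            continue  # ambiguous best: conservative default is no claim
        best[query] = top.subject
    return best


def reciprocal_best_hits(
    forward: Iterable[HitRow] | IO[str] | str,
    reverse: Iterable[HitRow] | IO[str] | str,
    lexicographic_ties: bool = False,
) -> set[tuple[str, str]]:
    """Mutual-best-hit pairs (a, b) between two hit tables.

    (a, b) is reported iff b is a's unique best forward hit and a is b's
    unique best reverse hit; each id appears in at most one pair.
    """
    if isinstance(forward, (str,)) or hasattr(forward, "read"):
        forward = parse_hits(forward)
    if isinstance(reverse, (str,)) or hasattr(reverse, "read"):
        reverse = parse_hits(reverse)
    fwd = _best_hits(forward, lexicographic_ties)
    rev = _best_hits(reverse, lexicographic_ties)
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}


def transfer_by_rbh(
    pairs: Iterable[tuple[str, str]], donor: AnnotationSet
) -> AnnotationSet:
    """Inherit donor annotations across RBH pairs.

    For each pair (a, b) and donor record (b, t, s), emit (a, t, s) with
    source ``rbh:<donor label>``. Pairs whose donor gene has no annotation
    contribute nothing.
    """
    donor_by_gene = donor.by_gene()
    out = []
    src = f"rbh:{donor.label or 'donor'}"
    for a, b in pairs:
        for rec in donor_by_gene.get(b, []):
            out.append(Annotation(a, rec.term, rec.score, src, rec.evidence))
    return AnnotationSet(merge_records(out), label=src)


def make_fasta(records: Iterable[tuple[str, str]]) -> str:
    """Tiny helper: (id, sequence) pairs -> FASTA text (used by fixtures)."""
    out = []
    for rid, seq in records:
        out.append(f">{rid}")
        out.append(seq)
    return "\n".join(out) + "\n"
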