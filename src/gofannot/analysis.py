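"""Dataset-level analysis metrics: coverage, annotations/gene, specificity.

These quantify *how much* a dataset annotates, per GO aspect:

* **coverage** — percentage of the gene universe with at least one
  annotation;
* **annotations per gene** — total records divided by annotated genes,
  with a standard error over per-gene counts;
* **specificity** — ancestor count of the annotated term (deeper terms have
  more ancestors, hence carry more information), averaged over annotations.

All three are reported per aspect and overall, mirroring the way annotation
pipelines are compared against community datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .annotations import ASPECTS, AnnotationSet, split_by_aspect
from .errors import UndefinedMetricError, UsageError
from .ontology import OntologyGraph


@dataclass(frozen=True)
class MeanSE:
    """A sample mean with its standard error (sd/sqrt(n); 0 when n == 1)."""

    mean: float
    se: float
    n: int

    @staticmethod
    def of(values: Iterable[float]) -> "MeanSE":
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise UndefinedMetricError("mean of an empty sample is undefined")
        se = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        return MeanSE(float(arr.mean()), se, int(arr.size))


def coverage(aset: AnnotationSet) -> float:
    """Percentage of universe genes with >= 1 annotation."""
    if aset.universe is None or not aset.universe:
        raise UsageError(
            "coverage needs a gene universe; supply a gene list or FASTA-derived "
            "universe on the AnnotationSet"
        )
    return 100.0 * len(aset.genes()) / len(aset.universe)


def annotations_per_gene(aset: AnnotationSet) -> MeanSE:
    """Mean records per annotated gene, SE over per-gene counts."""
    counts = [len(v) for v in aset.by_gene().values()]
    if not counts:
        raise UndefinedMetricError("annotations/gene undefined on an empty set")
    return MeanSE.of(counts)


def specificity(
    aset: AnnotationSet, graph: OntologyGraph, include_root: bool = True
) -> MeanSE:
    """Mean ancestor count per annotation; SE over annotations.

    The annotated term itself is not counted. With ``include_root`` (default)
    the namespace root counts as an ancestor, so a direct child of the root
    has specificity 1 and the root itself 0; ``include_root=False`` shifts
    every non-root value down by one.
    """
    values = []
    for rec in aset.records:
        anc = graph.ancestors(rec.term)
        n = len(anc)
        if not include_root and n > 0:
            n -= len(anc & graph.root_ids)
        values.append(n)
    if not values:
        raise UndefinedMetricError("specificity undefined on an empty set")
    return MeanSE.of(values)


@dataclass(frozen=True)
class AspectMetrics:
    aspect: str
    universe_size: int
    n_genes_annotated: int
    n_annotations: int
    coverage_pct: float
    annotations_per_gene: MeanSE | None  # None when no gene is annotated
    specificity: MeanSE | None


@dataclass(frozen=True)
class AnalysisReport:
    """Per-aspect metrics plus an overall (all-aspect) row."""

    label: str
    per_aspect: dict[str, AspectMetrics]  # keys: CC, MF, BP, all

    def to_rows(self) -> list[dict]:
        rows = []
        for aspect in (*ASPECTS, "all"):
            m = self.per_aspect[aspect]
            rows.append(
                {
                    "dataset": self.label,
                    "aspect": aspect,
                    "universe_size": m.universe_size,
                    "n_genes_annotated": m.n_genes_annotated,
                    "n_annotations": m.n_annotations,
                    "coverage_pct": round(m.coverage_pct, 4),
                    "annotations_per_gene_mean": None
                    if m.annotations_per_gene is None
                    else round(m.annotations_per_gene.mean, 6),
                    "annotations_per_gene_se": None
                    if m.annotations_per_gene is None
                    else round(m.annotations_per_gene.se, 6),
                    "specificity_mean": None
                    if m.specificity is None
                    else round(m.specificity.mean, 6),
                    "specificity_se": None
                    if m.specificity is None
                    else round(m.specificity.se, 6),
                }
            )
        return rows

    def to_tsv(self) -> str:
        rows = self.to_rows()
        header = list(rows[0])
        lines = ["\t".join(header)]
        for row in rows:
            lines.append(
                "\t".join("" if row[k] is None else str(row[k]) for k in header)
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.to_rows(), indent=2) + "\n"


def _aspect_metrics(
    aspect: str,
    aset: AnnotationSet,
    graph: OntologyGraph,
    include_root: bool,
) -> AspectMetrics:
    n_genes = len(aset.genes())
    return AspectMetrics(
        aspect=aspect,
        universe_size=len(aset.universe or ()),
        n_genes_annotated=n_genes,
        n_annotations=len(aset),
        coverage_pct=coverage(aset) if aset.universe else 0.0,
        annotations_per_gene=annotations_per_gene(aset) if n_genes else None,
        specificity=specificity(aset, graph, include_root) if n_genes else None,
    )


def analysis_report(
    aset: AnnotationSet, graph: OntologyGraph, include_root: bool = True
) -> AnalysisReport:
    """Coverage, annotations/gene, and specificity per aspect and overall.

    The coverage denominator is the full gene universe for every aspect (an
    aspect-limited dataset simply shows low coverage there).
    """
    if aset.universe is None:
        raise UsageError("analysis_report needs a gene universe on the set")
    parts = split_by_aspect(aset, graph)
    per = {
        aspect: _aspect_metrics(aspect, parts[aspect], graph, include_root)
        for aspect in ASPECTS
    }
    per["all"] = _aspect_metrics("all", aset, graph, include_root)
    return AnalysisReport(label=aset.label, per_aspect=per)
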