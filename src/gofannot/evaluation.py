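"""Protein-centric evaluation: Pr(tau), Rc(tau) and Fmax per GO aspect.

Following the Clark & Radivojac protein-centric protocol used by the CAFA
assessments: both the prediction set and the gold standard are expanded to
their ancestral closures (namespace roots excluded), and at each score
threshold tau

* per-gene precision is |P_i(tau) ∩ T_i| / |P_i(tau)|, averaged over the
  genes that have at least one prediction at tau, and
* per-gene recall is |P_i(tau) ∩ T_i| / |T_i|, averaged over *all* benchmark
  genes — a gene with no prediction contributes zero recall.

F(tau) is the harmonic mean of the two dataset averages; Fmax is its maximum
over the threshold grid and is the headline single-number comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .annotations import ASPECTS, AnnotationSet, split_by_aspect
from .errors import EmptyBenchmarkError, UndefinedMetricError
from .ontology import OntologyGraph, propagate

#: CAFA-convention threshold grid: 0.01, 0.02, ..., 1.00.
TAU_GRID = tuple(i / 100 for i in range(1, 101))

_EPS = 1e-12  # guards float comparison of scores against grid thresholds


@dataclass(frozen=True)
class EvalCurve:
    """Precision/recall as functions of the score threshold."""

    thresholds: tuple[float, ...]
    pr: tuple[float, ...]       # NaN where no gene has a prediction at tau
    rc: tuple[float, ...]
    n_benchmark: int            # recall denominator: gold genes
    m_at_tau: tuple[int, ...]   # precision denominator: genes with >=1 prediction

    def f_scores(self) -> tuple[float, ...]:
        out = []
        for p, r in zip(self.pr, self.rc):
            if math.isnan(p) or p + r == 0:
                out.append(0.0)
            else:
                out.append(2 * p * r / (p + r))
        return tuple(out)


def fmax(curve: EvalCurve) -> tuple[float, float]:
    """Maximum F over the grid and the smallest threshold achieving it."""
    if not curve.thresholds:
        raise UndefinedMetricError("fmax of an empty curve is undefined")
    fs = curve.f_scores()
    best = max(fs)
    tau_max = curve.thresholds[fs.index(best)]  # first == smallest tau
    return best, tau_max


@dataclass(frozen=True)
class AspectEval:
    aspect: str
    curve: EvalCurve
    fmax: float
    tau_max: float
    # per-gene mean +/- SE of precision and recall, at tau_max and at the
    # smallest tau (all predictions admitted); both are reported because
    # published figures are ambiguous about which threshold their means use.
    pr_at_tau_max: tuple[float, float]
    rc_at_tau_max: tuple[float, float]
    pr_at_min_tau: tuple[float, float]
    rc_at_min_tau: tuple[float, float]


@dataclass(frozen=True)
class EvalReport:
    label: str
    gold_label: str
    per_aspect: dict[str, AspectEval]  # only aspects with gold annotations

    def to_json(self) -> str:
        out = {}
        for aspect, ev in self.per_aspect.items():
            out[aspect] = {
                "fmax": round(ev.fmax, 6),
                "tau_max": ev.tau_max,
                "n_benchmark": ev.curve.n_benchmark,
                "pr_at_tau_max": {"mean": round(ev.pr_at_tau_max[0], 6),
                                  "se": round(ev.pr_at_tau_max[1], 6)},
                "rc_at_tau_max": {"mean": round(ev.rc_at_tau_max[0], 6),
                                  "se": round(ev.rc_at_tau_max[1], 6)},
                "pr_at_min_tau": {"mean": round(ev.pr_at_min_tau[0], 6),
                                  "se": round(ev.pr_at_min_tau[1], 6)},
                "rc_at_min_tau": {"mean": round(ev.rc_at_min_tau[0], 6),
                                  "se": round(ev.rc_at_min_tau[1], 6)},
            }
        return json.dumps(
            {"prediction": self.label, "gold": self.gold_label, "aspects": out},
            indent=2,
        ) + "\n"

    def curves_tsv(self) -> str:
        lines = ["aspect\ttau\tpr\trc\tf"]
        for aspect, ev in self.per_aspect.items():
            for tau, p, r, f in zip(
                ev.curve.thresholds, ev.curve.pr, ev.curve.rc, ev.curve.f_scores()
            ):
                p_str = "" if math.isnan(p) else f"{p:.6f}"
                lines.append(f"{aspect}\t{tau:.2f}\t{p_str}\t{r:.6f}\t{f:.6f}")
        return "\n".join(lines) + "\n"


def _mean_se(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return (float("nan"), float("nan"))
    se = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return (float(arr.mean()), se)


def pr_rc_at_threshold(
    pred: AnnotationSet,
    gold: AnnotationSet,
    graph: OntologyGraph,
    tau: float,
    propagated: bool = False,
) -> tuple[float, float, dict[str, float], dict[str, float]]:
    """Dataset precision and recall at one threshold, plus per-gene values.

    ``pred`` and ``gold`` are propagated (roots excluded) unless the caller
    states they already are. Returns (precision, recall, per-gene precision
    for genes with predictions, per-gene recall for all benchmark genes).
    Precision is NaN when no benchmark gene has a prediction at ``tau``.
    """
    if not propagated:
        pred = propagate(graph, pred)
        gold = propagate(graph, gold)
    if not gold.records:
        raise UndefinedMetricError("gold standard is empty for this aspect")
    gold_terms = {g: {r.term for r in recs} for g, recs in gold.by_gene().items()}
    pred_scores: dict[str, dict[str, float]] = {}
    for r in pred.records:
        pred_scores.setdefault(r.gene, {})[r.term] = r.score

    per_gene_pr: dict[str, float] = {}
    per_gene_rc: dict[str, float] = {}
    for gene, t_set in gold_terms.items():
        p_set = {
            t for t, s in pred_scores.get(gene, {}).items() if s >= tau - _EPS
        }
        per_gene_rc[gene] = len(p_set & t_set) / len(t_set)
        if p_set:
            per_gene_pr[gene] = len(p_set & t_set) / len(p_set)
    precision = (
        sum(per_gene_pr.values()) / len(per_gene_pr) if per_gene_pr else float("nan")
    )
    recall = sum(per_gene_rc.values()) / len(per_gene_rc)
    return precision, recall, per_gene_pr, per_gene_rc


def evaluate(
    pred: AnnotationSet,
    gold: AnnotationSet,
    graph: OntologyGraph,
    thresholds: tuple[float, ...] = TAU_GRID,
) -> EvalReport:
    """Full protein-centric evaluation of ``pred`` against ``gold``.

    Per aspect: both sets are propagated with roots excluded, the threshold
    grid is swept, and Fmax with its (smallest) argmax threshold is reported
    together with per-gene mean +/- SE of precision and recall. The benchmark
    for an aspect is every gene with at least one gold annotation there,
    restricted to the prediction universe when one is defined. Aspects with
    no benchmark genes are omitted from the report.
    """
    if pred.universe is not None:
        gold = AnnotationSet(
            [r for r in gold.records if r.gene in pred.universe],
            label=gold.label,
        )
    if not gold.records:
        raise EmptyBenchmarkError(
            "no gold-standard gene overlaps the prediction universe"
        )
    gold_parts = split_by_aspect(gold, graph)
    pred_parts = split_by_aspect(
        AnnotationSet(pred.records, label=pred.label), graph
    )

    per_aspect: dict[str, AspectEval] = {}
    for aspect in ASPECTS:
        gold_a = propagate(graph, gold_parts[aspect])
        if not gold_a.records:
            continue
        pred_a = propagate(graph, pred_parts[aspect])
        prs, rcs, ms = [], [], []
        per_gene_at: dict[float, tuple[dict, dict]] = {}
        for tau in thresholds:
            p, r, pg_pr, pg_rc = pr_rc_at_threshold(
                pred_a, gold_a, graph, tau, propagated=True
            )
            prs.append(p)
            rcs.append(r)
            ms.append(len(pg_pr))
            per_gene_at[tau] = (pg_pr, pg_rc)
        curve = EvalCurve(
            thresholds=tuple(thresholds),
            pr=tuple(prs),
            rc=tuple(rcs),
            n_benchmark=len(gold_a.genes()),
            m_at_tau=tuple(ms),
        )
        best, tau_max = fmax(curve)
        pg_pr_best, pg_rc_best = per_gene_at[tau_max]
        pg_pr_min, pg_rc_min = per_gene_at[thresholds[0]]
        per_aspect[aspect] = AspectEval(
            aspect=aspect,
            curve=curve,
            fmax=best,
            tau_max=tau_max,
            pr_at_tau_max=_mean_se(list(pg_pr_best.values())),
            rc_at_tau_max=_mean_se(list(pg_rc_best.values())),
            pr_at_min_tau=_mean_se(list(pg_pr_min.values())),
            rc_at_min_tau=_mean_se(list(pg_rc_min.values())),
        )
    return EvalReport(label=pred.label, gold_label=gold.label, per_aspect=per_aspect)
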