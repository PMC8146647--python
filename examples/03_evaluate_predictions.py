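"""CAFA-style protein-centric evaluation of a targeted synthetic predictor.

Generates a gold standard for 500 genes and a prediction set constructed to
measure precision 0.8 and recall 0.6 after ancestral expansion, then runs
the full threshold sweep. Fmax is the maximum harmonic mean of dataset
precision and recall over score thresholds; tau_max is the threshold that
achieves it.
"""

from gofannot import (
    FixtureSpec,
    evaluate,
    make_gold,
    make_predictions,
    make_toy_ontology,
)

spec = FixtureSpec(seed=2029, n_genes=500)
graph = make_toy_ontology(spec)
gold = make_gold(spec, graph)
pred = make_predictions(gold, graph, spec)

report = evaluate(pred, gold, graph)
print(f"predictions: {len(pred)} records over {len(pred.genes())} genes\n")
print(f"{'aspect':8}{'Fmax':>8}{'tau_max':>9}{'Pr@min_tau':>12}{'Rc@min_tau':>12}")
for aspect, ev in report.per_aspect.items():
    print(f"{aspect:8}{ev.fmax:>8.3f}{ev.tau_max:>9.2f}"
          f"{ev.pr_at_min_tau[0]:>12.3f}{ev.rc_at_min_tau[0]:>12.3f}")
print(
    "\nAt the smallest threshold every prediction counts, so Pr/Rc there\n"
    "recover the generator's targets (0.8, 0.6); Fmax ~0.75 sits at the\n"
    "threshold separating the high-scoring true calls from the false ones."
)
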