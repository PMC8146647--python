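"""Coverage, annotations/gene, and specificity of a synthetic dataset.

Generates a toy ontology and a leaf-biased curated-style annotation set for
200 genes, then prints the three analysis metrics per GO aspect. Coverage is
the percentage of the gene universe with at least one annotation;
annotations/gene averages record counts over annotated genes; specificity is
the mean number of ancestors of the annotated terms — deeper terms have more
ancestors and carry more information.
"""

from gofannot import FixtureSpec, analysis_report, make_gold, make_toy_ontology

spec = FixtureSpec(seed=42)          # 40 terms/aspect, 200 genes
graph = make_toy_ontology(spec)
gold = make_gold(spec, graph)

report = analysis_report(gold, graph)
print(f"dataset: {gold.label}   universe: {len(gold.universe)} genes\n")
print(f"{'aspect':8}{'coverage%':>10}{'ann/gene':>10}{'(se)':>8}"
      f"{'specificity':>13}{'(se)':>8}")
for aspect in ("CC", "MF", "BP", "all"):
    m = report.per_aspect[aspect]
    print(f"{aspect:8}{m.coverage_pct:>10.2f}"
          f"{m.annotations_per_gene.mean:>10.2f}"
          f"{m.annotations_per_gene.se:>8.3f}"
          f"{m.specificity.mean:>13.2f}{m.specificity.se:>8.3f}")
print(
    "\nEvery gene gets 1-5 terms per aspect by construction, so coverage is\n"
    "100% everywhere; specificity ~6 reflects the leaf-biased sampling on\n"
    "the depth-6 toy DAG (multiple inheritance gives leaves many ancestors)."
)
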