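"""Combine two annotation datasets into one clean aggregate.

Builds a three-term chain ontology (root <- parent <- leaf) and two tiny
prediction datasets that disagree in depth and score, then aggregates them:
duplicates collapse to the maximum score with sources unioned, and a record
to a term whose descendant is also annotated to the same gene is redundant
under the true-path rule and is dropped.
"""

from gofannot import (
    Annotation,
    AnnotationSet,
    GoTerm,
    OntologyGraph,
    aggregate,
    write_gaf,
)

BP = "biological_process"
graph = OntologyGraph([
    GoTerm("GO:0000001", "biological process (root)", BP),
    GoTerm("GO:0000002", "signaling", BP, parents=(("GO:0000001", "is_a"),)),
    GoTerm("GO:0000003", "kinase signaling", BP, parents=(("GO:0000002", "is_a"),)),
])

tool_x = AnnotationSet([
    Annotation("gene1", "GO:0000002", 0.6, "toolX"),   # the parent term
    Annotation("gene2", "GO:0000002", 0.9, "toolX"),
], label="toolX")
tool_y = AnnotationSet([
    Annotation("gene1", "GO:0000003", 0.8, "toolY"),   # a more specific call
    Annotation("gene2", "GO:0000002", 0.5, "toolY"),   # duplicate of toolX's
], label="toolY")

agg = aggregate([tool_x, tool_y], graph)

print("input records :", len(tool_x) + len(tool_y))
print("aggregate     :", len(agg))
for rec in sorted(agg.records, key=lambda r: r.gene):
    print(f"  {rec.gene}  {rec.term}  score={rec.score}  source={rec.source}")
print(
    "\ngene1's GO:0000002 record was removed as redundant (its descendant\n"
    "GO:0000003 is annotated to the same gene); gene2's duplicate collapsed\n"
    "to the max score 0.9 with sources joined. GAF output:\n"
)
print(write_gaf(agg, graph))
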