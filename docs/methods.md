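# Methods

`gofannot` implements the computational core of a GO meta-annotation
workflow for plant genomes: cleaning and merging several prediction
datasets into one non-redundant aggregate, quantifying annotation sets, and
evaluating them against curated gold standards. This note documents the
models and conventions the package commits to, the knobs that matter, what
the synthetic-data generator does and does not emulate, and the numerical
choices behind the tests.

## The ontology model

The Gene Ontology is held as a directed acyclic graph per aspect
(cellular component, molecular function, biological process). Closure —
the ancestor set used by propagation, specificity, redundancy removal, and
evaluation — follows `is_a` and `part_of` edges by default. `part_of` is
included because annotation inheritance along part-whole relations is
standard practice for GO propagation; an `is_a`-only closure is available
through `OntologyGraph(relations={"is_a"})` for sensitivity analysis, since
published figures rarely state which convention they used. Closure never
crosses aspects; cross-namespace `part_of` edges are ignored.

Obsolete terms are recorded (so stale references in annotation files fail
loudly) but contribute no closure edges. `replaced_by` pointers are *not*
followed: silent remapping changes the meaning of an annotation, and the
caller should decide. Alt-ids resolve to their canonical accession on every
input path.

Validation at load time enforces: acyclicity (a violating cycle is reported
explicitly), a unique root per aspect, and reachability of the root from
every live term.

## Propagation and cleaning

Propagation applies the true-path rule: a record (gene, term, score)
implies (gene, ancestor, score) for every ancestor. When several records
reach the same term the maximum score survives — scores are confidences,
and the best-supported path should win — and contributing sources are
unioned into a sorted `+`-joined label, the same merge rule used by
deduplication so that merges are associative and order-free. Namespace
roots are dropped from propagated sets by default: a root annotation is
vacuously true and would let any predictor score perfect precision there.

Redundancy removal deletes, within each gene, records whose term is an
ancestor of another annotated term; what remains are the gene's most
specific (DAG-minimal) terms. The operation is information-preserving under
the true-path rule: the deleted records are exactly those propagation
regenerates. `aggregate()` is union → deduplicate → remove-redundancy;
because cleaning is confluent here, cleaning components first and then
aggregating gives the same result, which the test suite checks as
idempotence and input-order invariance.

## Analysis metrics

Per aspect and overall:

* **coverage** (%) — genes with ≥ 1 annotation over the full gene universe.
  The denominator is the whole genome for every aspect, so an aspect a
  method rarely predicts shows low coverage rather than a shrunken
  denominator.
* **annotations/gene** — total records / annotated genes; the standard
  error is computed over per-gene record counts.
* **specificity** — number of ancestors of the annotated term, averaged
  over annotations, SE over annotations. The term itself is excluded and
  the root included (a root annotation has specificity 0, a root's child
  1). Because published absolute values depend on that convention,
  `include_root=False` exposes the alternative, which shifts every value
  down by one.

Mean specificity usually rises under redundancy removal — removed
ancestors are shallower than the retained descendants — but this is a
statistical tendency, not a theorem: a deep-but-redundant record can sit
above the dataset mean while survivors elsewhere sit below it. The test
suite asserts the non-decrease on the generator's leaf-biased sets, where
it holds reliably; on adversarial sets it can fail.

## Protein-centric evaluation

Evaluation follows the protein-centric precision/recall protocol used by
the CAFA assessments. Both prediction and gold sets are propagated with
roots excluded. For gene *i* with propagated gold set *T_i* and predictions
*P_i(τ)* = {terms scoring ≥ τ}:

* precision_i = |P_i(τ) ∩ T_i| / |P_i(τ)|, averaged over genes with at
  least one prediction at τ (m(τ) genes);
* recall_i = |P_i(τ) ∩ T_i| / |T_i|, averaged over **all** benchmark genes
  (n genes) — a gene the method ignores contributes zero recall.

F(τ) is the harmonic mean of the two dataset averages (0 where undefined);
Fmax is its maximum over the grid τ ∈ {0.01, …, 1.00} in steps of 0.01,
with ties resolved to the smallest τ for deterministic reports. The
benchmark per aspect is every gene with ≥ 1 gold annotation there,
restricted to the prediction universe when one is declared; aspects with an
empty benchmark are omitted rather than reported as zero. Because figures
in the literature are ambiguous about the threshold at which mean ± SE
precision/recall are quoted, the report carries both the values at τ_max
and at the smallest τ, labelled.

A consequence of this protocol worth stating explicitly: when gold data are
incomplete, formerly-true predictions are counted as false positives, so
measured precision of a fixed predictor *drops* — the FP-inflation effect,
which the suite reproduces by deleting half the gold records (precision
dropped in 100/100 trials). Measured recall, by contrast, tends to *rise*
under the same deletion: propagated predictions are ancestor-closed and
therefore shallow-heavy, while deleting a gold record removes the deep,
leaf-exclusive part of the gold closure that the predictor was missing
anyway. Incomplete gold standards therefore bias benchmarks optimistically
on recall and pessimistically on precision at the same time.

## Gold inheritance and overlap comparison

`inherit_gold` projects curated records through a gene cross-reference map
(old release → new release, one-to-many allowed), deduplicating afterwards;
unmapped source genes are dropped with a logged count. Inherited gold sets
are deliberately *not* redundancy-reduced — curated sets may legitimately
assert ancestor terms.

`overlap_compare` expands gold and both prediction sets to their closures
(roots excluded) and classifies each gold entity as recovered by both
methods, one, or neither, at three granularities: annotations (expanded
gene-term pairs), terms, and genes. The four counts partition the gold
entities exactly, which is asserted on random inputs. Gene-level recovery
defaults to requiring at least one *correct* (gold-intersecting) expanded
prediction, keeping the three levels logically nested
(gene ⇐ term ⇐ annotation); `gene_mode="any"` gives the looser reading
(the method annotated the gene at all), since either interpretation is
defensible when comparing against published overlap tables.

## Sequence preparation and RBH transfer

`longest_isoform` keeps the longest translated transcript per gene, ties
broken to the lexicographically smallest transcript id, input gene order
preserved. The default header→gene rule strips one trailing transcript
suffix (`_T001`, `_P01`, `.1`, `-01`); genome releases differ, so a user
regex can replace it entirely. `sequence_stats` summarizes lengths and the
percentage of proteins strictly shorter than 50 residues — short proteins
carry little signal for sequence-based function prediction.

Reciprocal best hits are computed from BLAST-tabular text: the best hit per
query is the maximum bitscore, ties broken by minimum E-value; a residual
exact tie disqualifies the query by default, keeping the orthology claim
conservative (lexicographic resolution is opt-in). A pair is reported only
when best-ness is mutual, which makes the result a partial matching.
`transfer_by_rbh` then copies donor annotations across pairs with source
`rbh:<donor>`.

## The synthetic-data generator

The generator exists so that every stage is testable offline and every run
reproduces from a seed (one independent RNG stream per generator
operation, all derived from `FixtureSpec.seed`).

* **Ontology** — per aspect, a random rooted DAG: each new term attaches to
  one or two existing terms, parent choice weighted toward deeper terms so
  the requested depth is actually reached. Defaults: 40 terms/aspect,
  depth ≤ 6 — deep enough that propagation, redundancy, and specificity are
  non-trivial, small enough that brute-force oracles stay instant.
* **Gold standard** — 1–5 terms per gene per aspect, sampled with weight
  (1 + ancestors²) so annotations cluster near leaves, as curated
  annotations do; score 1.0; universe = all genes (200 by default).
* **Predictions** — built to measure back stated precision/recall targets
  (defaults 0.8/0.6) *after* propagation. The true part is an
  ancestor-closed subset of the propagated gold set, produced by deleting
  random leaf-most elements until the target recall fraction remains;
  closure-closedness means evaluation-time propagation adds nothing, so
  measured recall equals the target. False terms are drawn from same-aspect
  terms whose closure drags no unpredicted gold term along, greedily sized
  (with a final probabilistic acceptance) so the expected propagated false
  count is |S|(1−p)/p, putting measured precision at the target. True
  records score 0.9, false 0.5, independently jittered (σ = 0.05 default)
  and clamped to [0.01, 1]. Recovery is within ±0.01 of the targets at 500
  genes across seeds; the acceptance check allows ±0.05.

What the generator does **not** emulate: the real GO's scale and shape
(tens of thousands of terms, heavy multiple inheritance, regulates-type
relations), realistic per-tool score distributions, evidence-code
semantics, or correlated errors between prediction methods. Passing tests
therefore demonstrate the correctness of the algorithms and the internal
consistency of the metrics — not the field performance of any annotation
pipeline on a real genome, which depends on external databases and tools
out of scope here.

## Numerical and degenerate-input conventions

* Standard errors are sample SD / √n (ddof = 1), defined as 0 for n = 1.
* Score-vs-threshold comparison uses `score ≥ τ − 1e−12` to absorb float
  grid artifacts.
* Empty metric inputs raise a typed `UndefinedMetricError` (or report
  `None` fields inside composite reports) rather than returning 0, so
  "no data" is distinguishable from "measured zero". An empty benchmark
  raises `EmptyBenchmarkError`.
* Propagation that empties a nonempty set through root removal warns
  instead of failing (the input was root-only, which is legal but
  information-free).
* GAF output is sorted (gene, term) with fixed date/taxon placeholder
  columns, so re-runs are byte-identical; GAF carries no score column, so
  the round-trip contract covers (gene, term) pairs.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence checks use 100 random DAGs of ≤ 50 terms with annotation
sets of ≤ 200 records; self-evaluation identity uses 20 seeds × 12 genes;
parameter recovery uses 500 genes; aggregation/overlap properties use 20–50
random instances; the gold-deletion experiment uses 100 deletion seeds on a
60-gene fixture. These sizes give the statistical assertions comfortable
margins while keeping the whole suite in seconds.

## Known limitations

* Only `is_a`/`part_of` closures; `regulates`-family relations and
  cross-ontology links are out of scope.
* Blocklist filtering matches annotated terms exactly; filtering a whole
  branch requires pre-expanding the blocklist with descendants.
* No information-content (Resnik-style) specificity and no term-centric or
  weighted evaluation variants; `Smin` is not computed.
* The CLI reads uncompressed text only.
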