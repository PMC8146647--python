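"""GAF/TSV I/O and aggregation-stage cleaning."""

import random

import pytest

from gofannot import (
    Annotation,
    AnnotationSet,
    aggregate,
    deduplicate,
    filter_blocklist,
    read_gaf,
    read_scored_tsv,
    remove_redundancy,
    split_by_aspect,
    write_gaf,
)
from gofannot.errors import ParseError, UsageError

from conftest import A, B, R, aset, bf_remove_redundancy, random_annotations, random_dag


def gaf_line(gene, term, qualifier="", aspect="P", evidence="IEA"):
    cols = ["DB", gene, gene, qualifier, term, "GO_REF:0000000", evidence, "",
            aspect, "", "", "protein", "taxon:1", "20200101", "src", "", ""]
    return "\t".join(cols)


class TestReadGaf:
    def test_single_valid_line(self, chain_graph):
        s = read_gaf("!gaf-version: 2.0\n" + gaf_line("g1", B), chain_graph)
        assert len(s) == 1
        rec = s.records[0]
        assert (rec.gene, rec.term, rec.score) == ("g1", B, 1.0)

    def test_not_qualifier_is_dropped(self, chain_graph):
        s = read_gaf(gaf_line("g1", B, qualifier="NOT"), chain_graph)
        assert len(s) == 0

    def test_alt_id_is_canonicalised(self):
        from gofannot import parse_obo
        from test_ontology import TOY_OBO

        g = parse_obo(TOY_OBO)
        s = read_gaf(gaf_line("g1", "GO:0000042"), g)
        assert s.records[0].term == A

    def test_column_count_mismatch_names_line(self, chain_graph):
        with pytest.raises(ParseError, match="line 2"):
            read_gaf(gaf_line("g1", B) + "\ng1\t" + B, chain_graph)

    def test_aspect_contradiction_warns_and_trusts_ontology(self, chain_graph):
        with pytest.warns(UserWarning, match="aspect"):
            s = read_gaf(gaf_line("g1", B, aspect="C"), chain_graph)
        assert chain_graph.aspect(s.records[0].term) == "BP"


class TestReadScoredTsv:
    def test_basic_row(self, chain_graph):
        s = read_scored_tsv(f"g1\t{B}\t0.9\ttoolX\n", chain_graph)
        assert len(s) == 1
        assert s.records[0].score == 0.9
        assert s.records[0].source == "toolX"

    def test_score_out_of_range_raises(self, chain_graph):
        with pytest.raises(ParseError, match="line 1"):
            read_scored_tsv(f"g1\t{B}\t1.5\ttoolX\n", chain_graph)

    def test_non_numeric_score_after_header_raises(self, chain_graph):
        text = f"gene\tterm\tscore\tsource\ng1\t{B}\tbad\tx\n"
        with pytest.raises(ParseError, match="line 2"):
            read_scored_tsv(text, chain_graph)

    def test_empty_file_gives_empty_set(self, chain_graph):
        assert len(read_scored_tsv("", chain_graph)) == 0

    def test_header_row_is_tolerated(self, chain_graph):
        s = read_scored_tsv(f"gene\tterm\tscore\tsource\ng1\t{B}\t0.4\tx\n", chain_graph)
        assert len(s) == 1


class TestWriteGaf:
    def test_round_trip_preserves_pairs(self, chain_graph):
        s = aset(("g1", B, 0.9), ("g2", A, 0.5), ("g1", A, 0.2))
        back = read_gaf(write_gaf(s, chain_graph), chain_graph)
        assert back.pairs() == s.pairs()

    def test_bp_terms_get_aspect_p(self, chain_graph):
        line = write_gaf(aset(("g1", B)), chain_graph).splitlines()[1]
        assert line.split("\t")[8] == "P"

    def test_empty_set_writes_header_only(self, chain_graph):
        assert write_gaf(aset(), chain_graph) == "!gaf-version: 2.0\n"

    def test_output_is_deterministic(self, chain_graph):
        s = aset(("g2", A, 0.5), ("g1", B, 0.9))
        assert write_gaf(s, chain_graph) == write_gaf(s, chain_graph)


class TestDeduplicate:
    def test_max_score_and_source_union(self):
        s = aset(("g1", B, 0.7, "s1"), ("g1", B, 0.9, "s2"))
        out = deduplicate(s)
        assert len(out) == 1
        assert out.records[0].score == 0.9
        assert out.records[0].source == "s1+s2"

    def test_already_unique_unchanged(self):
        s = aset(("g1", B, 0.7), ("g2", B, 0.9))
        assert deduplicate(s) == s

    def test_three_sources_same_pair(self):
        s = aset(("g1", B, 0.2, "x"), ("g1", B, 0.5, "y"), ("g1", B, 0.5, "z"))
        out = deduplicate(s)
        assert len(out) == 1
        assert out.records[0].score == 0.5
        assert out.records[0].source == "x+y+z"


class TestRemoveRedundancy:
    def test_ancestor_removed_on_chain(self, chain_graph):
        out = remove_redundancy(aset(("g1", A), ("g1", B)), chain_graph)
        assert out.pairs() == {("g1", B)}

    def test_siblings_untouched(self, sibling_graph):
        s = aset(("g1", "GO:0000003"), ("g1", "GO:0000004"))
        assert remove_redundancy(s, sibling_graph).pairs() == s.pairs()

    def test_redundancy_is_within_gene_only(self, chain_graph):
        s = aset(("g1", A), ("g2", B))
        assert remove_redundancy(s, chain_graph).pairs() == s.pairs()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = random.Random(seed)
        graph, edges = random_dag(rng, n_terms=rng.randint(5, 40), n_aspects=2)
        s = random_annotations(rng, graph, n_genes=6, max_records=200)
        got = remove_redundancy(s, graph)
        expect = bf_remove_redundancy(s.records, edges)
        assert got.pairs() == {(r.gene, r.term) for r in expect}


class TestAggregate:
    def test_single_set_equals_clean(self, chain_graph):
        s = aset(("g1", A, 0.3), ("g1", B, 0.8), ("g1", B, 0.5, "other"))
        assert aggregate([s], chain_graph) == remove_redundancy(
            deduplicate(s), chain_graph
        )

    def test_union_then_redundancy_rule(self, chain_graph):
        x = aset(("g1", A), label="x")
        y = aset(("g1", B), label="y")
        assert aggregate([x, y], chain_graph).pairs() == {("g1", B)}

    def test_disjoint_gene_sets_sum(self, chain_graph):
        x = aset(("g1", A), ("g1", B), label="x")
        y = aset(("g2", B), label="y")
        agg = aggregate([x, y], chain_graph)
        clean = lambda s: remove_redundancy(deduplicate(s), chain_graph)
        assert len(agg) == len(clean(x)) + len(clean(y))

    def test_idempotent_and_order_invariant(self, diamond_graph):
        x = aset(("g1", "GO:0000004", 0.9), ("g1", "GO:0000002", 0.4), label="x")
        y = aset(("g2", "GO:0000003", 0.6), ("g1", "GO:0000003", 0.7), label="y")
        once = aggregate([x, y], diamond_graph)
        assert aggregate([once], diamond_graph) == once
        assert aggregate([y, x], diamond_graph) == once

    def test_empty_input_list_raises(self, chain_graph):
        with pytest.raises(UsageError):
            aggregate([], chain_graph)


class TestBlocklistAndSplit:
    def test_blocklist_removes_exact_terms(self, sibling_graph):
        s = aset(("g1", "GO:0000003"), ("g1", "GO:0000004"))
        out = filter_blocklist(s, {"GO:0000004"})
        assert out.pairs() == {("g1", "GO:0000003")}

    def test_empty_blocklist_is_identity(self, chain_graph):
        s = aset(("g1", B))
        assert filter_blocklist(s, set()) == s

    def test_full_blocklist_empties_set(self, chain_graph):
        assert len(filter_blocklist(aset(("g1", A), ("g1", B)), {A, B})) == 0

    def test_split_counts_by_aspect(self):
        rng = random.Random(0)
        graph, _ = random_dag(rng, n_terms=10, n_aspects=3)
        s = random_annotations(rng, graph, n_genes=5, max_records=60)
        parts = split_by_aspect(s, graph)
        assert set(parts) == {"CC", "MF", "BP"}
        assert sum(len(p) for p in parts.values()) == len(s)
        assert all(p.universe == s.universe for p in parts.values())

    def test_split_empty_set(self, chain_graph):
        parts = split_by_aspect(aset(), chain_graph)
        assert all(len(p) == 0 for p in parts.values())


class TestAnnotationSetInvariants:
    def test_score_range_enforced(self):
        with pytest.raises(ValueError):
            Annotation("g1", B, 0.0)
        with pytest.raises(ValueError):
            Annotation("g1", B, 1.2)

    def test_universe_must_cover_annotated_genes(self):
        with pytest.raises(UsageError):
            AnnotationSet([Annotation("g9", B)], universe={"g1"})
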