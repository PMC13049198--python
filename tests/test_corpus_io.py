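"""Corpus construction: parsing, architecture extraction, dedup, GO handling."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from archsem.corpus_io import (
    AnnotationMap,
    DomainArchitecture,
    DomainHit,
    OntologyGraph,
    annotate_architectures,
    corpus_from_architectures,
    deduplicate,
    extract_architectures,
    load_ontology,
    parse_domain_assignments,
    propagate_ancestors,
    read_corpus_jsonl,
    write_corpus_jsonl,
)


def _arch(*domains, proteins=("p1",)):
    return DomainArchitecture(domains=tuple(domains), proteins=frozenset(proteins))


class TestParsing:
    def test_row_maps_directly_to_hit(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("p1\tSF1\t10\t80\n")
        assert parse_domain_assignments(f) == [DomainHit("p1", "SF1", 10, 80)]

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("")
        assert parse_domain_assignments(f) == []

    def test_inverted_coordinates_row_skipped_with_warning(self, tmp_path, caplog):
        f = tmp_path / "a.tsv"
        f.write_text("p1\tSF1\t10\t80\np2\tSF2\t90\t20\n")
        with caplog.at_level(logging.WARNING, logger="archsem"):
            hits = parse_domain_assignments(f)
        assert [h.protein_id for h in hits] == ["p1"]
        assert "1 malformed" in caplog.text

    def test_header_line_is_tolerated(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("protein_id\tdomain_id\tstart\tend\np1\tSF1\t1\t5\n")
        assert len(parse_domain_assignments(f)) == 1

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(OSError):
            parse_domain_assignments(tmp_path / "nope.tsv")


class TestExtraction:
    def test_maguk_architecture_in_n_to_c_order(self):
        hits = [
            DomainHit("mpp6", "L27", 1, 60),
            DomainHit("mpp6", "L27", 70, 130),
            DomainHit("mpp6", "PDZ", 150, 230),
            DomainHit("mpp6", "SH3", 240, 300),
            DomainHit("mpp6", "GuK", 320, 500),
        ]
        archs = extract_architectures(hits)
        assert archs["mpp6"].domains == ("L27", "L27", "PDZ", "SH3", "GuK")

    def test_single_hit_gives_length_one(self):
        archs = extract_architectures([DomainHit("p", "SF", 5, 9)])
        assert len(archs["p"]) == 1

    def test_unsorted_input_ordered_by_start(self):
        hits = [DomainHit("p", "B", 200, 300), DomainHit("p", "A", 10, 90)]
        assert extract_architectures(hits)["p"].domains == ("A", "B")

    def test_overlap_ties_break_by_end_then_id(self):
        hits = [DomainHit("p", "Z", 10, 50), DomainHit("p", "A", 10, 50), DomainHit("p", "M", 10, 40)]
        assert extract_architectures(hits)["p"].domains == ("M", "A", "Z")


class TestDeduplication:
    def test_identical_sequences_merge_proteins(self):
        corpus = deduplicate(
            {"p1": _arch("A", "B", proteins=("p1",)), "p2": _arch("A", "B", proteins=("p2",))}
        )
        assert corpus.N == 1
        assert corpus.architectures[0].proteins == frozenset({"p1", "p2"})

    def test_ngram_counts_over_unique_das(self):
        corpus = corpus_from_architectures([_arch("A", "B"), _arch("A", "C")])
        assert dict(corpus.unigram_counts) == {"A": 2, "B": 1, "C": 1}
        assert dict(corpus.bigram_counts) == {("A", "B"): 1, ("A", "C"): 1}

    def test_repeat_domain_bigrams(self):
        corpus = corpus_from_architectures([_arch("A", "A", "B")])
        assert dict(corpus.bigram_counts) == {("A", "A"): 1, ("A", "B"): 1}

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.lists(st.sampled_from("ABCDE"), min_size=1, max_size=4),
            min_size=1,
            max_size=12,
        )
    )
    def test_dedup_idempotent_and_bounded(self, seqs):
        archs = [_arch(*s, proteins=(f"p{i}",)) for i, s in enumerate(seqs)]
        c1 = corpus_from_architectures(archs)
        c2 = corpus_from_architectures(c1.architectures)
        assert [a.domains for a in c1.architectures] == [a.domains for a in c2.architectures]
        assert c1.unigram_counts == c2.unigram_counts
        assert c1.N <= len(seqs)

    def test_jsonl_round_trip(self, tmp_path):
        c1 = corpus_from_architectures([_arch("A", "B"), _arch("C")])
        write_corpus_jsonl(c1, tmp_path / "c.jsonl")
        c2 = read_corpus_jsonl(tmp_path / "c.jsonl")
        assert c1.keys() == c2.keys()
        assert c1.bigram_counts == c2.bigram_counts


class TestOntology:
    def test_is_a_and_part_of_edges_retained(self, toy_obo):
        g = load_ontology(toy_obo)
        assert g.graph.has_edge("GO:0000002", "GO:0000001")
        assert g.graph.has_edge("GO:0000003", "GO:0000002")

    def test_regulates_edge_not_retained(self, toy_obo):
        g = load_ontology(toy_obo)
        assert not g.graph.has_edge("GO:0000004", "GO:0000002")
        assert g.graph.has_edge("GO:0000004", "GO:0000001")

    def test_obsolete_term_absent(self, toy_obo):
        assert "GO:0000005" not in load_ontology(toy_obo).terms

    def test_root_only_input_unchanged(self, toy_obo):
        g = load_ontology(toy_obo)
        assert propagate_ancestors({"GO:0000001"}, g) == {"GO:0000001"}

    def test_transitive_closure_through_mixed_relations(self, toy_obo):
        g = load_ontology(toy_obo)
        closed = propagate_ancestors({"GO:0000003"}, g)
        assert closed == {"GO:0000003", "GO:0000002", "GO:0000001"}

    def test_closure_is_idempotent(self, toy_obo):
        g = load_ontology(toy_obo)
        once = propagate_ancestors({"GO:0000003", "GO:0000002"}, g)
        assert propagate_ancestors(once, g) == once

    def test_unknown_term_passes_through(self, toy_obo):
        g = load_ontology(toy_obo)
        assert "GO:9999999" in propagate_ancestors({"GO:9999999"}, g)


class TestAnnotation:
    @pytest.fixture()
    def graph(self, toy_obo):
        return load_ontology(toy_obo)

    def test_single_protein_terms_are_closed(self, graph):
        corpus = corpus_from_architectures([_arch("A", "B", proteins=("p1",))])
        ann = annotate_architectures(corpus, {"p1": {"GO:0000003"}}, graph, "MF")
        assert ann.get(("A", "B")) == {"GO:0000003", "GO:0000002", "GO:0000001"}

    def test_half_threshold_is_inclusive(self, graph):
        corpus = corpus_from_architectures(
            [_arch("A", "B", proteins=("p1", "p2"))]
        )
        go = {"p1": {"GO:0000003", "GO:0000004"}, "p2": {"GO:0000003"}}
        ann = annotate_architectures(corpus, go, graph, "MF")
        # GO:0000004 is in exactly 1/2 of the proteins: kept
        assert "GO:0000004" in ann.get(("A", "B"))

    def test_minority_term_dropped(self, graph):
        corpus = corpus_from_architectures([_arch("A", "B", proteins=("p1", "p2", "p3"))])
        go = {"p1": {"GO:0000004"}, "p2": {"GO:0000003"}, "p3": {"GO:0000003"}}
        ann = annotate_architectures(corpus, go, graph, "MF")
        assert "GO:0000004" not in ann.get(("A", "B"))

    def test_raising_threshold_never_adds_terms(self, graph):
        corpus = corpus_from_architectures([_arch("A", "B", proteins=("p1", "p2", "p3"))])
        go = {"p1": {"GO:0000003", "GO:0000004"}, "p2": {"GO:0000003"}, "p3": {"GO:0000004"}}
        lo = annotate_architectures(corpus, go, graph, "MF", threshold=0.3)
        hi = annotate_architectures(corpus, go, graph, "MF", threshold=0.7)
        assert hi.get(("A", "B")) <= lo.get(("A", "B"))

    def test_annotation_sets_closed_under_ancestors(self, synth):
        _, _, _, annotations, graph = synth
        for key, terms in annotations["MF"].terms_for.items():
            assert propagate_ancestors(terms, graph) == terms

    def test_protein_binding_only_da_removed_from_mf(self, tmp_path):
        obo = tmp_path / "pb.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: r\n"
            "namespace: molecular_function\n\n[Term]\nid: GO:0005515\n"
            "name: protein binding\nnamespace: molecular_function\nis_a: GO:0000001\n"
        )
        graph = load_ontology(obo)
        corpus = corpus_from_architectures(
            [_arch("A", "B", proteins=("p1",)), _arch("C", "D", proteins=("p2",))]
        )
        go = {"p1": {"GO:0005515"}, "p2": {"GO:0005515", "GO:0000001"}}
        ann = annotate_architectures(corpus, go, graph, "MF")
        assert ("A", "B") not in ann.annotated_multidomain
        assert ("C", "D") not in ann.annotated_multidomain  # same closure
        assert ann.annotated_multidomain == set()

    def test_single_domain_das_excluded_from_evaluation_set(self, graph):
        corpus = corpus_from_architectures([_arch("A", proteins=("p1",))])
        ann = annotate_architectures(corpus, {"p1": {"GO:0000003"}}, graph, "MF")
        assert ann.get(("A",))  # annotated
        assert ("A",) not in ann.annotated_multidomain

    def test_empty_associations_give_empty_evaluation_set(self, graph):
        corpus = corpus_from_architectures([_arch("A", "B")])
        ann = annotate_architectures(corpus, {}, graph, "MF")
        assert ann.annotated_multidomain == set()
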