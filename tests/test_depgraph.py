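"""Graph model, CoNLL-U round-trips, and subtree yields."""

import random

import pytest

from tweetcause.depgraph import (
    ConlluParseError,
    DependencyEdge,
    DependencyGraph,
    GraphIntegrityError,
    Token,
    read_conllu,
    subtree_yield,
    write_conllu,
)
from tweetcause.fixtures import gold_fixtures

from conftest import random_graph


def all_fixture_graphs():
    return [ex.graph for ex in gold_fixtures()]


class TestConlluRoundTrip:
    def test_read_write_identity_on_all_fixtures(self):
        graphs = all_fixture_graphs()
        doc = write_conllu(graphs)
        assert read_conllu(doc) == graphs

    def test_write_is_idempotent_through_read(self):
        doc = write_conllu(all_fixture_graphs())
        assert write_conllu(read_conllu(doc)) == doc

    def test_single_token_graph_block(self):
        g = DependencyGraph(
            "one/0", "hi", [Token(1, "hi", "hi", "INTJ", "UH")],
            [DependencyEdge(0, 1, "root")],
        )
        doc = write_conllu([g])
        lines = doc.splitlines()
        assert lines[0] == "# sent_id = one/0"
        assert lines[2].startswith("1\thi\thi\tINTJ\tUH")
        assert doc.endswith("\n")

    def test_deprel_column_of_simple_transitive_sentence(self, fixtures_by_slug):
        g = fixtures_by_slug["stress-causes-insomnia"].graph
        deprels = [line.split("\t")[7] for line in write_conllu([g]).splitlines()
                   if line and not line.startswith("#")]
        assert deprels == ["nsubj", "root", "dobj"]


class TestConlluReader:
    def test_empty_document_gives_no_graphs(self):
        assert read_conllu("") == []

    def test_simple_block_structure(self, fixtures_by_slug):
        g = read_conllu(write_conllu([fixtures_by_slug["stress-causes-insomnia"].graph]))[0]
        assert [t.form for t in g.tokens] == ["Stress", "causes", "insomnia"]
        assert DependencyEdge(2, 1, "nsubj") in g.edges
        assert DependencyEdge(2, 3, "dobj") in g.edges
        assert DependencyEdge(0, 2, "root") in g.edges
        assert g.text == "Stress causes insomnia"

    def test_wrong_column_count_names_line(self):
        with pytest.raises(ConlluParseError, match="line 1"):
            read_conllu("1\tfoo\tfoo\n")

    def test_non_integer_head_names_line(self):
        bad = "\t".join(["1", "x", "x", "X", "X", "_", "zero", "root", "_", "_"])
        with pytest.raises(ConlluParseError, match="line 2.*head"):
            read_conllu("# text = x\n" + bad + "\n")

    def test_dangling_head_is_structural_error(self):
        bad = "\t".join(["1", "x", "x", "X", "X", "_", "9", "dep", "_", "_"])
        with pytest.raises(GraphIntegrityError, match="head 9"):
            read_conllu(bad + "\n")

    def test_multiword_and_empty_node_rows_are_skipped(self, caplog):
        rows = [
            "1-2\tdon't\t_\t_\t_\t_\t_\t_\t_\t_",
            "\t".join(["1", "do", "do", "AUX", "VBP", "_", "0", "root", "_", "_"]),
            "\t".join(["2", "n't", "not", "PART", "RB", "_", "1", "neg", "_", "_"]),
            "2.1\telided\t_\t_\t_\t_\t_\t_\t_\t_",
        ]
        with caplog.at_level("WARNING"):
            graphs = read_conllu("\n".join(rows) + "\n")
        assert len(graphs[0].tokens) == 2
        assert any("skipping" in r.message for r in caplog.records)

    def test_deps_column_yields_multiple_governors(self):
        rows = [
            "\t".join(["1", "a", "a", "X", "X", "_", "0", "root", "0:root", "_"]),
            "\t".join(["2", "b", "b", "X", "X", "_", "1", "dep", "1:dep|1:conj", "_"]),
        ]
        g = read_conllu("\n".join(rows) + "\n")[0]
        assert set(g.governors_of(2)) == {("dep", 1), ("conj", 1)}


class TestGraphInvariants:
    def test_duplicate_token_index_rejected(self):
        with pytest.raises(GraphIntegrityError, match="duplicate"):
            DependencyGraph(
                "x", "a a", [Token(1, "a"), Token(1, "a")],
                [DependencyEdge(0, 1, "root")],
            ).validate()

    def test_self_loop_rejected(self):
        with pytest.raises(GraphIntegrityError, match="self-loop"):
            DependencyGraph(
                "x", "a", [Token(1, "a")],
                [DependencyEdge(0, 1, "root"), DependencyEdge(1, 1, "dep")],
            ).validate()

    def test_rootless_graph_rejected(self):
        with pytest.raises(GraphIntegrityError, match="root"):
            DependencyGraph(
                "x", "a b", [Token(1, "a"), Token(2, "b")],
                [DependencyEdge(1, 2, "dep")],
            ).validate()

    def test_all_fixtures_validate(self):
        for g in all_fixture_graphs():
            g.validate()


class TestSubtreeYield:
    def test_multiword_subject_phrase(self, fixtures_by_slug):
        g = fixtures_by_slug["missing-someone-causes-insomnia"].graph
        assert subtree_yield(g, 2) == "Missing someone"

    def test_leaf_yields_own_form(self, fixtures_by_slug):
        g = fixtures_by_slug["stress-causes-insomnia"].graph
        assert subtree_yield(g, 1) == "Stress"

    def test_exclusion_removes_whole_subtree(self, fixtures_by_slug):
        g = fixtures_by_slug["my-neck-just-made-my-headache-worse"].graph
        # excluding the verb cuts off everything below it
        assert subtree_yield(g, 4, exclude={6, 8}) == "My neck just made"

    def test_root_yield_is_full_sentence_without_punctuation(self):
        for ex in gold_fixtures():
            g = ex.graph
            root = next(d for r, d in g.dependents_of(0))
            expected = " ".join(
                t.form for t in g.tokens if t.upos != "PUNCT"
            )
            assert subtree_yield(g, root) == expected, ex.record.record_id

    def test_unknown_node_raises(self, fixtures_by_slug):
        g = fixtures_by_slug["stress-causes-insomnia"].graph
        with pytest.raises(KeyError):
            subtree_yield(g, 99)

    def test_cycle_terminates_via_visited_guard(self):
        g = DependencyGraph(
            "cyc/0", "a b",
            [Token(1, "a", "a", "X", "X"), Token(2, "b", "b", "X", "X")],
            [
                DependencyEdge(0, 1, "root"),
                DependencyEdge(1, 2, "dep"),
                DependencyEdge(2, 1, "dep"),
            ],
        )
        assert subtree_yield(g, 1) == "a b"

    def test_yield_matches_transitive_closure_oracle(self):
        rng = random.Random(20240)
        for _ in range(150):
            g = random_graph(rng)
            for tok in g.tokens:
                # brute-force closure of governor->dependent edges
                reach = {tok.index}
                changed = True
                while changed:
                    changed = False
                    for e in g.edges:
                        if e.governor in reach and e.dependent not in reach:
                            reach.add(e.dependent)
                            changed = True
                expected = " ".join(
                    t.form
                    for t in g.tokens
                    if t.index in reach and t.upos != "PUNCT"
                )
                assert subtree_yield(g, tok.index) == expected
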