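"""Trigger lexicon, rule compilation, and triple extraction semantics."""

import random

import pytest

from tweetcause.depgraph import DependencyEdge, DependencyGraph, Token
from tweetcause.fixtures import gold_fixtures
from tweetcause.rules import (
    CausalTriple,
    DirectionPolicy,
    compile_rules,
    default_lexicon,
    extract_triples,
    rules_from_config,
    rules_to_config,
)
from tweetcause.synthgen import DistractorKind, SynthConfig, generate_corpus


def _svo(verb_form, verb_xpos, sent_id="svo/0"):
    """Minimal '<Subj> <verb> insomnia' graph with lemma 'cause'."""
    return DependencyGraph(
        sent_id,
        f"Stress {verb_form} insomnia",
        [
            Token(1, "Stress", "stress", "NOUN", "NN"),
            Token(2, verb_form, "cause", "VERB", verb_xpos),
            Token(3, "insomnia", "insomnia", "NOUN", "NN"),
        ],
        [
            DependencyEdge(0, 2, "root"),
            DependencyEdge(2, 1, "nsubj"),
            DependencyEdge(2, 3, "dobj"),
        ],
    )


class TestLexicon:
    def test_published_lexicon_sizes(self):
        lex = default_lexicon()
        assert len(lex.verbs) == 7
        assert len(lex.nouns) == 3

    def test_published_lexicon_contents(self):
        lex = default_lexicon()
        assert lex.verbs == {
            "cause", "stimulate", "make", "derive", "trigger", "result", "lead"
        }
        assert lex.nouns == {"result", "reason", "cause"}
        assert lex.phrasal_preps == {"in", "to", "from"}

    def test_ambiguous_synonyms_excluded(self):
        lex = default_lexicon()
        assert "do" not in lex.verbs | lex.nouns
        assert "get" not in lex.verbs | lex.nouns


class TestRuleCompilation:
    def test_six_rules_with_unique_ids(self):
        rules = compile_rules()
        assert [r.rule_id for r in rules] == [1, 2, 3, 4, 5, 6]

    def test_capture_names_distinct_within_each_rule(self):
        for r in compile_rules():
            names = {r.cause_capture, r.effect_capture, r.trigger_capture}
            assert len(names) == 3

    def test_direction_policies(self):
        policies = {r.rule_id: r.direction_policy for r in compile_rules()}
        assert policies[4] is DirectionPolicy.FLIP_ON_RESULT_NOUN
        assert policies[6] is DirectionPolicy.FLIP_ON_FROM
        assert all(
            policies[i] is DirectionPolicy.FIXED for i in (1, 2, 3, 5)
        )

    def test_config_round_trip(self):
        rules = compile_rules()
        assert rules_from_config(rules_to_config(rules)) == rules

    def test_config_loaded_rules_extract_identically(self, fixtures_by_slug):
        ex = fixtures_by_slug["missing-someone-causes-insomnia"]
        reloaded = rules_from_config(rules_to_config(compile_rules()))
        assert extract_triples(ex.graph, {"insomnia"}, reloaded) == extract_triples(
            ex.graph, {"insomnia"}
        )


class TestExtraction:
    def test_passive_agent_is_the_cause(self, fixtures_by_slug):
        ex = fixtures_by_slug["insomnia-was-caused-by-stress"]
        (t,) = extract_triples(ex.graph, {"insomnia"})
        assert t.rule_id == 3
        assert t.cause == "stress" and t.cause_head == 6
        assert t.effect == "insomnia" and t.effect_head == 2

    def test_result_of_flips_direction(self, fixtures_by_slug):
        ex = fixtures_by_slug["insomnia-is-a-result-of-stress"]
        (t,) = extract_triples(ex.graph, {"insomnia"})
        assert t.rule_id == 4
        assert t.cause == "stress"
        assert t.effect == "insomnia"

    def test_reason_of_keeps_direction(self, fixtures_by_slug):
        ex = fixtures_by_slug["stress-is-a-reason-of-my-insomnia"]
        (t,) = extract_triples(ex.graph, {"insomnia"})
        assert t.cause == "Stress" and t.effect == "insomnia"

    def test_results_from_flips_direction(self):
        g = DependencyGraph(
            "from/0",
            "Insomnia results from stress",
            [
                Token(1, "Insomnia", "insomnia", "NOUN", "NN"),
                Token(2, "results", "result", "VERB", "VBZ"),
                Token(3, "from", "from", "ADP", "IN"),
                Token(4, "stress", "stress", "NOUN", "NN"),
            ],
            [
                DependencyEdge(0, 2, "root"),
                DependencyEdge(2, 1, "nsubj"),
                DependencyEdge(4, 3, "case"),
                DependencyEdge(2, 4, "nmod:from"),
            ],
        )
        (t,) = extract_triples(g, {"insomnia"})
        assert t.rule_id == 6
        assert t.cause == "stress" and t.cause_head == 4
        assert t.effect == "insomnia" and t.effect_head == 1

    def test_trigger_inflections_share_one_behavior(self):
        triples = [
            extract_triples(_svo(form, xpos), {"insomnia"})[0]
            for form, xpos in [
                ("causes", "VBZ"), ("caused", "VBD"), ("causing", "VBG")
            ]
        ]
        assert all(t.trigger == "cause" for t in triples)
        assert len({(t.cause, t.effect, t.rule_id) for t in triples}) == 1

    def test_effect_matched_on_lemma_covers_plurals(self, fixtures_by_slug):
        ex = fixtures_by_slug["you-are-the-cause-of-my-headaches"]
        (t,) = extract_triples(ex.graph, {"headache"})
        assert t.cause == "You" and t.trigger == "cause" and t.rule_id == 4
        assert t.effect == "headache"

    def test_conjunct_effect_is_reachable(self, fixtures_by_slug):
        ex = fixtures_by_slug["nervous-stressed-leads-to-headaches"]
        (t,) = extract_triples(ex.graph, {"headache"})
        assert t.rule_id == 6 and t.effect_head == 8

    def test_effect_filter_yields_nothing_without_target_lemma(self, fixtures_by_slug):
        ex = fixtures_by_slug["money-only-causes-stress"]
        assert extract_triples(ex.graph, {"insomnia"}) == []

    def test_one_triple_per_rule_and_keyword(self):
        g = DependencyGraph(
            "conj/0",
            "Money causes stress and insomnia",
            [
                Token(1, "Money", "money", "NOUN", "NN"),
                Token(2, "causes", "cause", "VERB", "VBZ"),
                Token(3, "stress", "stress", "NOUN", "NN"),
                Token(4, "and", "and", "CCONJ", "CC"),
                Token(5, "insomnia", "insomnia", "NOUN", "NN"),
            ],
            [
                DependencyEdge(0, 2, "root"),
                DependencyEdge(2, 1, "nsubj"),
                DependencyEdge(2, 3, "dobj"),
                DependencyEdge(5, 4, "cc"),
                DependencyEdge(3, 5, "conj"),
                DependencyEdge(2, 5, "dobj"),  # propagated conjunct object
            ],
        )
        triples = extract_triples(g, {"stress", "insomnia"})
        assert sorted(t.effect for t in triples) == ["insomnia", "stress"]
        assert all(t.rule_id == 1 and t.cause == "Money" for t in triples)

    def test_empty_effect_set_rejected(self, fixtures_by_slug):
        with pytest.raises(ValueError):
            extract_triples(
                fixtures_by_slug["stress-causes-insomnia"].graph, set()
            )

    def test_noun_trigger_does_not_fire_verb_rules(self, fixtures_by_slug):
        # "cause/NN" must dispatch to the copular rule only
        ex = fixtures_by_slug["school-is-the-main-cause-of-my-stress"]
        triples = extract_triples(ex.graph, {"stress"})
        assert [t.rule_id for t in triples] == [4]

    def test_gold_fixture_triples_are_recovered_exactly(self):
        for ex in gold_fixtures():
            if not ex.gold_triples:
                continue
            got = tuple(extract_triples(ex.graph, {ex.topic}))
            assert got == ex.gold_triples, ex.record.record_id


class TestExtractionInvariants:
    def test_rule_ids_and_effects_are_well_formed(self):
        cfg = SynthConfig(n_sentences=200, seed=31, distractor_rate=0.25)
        effects = set(cfg.effect_vocab)
        for ex in generate_corpus(cfg):
            for t in extract_triples(ex.graph, effects):
                assert 1 <= t.rule_id <= 6
                assert t.effect in effects

    def test_cause_phrase_never_contains_the_effect_token(self):
        cfg = SynthConfig(n_sentences=200, seed=32, distractor_rate=0.25)
        effects = set(cfg.effect_vocab)
        for ex in generate_corpus(cfg):
            for t in extract_triples(ex.graph, effects):
                assert t.effect not in t.cause.lower().split()
                assert t.cause.strip()
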