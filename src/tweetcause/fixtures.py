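"""Hand-annotated gold dependency graphs for a reference sentence set.

These fixtures cover every construction the rule set targets, grouped as:

* ``canonical`` — one minimal example per rule template (rules 1-6);
* ``variant``   — paraphrases exercising inflection, the passive with a
  nominal agent, and the direction flips of "result of" / "results from";
* ``reported``  — eight informal health-related messages of the kind the
  extractor is meant for, three per the direct construction, two copular,
  three phrasal;
* ``modality``  — hypothetical and interrogative causal statements;
* ``error``     — known false-positive shapes: matrix-clause negation and
  non-causal trigger usage.

Graphs are enhanced-style UD, hand-built (no parser involved) so tests
are hermetic; treebank tags follow the usual Penn conventions (VBZ for a
finite verb trigger, NN for a noun trigger).  Where a sentence admits
several defensible annotations, the choice here is documented inline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .depgraph import DependencyEdge, DependencyGraph, Token
from .pipeline import CorpusRecord
from .rules import CausalTriple
from .synthgen import DistractorKind, GoldExample

__all__ = ["gold_fixtures", "fixture_map", "REPORTED_SLUGS", "CANONICAL_SLUGS"]


def _graph(sent_id: str, text: str, rows) -> DependencyGraph:
    tokens, edges = [], []
    for i, row in enumerate(rows, 1):
        form, lemma, upos, xpos, head, rel, *extra = row
        tokens.append(Token(i, form, lemma, upos, xpos))
        edges.append(DependencyEdge(head, i, rel))
        for gov, rel2 in (extra[0] if extra else ()):
            edges.append(DependencyEdge(gov, i, rel2))
    return DependencyGraph(sent_id, text, tokens, edges).validate()


@dataclass(frozen=True)
class _Fix:
    slug: str
    group: str
    topic: str
    text: str
    rows: tuple
    rule: int | None = None  # rule expected to fire
    gold: tuple | None = None  # (cause phrase, trigger lemma, cause_head, effect_head)
    distractor: DistractorKind = DistractorKind.NONE


_FIXTURES: tuple[_Fix, ...] = (
    # ------------------------------------------------------------------
    # canonical: one example per rule template
    # ------------------------------------------------------------------
    _Fix(
        "stress-causes-insomnia", "canonical", "insomnia",
        "Stress causes insomnia",
        (
            ("Stress", "stress", "NOUN", "NN", 2, "nsubj"),
            ("causes", "cause", "VERB", "VBZ", 0, "root"),
            ("insomnia", "insomnia", "NOUN", "NN", 2, "dobj"),
        ),
        rule=1, gold=("Stress", "cause", 1, 3),
    ),
    _Fix(
        "overthinking-increase-and-cause", "canonical", "insomnia",
        "Over thinking can increase anxiety and cause insomnia.",
        (
            # gerund subject; the conjoined verb "cause" receives a
            # propagated clausal-subject edge in the enhanced graph
            ("Over", "over", "ADV", "RB", 2, "advmod"),
            ("thinking", "thinking", "NOUN", "VBG", 4, "csubj", ((7, "csubj"),)),
            ("can", "can", "AUX", "MD", 4, "aux"),
            ("increase", "increase", "VERB", "VB", 0, "root"),
            ("anxiety", "anxiety", "NOUN", "NN", 4, "dobj"),
            ("and", "and", "CCONJ", "CC", 7, "cc"),
            ("cause", "cause", "VERB", "VB", 4, "conj"),
            ("insomnia", "insomnia", "NOUN", "NN", 7, "dobj"),
            (".", ".", "PUNCT", ".", 4, "punct"),
        ),
        rule=2, gold=("Over thinking", "cause", 2, 8),
    ),
    _Fix(
        "insomnia-was-caused-by-stress", "canonical", "insomnia",
        "My insomnia was caused by stress.",
        (
            ("My", "my", "PRON", "PRP$", 2, "nmod:poss"),
            ("insomnia", "insomnia", "NOUN", "NN", 4, "nsubjpass"),
            ("was", "be", "AUX", "VBD", 4, "auxpass"),
            ("caused", "cause", "VERB", "VBN", 0, "root"),
            ("by", "by", "ADP", "IN", 6, "case"),
            ("stress", "stress", "NOUN", "NN", 4, "nmod:agent"),
            (".", ".", "PUNCT", ".", 4, "punct"),
        ),
        rule=3, gold=("stress", "cause", 6, 2),
    ),
    _Fix(
        "stress-is-a-reason-of-my-insomnia", "canonical", "insomnia",
        "Stress is a reason of my insomnia",
        (
            ("Stress", "stress", "NOUN", "NN", 4, "nsubj"),
            ("is", "be", "AUX", "VBZ", 4, "cop"),
            ("a", "a", "DET", "DT", 4, "det"),
            ("reason", "reason", "NOUN", "NN", 0, "root"),
            ("of", "of", "ADP", "IN", 7, "case"),
            ("my", "my", "PRON", "PRP$", 7, "nmod:poss"),
            ("insomnia", "insomnia", "NOUN", "NN", 4, "nmod:of"),
        ),
        rule=4, gold=("Stress", "reason", 1, 7),
    ),
    _Fix(
        "insomnia-was-caused-by-overthinking", "canonical", "insomnia",
        "Insomnia was caused by overthinking",
        (
            # gerund agent attaches as a by-marked adverbial clause
            ("Insomnia", "insomnia", "NOUN", "NN", 3, "nsubjpass"),
            ("was", "be", "AUX", "VBD", 3, "auxpass"),
            ("caused", "cause", "VERB", "VBN", 0, "root"),
            ("by", "by", "ADP", "IN", 5, "mark"),
            ("overthinking", "overthinking", "NOUN", "VBG", 3, "advcl:by"),
        ),
        rule=5, gold=("overthinking", "cause", 5, 1),
    ),
    _Fix(
        "stress-results-to-insomnia", "canonical", "insomnia",
        "Stress results to insomnia.",
        (
            ("Stress", "stress", "NOUN", "NN", 2, "nsubj"),
            ("results", "result", "VERB", "VBZ", 0, "root"),
            ("to", "to", "ADP", "IN", 4, "case"),
            ("insomnia", "insomnia", "NOUN", "NN", 2, "nmod:to"),
            (".", ".", "PUNCT", ".", 2, "punct"),
        ),
        rule=6, gold=("Stress", "result", 1, 4),
    ),
    # ------------------------------------------------------------------
    # variant: paraphrases and direction flips
    # ------------------------------------------------------------------
    _Fix(
        "stress-caused-my-insomnia", "variant", "insomnia",
        "Stress caused my insomnia",
        (
            ("Stress", "stress", "NOUN", "NN", 2, "nsubj"),
            ("caused", "cause", "VERB", "VBD", 0, "root"),
            ("my", "my", "PRON", "PRP$", 4, "nmod:poss"),
            ("insomnia", "insomnia", "NOUN", "NN", 2, "dobj"),
        ),
        rule=1, gold=("Stress", "cause", 1, 4),
    ),
    _Fix(
        "stress-results-in-insomnia", "variant", "insomnia",
        "Stress results in insomnia",
        (
            ("Stress", "stress", "NOUN", "NN", 2, "nsubj"),
            ("results", "result", "VERB", "VBZ", 0, "root"),
            ("in", "in", "ADP", "IN", 4, "case"),
            ("insomnia", "insomnia", "NOUN", "NN", 2, "nmod:in"),
        ),
        rule=6, gold=("Stress", "result", 1, 4),
    ),
    _Fix(
        "stress-was-caused-by-insomnia", "variant", "stress",
        "Stress was caused by insomnia",
        (
            ("Stress", "stress", "NOUN", "NN", 3, "nsubjpass"),
            ("was", "be", "AUX", "VBD", 3, "auxpass"),
            ("caused", "cause", "VERB", "VBN", 0, "root"),
            ("by", "by", "ADP", "IN", 5, "case"),
            ("insomnia", "insomnia", "NOUN", "NN", 3, "nmod:agent"),
        ),
        rule=3, gold=("insomnia", "cause", 5, 1),
    ),
    _Fix(
        "insomnia-is-a-result-of-stress", "variant", "insomnia",
        "Insomnia is a result of stress",
        (
            # trigger noun "result" flips direction: stress is the cause
            ("Insomnia", "insomnia", "NOUN", "NN", 4, "nsubj"),
            ("is", "be", "AUX", "VBZ", 4, "cop"),
            ("a", "a", "DET", "DT", 4, "det"),
            ("result", "result", "NOUN", "NN", 0, "root"),
            ("of", "of", "ADP", "IN", 6, "case"),
            ("stress", "stress", "NOUN", "NN", 4, "nmod:of"),
        ),
        rule=4, gold=("stress", "result", 6, 1),
    ),
    # ------------------------------------------------------------------
    # reported: informal messages with their firing rule
    # ------------------------------------------------------------------
    _Fix(
        "missing-someone-causes-insomnia", "reported", "insomnia",
        "Missing someone causes insomnia.",
        (
            # "someone" heads the subject phrase and governs the
            # participle, matching the nominal-subject construction
            ("Missing", "miss", "VERB", "VBG", 2, "amod"),
            ("someone", "someone", "PRON", "NN", 3, "nsubj"),
            ("causes", "cause", "VERB", "VBZ", 0, "root"),
            ("insomnia", "insomnia", "NOUN", "NN", 3, "dobj"),
            (".", ".", "PUNCT", ".", 3, "punct"),
        ),
        rule=1, gold=("Missing someone", "cause", 2, 4),
    ),
    _Fix(
        "night-before-first-day-of-school", "reported", "insomnia",
        "Night before first day of school always results in insomnia.",
        (
            ("Night", "night", "NOUN", "NN", 8, "nsubj"),
            ("before", "before", "ADP", "IN", 4, "case"),
            ("first", "first", "ADJ", "JJ", 4, "amod"),
            ("day", "day", "NOUN", "NN", 1, "nmod:before"),
            ("of", "of", "ADP", "IN", 6, "case"),
            ("school", "school", "NOUN", "NN", 4, "nmod:of"),
            ("always", "always", "ADV", "RB", 8, "advmod"),
            ("results", "result", "VERB", "VBZ", 0, "root"),
            ("in", "in", "ADP", "IN", 10, "case"),
            ("insomnia", "insomnia", "NOUN", "NN", 8, "nmod:in"),
            (".", ".", "PUNCT", ".", 8, "punct"),
        ),
        rule=6, gold=("Night before first day of school", "result", 1, 10),
    ),
    _Fix(
        "money-only-causes-stress", "reported", "stress",
        "Money only causes stress and conflict",
        (
            ("Money", "money", "NOUN", "NN", 3, "nsubj"),
            ("only", "only", "ADV", "RB", 3, "advmod"),
            ("causes", "cause", "VERB", "VBZ", 0, "root"),
            ("stress", "stress", "NOUN", "NN", 3, "dobj"),
            ("and", "and", "CCONJ", "CC", 6, "cc"),
            ("conflict", "conflict", "NOUN", "NN", 4, "conj", ((3, "dobj"),)),
        ),
        rule=1, gold=("Money", "cause", 1, 4),
    ),
    _Fix(
        "school-is-the-main-cause-of-my-stress", "reported", "stress",
        "School is the main cause of my stress",
        (
            ("School", "school", "NOUN", "NNP", 5, "nsubj"),
            ("is", "be", "AUX", "VBZ", 5, "cop"),
            ("the", "the", "DET", "DT", 5, "det"),
            ("main", "main", "ADJ", "JJ", 5, "amod"),
            ("cause", "cause", "NOUN", "NN", 0, "root"),
            ("of", "of", "ADP", "IN", 8, "case"),
            ("my", "my", "PRON", "PRP$", 8, "nmod:poss"),
            ("stress", "stress", "NOUN", "NN", 5, "nmod:of"),
        ),
        rule=4, gold=("School", "cause", 1, 8),
    ),
    _Fix(
        "my-neck-just-made-my-headache-worse", "reported", "headache",
        "My neck just made my headache 100x worse",
        (
            ("My", "my", "PRON", "PRP$", 2, "nmod:poss"),
            ("neck", "neck", "NOUN", "NN", 4, "nsubj"),
            ("just", "just", "ADV", "RB", 4, "advmod"),
            ("made", "make", "VERB", "VBD", 0, "root"),
            ("my", "my", "PRON", "PRP$", 6, "nmod:poss"),
            ("headache", "headache", "NOUN", "NN", 4, "dobj"),
            ("100x", "100x", "ADV", "RB", 8, "advmod"),
            ("worse", "worse", "ADJ", "JJR", 4, "xcomp"),
        ),
        rule=1, gold=("My neck", "make", 2, 6),
    ),
    _Fix(
        "nervous-stressed-leads-to-headaches", "reported", "headache",
        "Nervous Stressed Leads to swollen eye & headaches",
        (
            ("Nervous", "nervous", "ADJ", "JJ", 2, "amod"),
            ("Stressed", "stressed", "NOUN", "NN", 3, "nsubj"),
            ("Leads", "lead", "VERB", "VBZ", 0, "root"),
            ("to", "to", "ADP", "IN", 6, "case"),
            ("swollen", "swollen", "ADJ", "JJ", 6, "amod"),
            ("eye", "eye", "NOUN", "NN", 3, "nmod:to"),
            ("&", "&", "CCONJ", "CC", 8, "cc"),
            ("headaches", "headache", "NOUN", "NNS", 6, "conj", ((3, "nmod:to"),)),
        ),
        rule=6, gold=("Nervous Stressed", "lead", 2, 8),
    ),
    _Fix(
        "you-are-the-cause-of-my-headaches", "reported", "headache",
        "You're the cause of my headaches.",
        (
            ("You", "you", "PRON", "PRP", 4, "nsubj"),
            ("'re", "be", "AUX", "VBP", 4, "cop"),
            ("the", "the", "DET", "DT", 4, "det"),
            ("cause", "cause", "NOUN", "NN", 0, "root"),
            ("of", "of", "ADP", "IN", 7, "case"),
            ("my", "my", "PRON", "PRP$", 7, "nmod:poss"),
            ("headaches", "headache", "NOUN", "NNS", 4, "nmod:of"),
            (".", ".", "PUNCT", ".", 4, "punct"),
        ),
        rule=4, gold=("You", "cause", 1, 7),
    ),
    _Fix(
        "too-many-tears-leads-to-headaches", "reported", "headache",
        "too many tears leads to headaches and heavy hearts",
        (
            ("too", "too", "ADV", "RB", 2, "advmod"),
            ("many", "many", "ADJ", "JJ", 3, "amod"),
            ("tears", "tear", "NOUN", "NNS", 4, "nsubj"),
            ("leads", "lead", "VERB", "VBZ", 0, "root"),
            ("to", "to", "ADP", "IN", 6, "case"),
            ("headaches", "headache", "NOUN", "NNS", 4, "nmod:to"),
            ("and", "and", "CCONJ", "CC", 9, "cc"),
            ("heavy", "heavy", "ADJ", "JJ", 9, "amod"),
            ("hearts", "heart", "NOUN", "NNS", 6, "conj", ((4, "nmod:to"),)),
        ),
        rule=6, gold=("too many tears", "lead", 3, 6),
    ),
    # ------------------------------------------------------------------
    # modality: hypothetical / interrogative causal statements
    # ------------------------------------------------------------------
    _Fix(
        "cell-phone-radiation-can-cause-insomnia", "modality", "insomnia",
        "Cell phone radiation can cause insomnia",
        (
            ("Cell", "cell", "NOUN", "NN", 3, "compound"),
            ("phone", "phone", "NOUN", "NN", 3, "compound"),
            ("radiation", "radiation", "NOUN", "NN", 5, "nsubj"),
            ("can", "can", "AUX", "MD", 5, "aux"),
            ("cause", "cause", "VERB", "VB", 0, "root"),
            ("insomnia", "insomnia", "NOUN", "NN", 5, "dobj"),
        ),
        rule=1, distractor=DistractorKind.HYPOTHETICAL,
    ),
    _Fix(
        "could-this-be-the-cause-of-my-insomnia", "modality", "insomnia",
        "Could this be the cause of my insomnia?",
        (
            ("Could", "could", "AUX", "MD", 5, "aux"),
            ("this", "this", "PRON", "DT", 5, "nsubj"),
            ("be", "be", "AUX", "VB", 5, "cop"),
            ("the", "the", "DET", "DT", 5, "det"),
            ("cause", "cause", "NOUN", "NN", 0, "root"),
            ("of", "of", "ADP", "IN", 8, "case"),
            ("my", "my", "PRON", "PRP$", 8, "nmod:poss"),
            ("insomnia", "insomnia", "NOUN", "NN", 5, "nmod:of"),
            ("?", "?", "PUNCT", ".", 5, "punct"),
        ),
        rule=4, distractor=DistractorKind.INTERROGATIVE,
    ),
    # ------------------------------------------------------------------
    # error: known false-positive shapes
    # ------------------------------------------------------------------
    _Fix(
        "i-wouldnt-say-it-causes-insomnia", "error", "insomnia",
        "I wouldn't say it causes insomnia though",
        (
            ("I", "i", "PRON", "PRP", 4, "nsubj"),
            ("would", "would", "AUX", "MD", 4, "aux"),
            ("n't", "not", "PART", "RB", 4, "neg"),
            ("say", "say", "VERB", "VB", 0, "root"),
            ("it", "it", "PRON", "PRP", 6, "nsubj"),
            ("causes", "cause", "VERB", "VBZ", 4, "ccomp"),
            ("insomnia", "insomnia", "NOUN", "NN", 6, "dobj"),
            ("though", "though", "ADV", "RB", 6, "advmod"),
        ),
        rule=1, distractor=DistractorKind.NEGATED,
    ),
    _Fix(
        "keeping-to-myself-makes-life-stress-free", "error", "stress",
        "Keeping to myself makes life way more stress free",
        (
            ("Keeping", "keep", "VERB", "VBG", 4, "csubj"),
            ("to", "to", "ADP", "IN", 3, "case"),
            ("myself", "myself", "PRON", "PRP", 1, "nmod:to"),
            ("makes", "make", "VERB", "VBZ", 0, "root"),
            ("life", "life", "NOUN", "NN", 4, "dobj"),
            ("way", "way", "ADV", "RB", 7, "advmod"),
            ("more", "more", "ADV", "RBR", 9, "advmod"),
            ("stress", "stress", "NOUN", "NN", 9, "compound"),
            ("free", "free", "ADJ", "JJ", 5, "amod"),
        ),
        rule=None, distractor=DistractorKind.NON_CAUSAL,
    ),
)

REPORTED_SLUGS = tuple(f.slug for f in _FIXTURES if f.group == "reported")
CANONICAL_SLUGS = tuple(f.slug for f in _FIXTURES if f.group == "canonical")


def gold_fixtures() -> list[GoldExample]:
    """All bundled gold examples as :class:`GoldExample` objects."""
    out = []
    for f in _FIXTURES:
        sid = f"{f.slug}/0"
        graph = _graph(sid, f.text, f.rows)
        if f.gold is not None and f.distractor is DistractorKind.NONE:
            cause, trigger, cause_head, effect_head = f.gold
            gold = (
                CausalTriple(
                    cause=cause,
                    trigger=trigger,
                    effect=f.topic,
                    rule_id=f.rule,
                    sentence_id=sid,
                    cause_head=cause_head,
                    effect_head=effect_head,
                ),
            )
        else:
            gold = ()
        out.append(
            GoldExample(
                record=CorpusRecord(f.slug, f.text),
                graph=graph,
                gold_triples=gold,
                distractor_kind=f.distractor,
                topic=f.topic,
                expected_rule_id=f.rule,
                group=f.group,
            )
        )
    return out


def fixture_map() -> dict[str, GoldExample]:
    """Gold examples keyed by their slug."""
    return {ex.record.record_id: ex for ex in gold_fixtures()}
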