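"""Deterministic generator of synthetic short messages with gold parses.

No public corpus exists for this task, so test corpora are generated from
templates that instantiate the six causal constructions the rule set
targets — "A causes B", gerund subjects, passives with nominal or clausal
agents, copular trigger nouns, and phrasal "results in/from" — plus
distractors reproducing the documented error modes: negated, hypothetical
and interrogative causal statements and non-causal trigger usage.

Gold dependency graphs are template-built (no parser involved), so every
example carries its exact expected output: the extractor must recover the
gold triples on non-distractor sentences, and under strict semantics
distractors carry none.  Generation is fully reproducible under a seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum

from .depgraph import DependencyEdge, DependencyGraph, Token
from .pipeline import CorpusRecord
from .rules import CausalTriple

__all__ = [
    "DistractorKind",
    "GoldExample",
    "PhraseSpec",
    "SynthConfig",
    "SynthConfigError",
    "generate_corpus",
    "DEFAULT_CAUSE_PHRASES",
]


class SynthConfigError(ValueError):
    """Invalid generator configuration."""


class DistractorKind(Enum):
    NONE = "NONE"
    NEGATED = "NEGATED"
    HYPOTHETICAL = "HYPOTHETICAL"
    INTERROGATIVE = "INTERROGATIVE"
    NON_CAUSAL = "NON_CAUSAL"


@dataclass
class GoldExample:
    """One message with its gold parse and gold extraction output.

    ``gold_triples`` is empty for every distractor (strict semantics).
    ``expected_rule_id`` records which rule, if any, is *expected to fire*
    on the sentence — for negated/hypothetical/interrogative distractors a
    rule still fires even though the strict gold is empty.
    """

    record: CorpusRecord
    graph: DependencyGraph
    gold_triples: tuple[CausalTriple, ...]
    distractor_kind: DistractorKind = DistractorKind.NONE
    topic: str | None = None
    expected_rule_id: int | None = None
    group: str = "synthetic"


@dataclass(frozen=True)
class PhraseSpec:
    """A 1-3 token noun phrase with its internal dependency structure.

    ``tokens`` are (form, lemma, upos, xpos); ``head`` is the offset of
    the phrase head; ``edges`` are (governor_offset, dependent_offset,
    relation) within the phrase.
    """

    tokens: tuple
    head: int = 0
    edges: tuple = ()

    @property
    def text(self) -> str:
        return " ".join(t[0] for t in self.tokens)


def _np(*words: str) -> PhraseSpec:
    """Plain nominal phrase: last token heads, earlier tokens attach to it."""
    toks = []
    edges = []
    head = len(words) - 1
    for i, w in enumerate(words):
        if i == head:
            toks.append((w, w, "NOUN", "NN"))
        elif w in ("my", "your", "his", "her"):
            toks.append((w, w, "PRON", "PRP$"))
            edges.append((head, i, "nmod:poss"))
        elif w.endswith("ly") or w in ("too",):
            toks.append((w, w, "ADV", "RB"))
            edges.append((i + 1, i, "advmod"))
        else:
            toks.append((w, w, "ADJ", "JJ"))
            edges.append((head, i, "amod"))
    return PhraseSpec(tuple(toks), head, tuple(edges))


DEFAULT_CAUSE_PHRASES: tuple[PhraseSpec, ...] = (
    _np("coffee"),
    _np("money"),
    _np("school"),
    _np("hunger"),
    _np("overthinking"),
    _np("loud", "music"),
    _np("my", "job"),
    _np("social", "media"),
    _np("exam", "week"),
    _np("too", "much", "noise"),
)

# Gerund phrases for the clausal-subject / clausal-agent constructions.
_GERUNDS: tuple[PhraseSpec, ...] = (
    PhraseSpec(
        (("drinking", "drink", "VERB", "VBG"), ("coffee", "coffee", "NOUN", "NN")),
        0,
        ((0, 1, "dobj"),),
    ),
    PhraseSpec(
        (("skipping", "skip", "VERB", "VBG"), ("meals", "meal", "NOUN", "NNS")),
        0,
        ((0, 1, "dobj"),),
    ),
    PhraseSpec(
        (("watching", "watch", "VERB", "VBG"), ("movies", "movie", "NOUN", "NNS")),
        0,
        ((0, 1, "dobj"),),
    ),
    PhraseSpec(
        (("missing", "miss", "VERB", "VBG"), ("someone", "someone", "PRON", "NN")),
        0,
        ((0, 1, "dobj"),),
    ),
)

# Active-verb inflections for rule 1/2 templates: (form, lemma, xpos).
_ACTIVE_VERBS = (
    ("causes", "cause", "VBZ"),
    ("caused", "cause", "VBD"),
    ("triggers", "trigger", "VBZ"),
    ("makes", "make", "VBZ"),
    ("made", "make", "VBD"),
    ("stimulates", "stimulate", "VBZ"),
)
_PASSIVE_VERBS = (("caused", "cause", "VBN"), ("triggered", "trigger", "VBN"))
# Phrasal construction variants: (form, lemma, xpos, preposition).
_PHRASAL_VERBS = (
    ("results", "result", "VBZ", "in"),
    ("resulted", "result", "VBD", "in"),
    ("leads", "lead", "VBZ", "to"),
    ("led", "lead", "VBD", "to"),
    ("results", "result", "VBZ", "from"),
)
_TRIGGER_NOUNS = ("reason", "cause", "result")


@dataclass
class SynthConfig:
    n_sentences: int = 100
    seed: int = 0
    # Realistic skew: the direct active construction dominates informal
    # messages, the phrasal construction comes second, passives are rare.
    rule_mix: dict = field(
        default_factory=lambda: {1: 0.40, 2: 0.09, 3: 0.08, 4: 0.12, 5: 0.06, 6: 0.25}
    )
    distractor_rate: float = 0.0
    effect_vocab: tuple = ("stress", "insomnia", "headache")
    cause_vocab: tuple = DEFAULT_CAUSE_PHRASES

    def validate(self) -> "SynthConfig":
        if self.n_sentences < 0:
            raise SynthConfigError("n_sentences must be >= 0")
        if abs(sum(self.rule_mix.values()) - 1.0) > 1e-9:
            raise SynthConfigError("rule_mix probabilities must sum to 1")
        if not set(self.rule_mix) <= {1, 2, 3, 4, 5, 6}:
            raise SynthConfigError("rule_mix keys must be rule ids 1-6")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise SynthConfigError("distractor_rate must lie in [0, 1]")
        if not self.effect_vocab:
            raise SynthConfigError("effect_vocab must be non-empty")
        if not self.cause_vocab:
            raise SynthConfigError("cause_vocab must be non-empty")
        return self


# ---------------------------------------------------------------------------
# Sentence assembly
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self):
        self.tokens: list[Token] = []
        self.edges: list[DependencyEdge] = []

    def tok(self, form, lemma, upos, xpos) -> int:
        idx = len(self.tokens) + 1
        self.tokens.append(Token(idx, form, lemma, upos, xpos))
        return idx

    def phrase(self, spec: PhraseSpec, capitalize=False) -> tuple[int, str]:
        base = len(self.tokens)
        forms = []
        for i, (form, lemma, upos, xpos) in enumerate(spec.tokens):
            if capitalize and i == 0:
                form = form[:1].upper() + form[1:]
            forms.append(form)
            self.tok(form, lemma, upos, xpos)
        for gov_off, dep_off, rel in spec.edges:
            self.edge(base + gov_off + 1, base + dep_off + 1, rel)
        return base + spec.head + 1, " ".join(forms)

    def edge(self, gov, dep, rel) -> None:
        self.edges.append(DependencyEdge(gov, dep, rel))

    def graph(self, sentence_id) -> DependencyGraph:
        text = " ".join(t.form for t in self.tokens)
        return DependencyGraph(sentence_id, text, self.tokens, self.edges).validate()


def _triple(sid, cause_text, trigger_lemma, effect, rule_id, cause_head, eff_idx):
    return CausalTriple(
        cause=cause_text,
        trigger=trigger_lemma,
        effect=effect,
        rule_id=rule_id,
        sentence_id=sid,
        cause_head=cause_head,
        effect_head=eff_idx,
    )


def _build_rule(rule_id: int, rng: random.Random, cfg: SynthConfig, sid: str):
    b = _Builder()
    effect = rng.choice(sorted(cfg.effect_vocab))
    if rule_id == 1:
        ph = rng.choice(cfg.cause_vocab)
        head, text = b.phrase(ph, capitalize=True)
        form, lemma, xpos = rng.choice(_ACTIVE_VERBS)
        v = b.tok(form, lemma, "VERB", xpos)
        e = b.tok(effect, effect, "NOUN", "NN")
        b.edge(0, v, "root"), b.edge(v, head, "nsubj"), b.edge(v, e, "dobj")
        gold = _triple(sid, text, lemma, effect, 1, head, e)
    elif rule_id == 2:
        ph = rng.choice(_GERUNDS)
        head, text = b.phrase(ph, capitalize=True)
        form, lemma, xpos = rng.choice(_ACTIVE_VERBS)
        v = b.tok(form, lemma, "VERB", xpos)
        e = b.tok(effect, effect, "NOUN", "NN")
        b.edge(0, v, "root"), b.edge(v, head, "csubj"), b.edge(v, e, "dobj")
        gold = _triple(sid, text, lemma, effect, 2, head, e)
    elif rule_id == 3:
        e = b.tok(effect, effect, "NOUN", "NN")
        b.tok("was", "be", "AUX", "VBD")
        form, lemma, _ = rng.choice(_PASSIVE_VERBS)
        v = b.tok(form, lemma, "VERB", "VBN")
        by = b.tok("by", "by", "ADP", "IN")
        ph = rng.choice(cfg.cause_vocab)
        head, text = b.phrase(ph)
        b.edge(0, v, "root"), b.edge(v, e, "nsubjpass"), b.edge(v, 2, "auxpass")
        b.edge(head, by, "case"), b.edge(v, head, "nmod:agent")
        gold = _triple(sid, text, lemma, effect, 3, head, e)
    elif rule_id == 4:
        noun = rng.choice(_TRIGGER_NOUNS)
        if noun == "result":
            # "B is a result of A": subject is the effect, of-object the cause.
            e = b.tok(effect[:1].upper() + effect[1:], effect, "NOUN", "NN")
            cop = b.tok("is", "be", "AUX", "VBZ")
            det = b.tok("a", "a", "DET", "DT")
            t = b.tok(noun, noun, "NOUN", "NN")
            of = b.tok("of", "of", "ADP", "IN")
            head, text = b.phrase(rng.choice(cfg.cause_vocab))
            b.edge(0, t, "root"), b.edge(t, e, "nsubj"), b.edge(t, cop, "cop")
            b.edge(t, det, "det"), b.edge(t, head, "nmod:of"), b.edge(head, of, "case")
        else:
            head, text = b.phrase(rng.choice(cfg.cause_vocab), capitalize=True)
            cop = b.tok("is", "be", "AUX", "VBZ")
            det = b.tok("the", "the", "DET", "DT")
            t = b.tok(noun, noun, "NOUN", "NN")
            of = b.tok("of", "of", "ADP", "IN")
            e = b.tok(effect, effect, "NOUN", "NN")
            b.edge(0, t, "root"), b.edge(t, head, "nsubj"), b.edge(t, cop, "cop")
            b.edge(t, det, "det"), b.edge(t, e, "nmod:of"), b.edge(e, of, "case")
        gold = _triple(sid, text, noun, effect, 4, head, e)
    elif rule_id == 5:
        e = b.tok(effect[:1].upper() + effect[1:], effect, "NOUN", "NN")
        b.tok("was", "be", "AUX", "VBD")
        form, lemma, _ = rng.choice(_PASSIVE_VERBS)
        v = b.tok(form, lemma, "VERB", "VBN")
        by = b.tok("by", "by", "ADP", "IN")
        head, text = b.phrase(rng.choice(_GERUNDS))
        b.edge(0, v, "root"), b.edge(v, e, "nsubjpass"), b.edge(v, 2, "auxpass")
        b.edge(head, by, "mark"), b.edge(v, head, "advcl:by")
        gold = _triple(sid, text, lemma, effect, 5, head, e)
    else:  # rule 6
        form, lemma, xpos, prep = rng.choice(_PHRASAL_VERBS)
        if prep == "from":
            # "B results from A": subject is the effect, pobj the cause.
            e = b.tok(effect[:1].upper() + effect[1:], effect, "NOUN", "NN")
            v = b.tok(form, lemma, "VERB", xpos)
            p = b.tok(prep, prep, "ADP", "IN")
            head, text = b.phrase(rng.choice(cfg.cause_vocab))
            b.edge(0, v, "root"), b.edge(v, e, "nsubj")
            b.edge(v, head, f"nmod:{prep}"), b.edge(head, p, "case")
        else:
            head, text = b.phrase(rng.choice(cfg.cause_vocab), capitalize=True)
            v = b.tok(form, lemma, "VERB", xpos)
            p = b.tok(prep, prep, "ADP", "IN")
            e = b.tok(effect, effect, "NOUN", "NN")
            b.edge(0, v, "root"), b.edge(v, head, "nsubj")
            b.edge(v, e, f"nmod:{prep}"), b.edge(e, p, "case")
        gold = _triple(sid, text, lemma, effect, 6, head, e)
    graph = b.graph(sid)
    return graph, (gold,), effect


def _build_distractor(kind, rng: random.Random, cfg: SynthConfig, sid: str):
    b = _Builder()
    effect = rng.choice(sorted(cfg.effect_vocab))
    expected: int | None = 1
    if kind is DistractorKind.NEGATED:
        head, _ = b.phrase(rng.choice(cfg.cause_vocab), capitalize=True)
        neg = b.tok("never", "never", "ADV", "RB")
        v = b.tok("causes", "cause", "VERB", "VBZ")
        e = b.tok(effect, effect, "NOUN", "NN")
        b.edge(0, v, "root"), b.edge(v, head, "nsubj"), b.edge(v, neg, "neg")
        b.edge(v, e, "dobj")
    elif kind is DistractorKind.HYPOTHETICAL:
        head, _ = b.phrase(rng.choice(cfg.cause_vocab), capitalize=True)
        modal = rng.choice(["can", "could", "might"])
        aux = b.tok(modal, modal, "AUX", "MD")
        v = b.tok("cause", "cause", "VERB", "VB")
        e = b.tok(effect, effect, "NOUN", "NN")
        b.edge(0, v, "root"), b.edge(v, head, "nsubj"), b.edge(v, aux, "aux")
        b.edge(v, e, "dobj")
    elif kind is DistractorKind.INTERROGATIVE:
        aux = b.tok("could", "could", "AUX", "MD")
        head, _ = b.phrase(rng.choice(cfg.cause_vocab))
        v = b.tok("cause", "cause", "VERB", "VB")
        e = b.tok(effect, effect, "NOUN", "NN")
        q = b.tok("?", "?", "PUNCT", ".")
        b.edge(0, v, "root"), b.edge(v, aux, "aux"), b.edge(v, head, "nsubj")
        b.edge(v, e, "dobj"), b.edge(v, q, "punct")
    else:  # NON_CAUSAL: trigger verb present, but no effect in a causal slot
        expected = None
        if rng.random() < 0.5:
            head, _ = b.phrase(rng.choice(cfg.cause_vocab), capitalize=True)
            v = b.tok("makes", "make", "VERB", "VBZ")
            o = b.tok("life", "life", "NOUN", "NN")
            more = b.tok("more", "more", "ADV", "RBR")
            e = b.tok(effect, effect, "NOUN", "NN")
            free = b.tok("free", "free", "ADJ", "JJ")
            b.edge(0, v, "root"), b.edge(v, head, "nsubj"), b.edge(v, o, "dobj")
            b.edge(o, free, "amod"), b.edge(free, more, "advmod")
            b.edge(free, e, "compound")
        else:
            i = b.tok("i", "i", "PRON", "PRP")
            v = b.tok("hate", "hate", "VERB", "VBP")
            my = b.tok("my", "my", "PRON", "PRP$")
            e = b.tok(effect, effect, "NOUN", "NN")
            b.edge(0, v, "root"), b.edge(v, i, "nsubj"), b.edge(v, e, "dobj")
            b.edge(e, my, "nmod:poss")
    graph = b.graph(sid)
    return graph, effect, expected


def generate_corpus(config: SynthConfig) -> list[GoldExample]:
    """Generate a reproducible corpus of gold examples.

    Byte-identical output (including CoNLL-U serialization) under the
    same config; distractors appear at ``distractor_rate`` and carry no
    strict-gold triples.
    """
    config.validate()
    rng = random.Random(config.seed)
    rule_ids = sorted(config.rule_mix)
    weights = [config.rule_mix[r] for r in rule_ids]
    kinds = [
        DistractorKind.NEGATED,
        DistractorKind.HYPOTHETICAL,
        DistractorKind.INTERROGATIVE,
        DistractorKind.NON_CAUSAL,
    ]
    out: list[GoldExample] = []
    for i in range(config.n_sentences):
        rid = f"synth-{i:05d}"
        sid = f"{rid}/0"
        if rng.random() < config.distractor_rate:
            kind = rng.choice(kinds)
            graph, effect, expected = _build_distractor(kind, rng, config, sid)
            out.append(
                GoldExample(
                    record=CorpusRecord(rid, graph.text),
                    graph=graph,
                    gold_triples=(),
                    distractor_kind=kind,
                    topic=effect,
                    expected_rule_id=expected,
                )
            )
        else:
            rule = rng.choices(rule_ids, weights=weights, k=1)[0]
            graph, gold, effect = _build_rule(rule, rng, config, sid)
            out.append(
                GoldExample(
                    record=CorpusRecord(rid, graph.text),
                    graph=graph,
                    gold_triples=gold,
                    topic=effect,
                    expected_rule_id=rule,
                )
            )
    return out
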