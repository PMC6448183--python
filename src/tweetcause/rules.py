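"""Causal rule templates, trigger lexicon, and triple extraction.

Six lexico-syntactic templates recognize explicit in-sentence causal
statements on a dependency graph, anchored on a small trigger lexicon
(seven causal verbs, three causal nouns).  Each template is a pattern in
the Semgrex-subset language plus a capture->role map and a direction
policy; the policy handles constructions whose surface order reverses the
causal direction ("B is a result of A", "B results from A").

Extraction is effect-driven: a match only yields a triple when the token
in the effect role (or a conjunct reachable from it) has a configured
target lemma such as "insomnia".  The output is the triple
``<cause phrase, trigger lemma, effect keyword>`` plus provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, auto

from .depgraph import DependencyGraph, subtree_yield
from .patternlang import PatternAST, find_matches, parse_pattern

__all__ = [
    "TriggerLexicon",
    "DirectionPolicy",
    "CausalRule",
    "CausalTriple",
    "default_lexicon",
    "compile_rules",
    "extract_triples",
    "rules_to_config",
    "rules_from_config",
]

DEFAULT_VERBS = frozenset(
    {"cause", "stimulate", "make", "derive", "trigger", "result", "lead"}
)
DEFAULT_NOUNS = frozenset({"result", "reason", "cause"})
DEFAULT_PHRASAL_PREPS = frozenset({"in", "to", "from"})
# Verbs that license the phrasal "A <trigger> <prep> B" construction.
DEFAULT_PHRASAL_VERBS = frozenset({"cause", "result", "reason", "lead"})


@dataclass(frozen=True)
class TriggerLexicon:
    verbs: frozenset = DEFAULT_VERBS
    nouns: frozenset = DEFAULT_NOUNS
    phrasal_preps: frozenset = DEFAULT_PHRASAL_PREPS
    phrasal_verbs: frozenset = DEFAULT_PHRASAL_VERBS


def default_lexicon() -> TriggerLexicon:
    """The published trigger lexicon: 7 verbs, 3 nouns, 3 phrasal preps."""
    return TriggerLexicon()


class DirectionPolicy(Enum):
    FIXED = auto()
    # "A results/derives from B": with preposition "from" the pobj is the cause.
    FLIP_ON_FROM = auto()
    # "A is a result of B": with trigger noun "result" the of-object is the cause.
    FLIP_ON_RESULT_NOUN = auto()


@dataclass(frozen=True)
class CausalRule:
    rule_id: int
    pattern: str
    cause_capture: str
    effect_capture: str
    trigger_capture: str
    direction_policy: DirectionPolicy
    ast: PatternAST = field(compare=False, default=None)

    def __post_init__(self):
        if self.ast is None:
            object.__setattr__(self, "ast", parse_pattern(self.pattern))


@dataclass(frozen=True)
class CausalTriple:
    cause: str
    trigger: str
    effect: str
    rule_id: int
    sentence_id: str
    cause_head: int
    effect_head: int


def _alt(words) -> str:
    return "(" + "|".join(sorted(words)) + ")"


def compile_rules(lexicon: TriggerLexicon | None = None) -> list[CausalRule]:
    """The six rule templates, instantiated for a trigger lexicon.

    1. A caused B           (nominal subject, direct object)
    2. A-ing caused B       (clausal subject, direct object)
    3. B was caused by A    (passive, nominal agent)
    4. A is a reason/cause/result of B   (copular noun + of-phrase)
    5. B was caused by A-ing             (passive, gerund adverbial clause)
    6. A results in/to B, A results from B  (phrasal verb + preposition)

    Verb triggers additionally require a verbal treebank tag (VB*) and
    noun triggers a nominal tag (NN*), so that e.g. the lemma "cause"
    dispatches to rule 1 as "causes/VBZ" but to rule 4 as "cause/NN".
    """
    lex = lexicon or default_lexicon()
    v = _alt(lex.verbs)
    n = _alt(lex.nouns)
    pv = _alt(lex.phrasal_verbs)
    prep = "|".join(sorted(lex.phrasal_preps))
    specs = [
        (
            1,
            f"{{}}=subj <nsubj ({{lemma:/{v}/;tag:/VB.*/}}=target >dobj {{}}=obj)",
            "subj", "obj", DirectionPolicy.FIXED,
        ),
        (
            2,
            f"{{}}=subj <csubj ({{lemma:/{v}/;tag:/VB.*/}}=target >dobj {{}}=obj)",
            "subj", "obj", DirectionPolicy.FIXED,
        ),
        (
            3,
            f"{{}}=psubj <nsubjpass ({{lemma:/{v}/;tag:/VB.*/}}=target "
            f">/nmod:agent/ {{}}=agent)",
            "agent", "psubj", DirectionPolicy.FIXED,
        ),
        (
            4,
            f"{{}}=subj <nsubj ({{lemma:/{n}/;tag:/NN.*/}}=target "
            f">/nmod:of/ {{}}=of)",
            "subj", "of", DirectionPolicy.FLIP_ON_RESULT_NOUN,
        ),
        (
            5,
            f"{{}}=psubj <nsubjpass ({{lemma:/{v}/;tag:/VB.*/}}=target "
            f">/advcl:by/ {{}}=adv)",
            "adv", "psubj", DirectionPolicy.FIXED,
        ),
        (
            6,
            f"{{}}=subj <nsubj ({{lemma:/{pv}/;tag:/VB.*/}}=target "
            f">/nmod:({prep})/ {{}}=pobj)",
            "subj", "pobj", DirectionPolicy.FLIP_ON_FROM,
        ),
    ]
    return [
        CausalRule(rid, pat, cause, effect, "target", policy)
        for rid, pat, cause, effect, policy in specs
    ]


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def _conj_closure(graph: DependencyGraph, idx: int) -> list[int]:
    """The token plus everything reachable from it over conj edges."""
    seen = {idx}
    stack = [idx]
    while stack:
        i = stack.pop()
        for rel, dep in graph.dependents_of(i):
            if (rel == "conj" or rel.startswith("conj:")) and dep not in seen:
                seen.add(dep)
                stack.append(dep)
    others = sorted(seen - {idx})
    return [idx, *others]


def _resolve_effect(graph, idx: int, effects: set[str]):
    for i in _conj_closure(graph, idx):
        lemma = graph.token(i).lemma.lower()
        if lemma in effects:
            return i, lemma
    return None, None


def _roles(rule: CausalRule, graph, bindings: dict[str, int]):
    cause = bindings[rule.cause_capture]
    effect = bindings[rule.effect_capture]
    trigger = bindings[rule.trigger_capture]
    policy = rule.direction_policy
    if policy is DirectionPolicy.FLIP_ON_RESULT_NOUN:
        if graph.token(trigger).lemma.lower() == "result":
            cause, effect = effect, cause
    elif policy is DirectionPolicy.FLIP_ON_FROM:
        # effect_capture holds the prepositional object; flip when it is
        # attached to the trigger as nmod:from ("A results from B").
        from_edge = any(
            dep == effect and rel == "nmod:from"
            for rel, dep in graph.dependents_of(trigger)
        )
        if from_edge:
            cause, effect = effect, cause
    return cause, effect, trigger


_PHRASE_DROP_RELS = ("case", "mark")


def extract_triples(
    graph: DependencyGraph,
    effects,
    rules: list[CausalRule] | None = None,
) -> list[CausalTriple]:
    """Extract causal triples for the configured effect keywords.

    For each rule (in rule-id order) and each pattern match, the capture
    map and direction policy assign cause / effect / trigger tokens.  The
    match is kept only when the effect token's lemma — or that of a token
    reachable from it via conj edges — is a target keyword.  The cause
    phrase is the cause token's subtree yield, excluding the trigger and
    effect subtrees and any case/mark function words hanging off the cause
    head.  A sentence contributes at most one triple per (rule, keyword);
    the match with the lowest anchor wins.
    """
    if rules is None:
        rules = compile_rules()
    targets = {e.lower() for e in effects}
    if not targets:
        raise ValueError("effects must be non-empty")
    triples: list[CausalTriple] = []
    emitted: set[tuple[int, str]] = set()
    dedup: set[tuple[int, str, int]] = set()
    for rule in sorted(rules, key=lambda r: r.rule_id):
        for m in find_matches(rule.ast, graph):
            bindings = dict(m.bindings)
            cause_idx, effect_idx, trig_idx = _roles(rule, graph, bindings)
            eff_tok, keyword = _resolve_effect(graph, effect_idx, targets)
            if keyword is None:
                continue
            if (rule.rule_id, keyword) in emitted:
                continue
            exclude = {trig_idx, effect_idx, eff_tok}
            exclude.update(
                dep
                for rel, dep in graph.dependents_of(cause_idx)
                if rel in _PHRASE_DROP_RELS
                or rel.startswith(tuple(r + ":" for r in _PHRASE_DROP_RELS))
            )
            phrase = subtree_yield(graph, cause_idx, exclude)
            if not phrase:
                continue
            key = (cause_idx, keyword, rule.rule_id)
            if key in dedup:
                continue
            dedup.add(key)
            emitted.add((rule.rule_id, keyword))
            triples.append(
                CausalTriple(
                    cause=phrase,
                    trigger=graph.token(trig_idx).lemma.lower(),
                    effect=keyword,
                    rule_id=rule.rule_id,
                    sentence_id=graph.sentence_id,
                    cause_head=cause_idx,
                    effect_head=eff_tok,
                )
            )
    return triples


# ---------------------------------------------------------------------------
# Rule-config serialization
# ---------------------------------------------------------------------------

_CONFIG_HEADER = "# rule_id\tcause\teffect\ttrigger\tpolicy\tpattern"


def rules_to_config(rules: list[CausalRule]) -> str:
    lines = [_CONFIG_HEADER]
    for r in sorted(rules, key=lambda r: r.rule_id):
        lines.append(
            "\t".join(
                [
                    str(r.rule_id),
                    r.cause_capture,
                    r.effect_capture,
                    r.trigger_capture,
                    r.direction_policy.name,
                    r.pattern,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def rules_from_config(text: str) -> list[CausalRule]:
    rules = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(
                f"rule config line {lineno}: expected 6 tab-separated fields"
            )
        rid, cause, effect, trigger, policy, pattern = parts
        rules.append(
            CausalRule(
                int(rid), pattern, cause, effect, trigger, DirectionPolicy[policy]
            )
        )
    return rules
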