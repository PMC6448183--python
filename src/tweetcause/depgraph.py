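"""Dependency-graph data model with CoNLL-U serialization.

The substrate for all pattern matching is an *enhanced-style* dependency
graph: a directed graph over the tokens of one sentence in which a token
may have more than one governor (as produced by enhanced Universal
Dependencies exports, where e.g. conjuncts receive propagated subject
edges).  Because of that, the primary representation is an explicit edge
list rather than a per-token head array.  Token indices are 1-based, with
0 denoting the artificial root, exactly as in CoNLL-U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "Token",
    "DependencyEdge",
    "DependencyGraph",
    "ConlluParseError",
    "GraphIntegrityError",
    "read_conllu",
    "write_conllu",
    "subtree_yield",
]

log = logging.getLogger(__name__)


class ConlluParseError(ValueError):
    """A CoNLL-U line could not be parsed (wrong arity, bad integer...)."""


class GraphIntegrityError(ValueError):
    """A graph violates a structural invariant (dangling head, no root...)."""


@dataclass(frozen=True)
class Token:
    """One token of a sentence.

    ``xpos`` carries the treebank tag (NN, VBZ, ...) that the rule
    templates constrain via the ``tag`` attribute; ``upos`` is the
    universal tag, used only to recognize punctuation.
    """

    index: int
    form: str
    lemma: str = "_"
    upos: str = "_"
    xpos: str = "_"


@dataclass(frozen=True)
class DependencyEdge:
    governor: int  # 0 = artificial root
    dependent: int
    relation: str  # possibly subtyped, e.g. "nmod:agent"


@dataclass
class DependencyGraph:
    sentence_id: str
    text: str
    tokens: list[Token]
    edges: list[DependencyEdge]
    _by_index: dict = field(init=False, repr=False, compare=False)
    _deps: dict = field(init=False, repr=False, compare=False)
    _govs: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.tokens = sorted(self.tokens, key=lambda t: t.index)
        self.edges = sorted(
            set(self.edges), key=lambda e: (e.dependent, e.governor, e.relation)
        )
        self._by_index = {t.index: t for t in self.tokens}
        self._deps = {}
        self._govs = {}
        for e in self.edges:
            self._deps.setdefault(e.governor, []).append((e.relation, e.dependent))
            self._govs.setdefault(e.dependent, []).append((e.relation, e.governor))

    # -- access helpers -------------------------------------------------

    def token(self, index: int) -> Token:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(
                f"sentence {self.sentence_id!r} has no token {index}"
            ) from None

    def dependents_of(self, index: int) -> list[tuple[str, int]]:
        """(relation, dependent-index) pairs governed by ``index``."""
        return self._deps.get(index, [])

    def governors_of(self, index: int) -> list[tuple[str, int]]:
        """(relation, governor-index) pairs governing ``index`` (0 = root)."""
        return self._govs.get(index, [])

    # -- invariants ------------------------------------------------------

    def validate(self) -> "DependencyGraph":
        if not self.tokens:
            raise GraphIntegrityError(f"sentence {self.sentence_id!r}: no tokens")
        seen = set()
        for t in self.tokens:
            if t.index < 1:
                raise GraphIntegrityError(
                    f"sentence {self.sentence_id!r}: token index {t.index} < 1"
                )
            if t.index in seen:
                raise GraphIntegrityError(
                    f"sentence {self.sentence_id!r}: duplicate token index {t.index}"
                )
            seen.add(t.index)
            if not t.form:
                raise GraphIntegrityError(
                    f"sentence {self.sentence_id!r}: empty form at index {t.index}"
                )
        for e in self.edges:
            if e.dependent not in seen:
                raise GraphIntegrityError(
                    f"sentence {self.sentence_id!r}: edge dependent {e.dependent} "
                    "refers to no token"
                )
            if e.governor != 0 and e.governor not in seen:
                raise GraphIntegrityError(
                    f"sentence {self.sentence_id!r}: head {e.governor} refers to "
                    "no token"
                )
            if e.governor == e.dependent:
                raise GraphIntegrityError(
                    f"sentence {self.sentence_id!r}: self-loop at {e.dependent}"
                )
        if not any(e.governor == 0 for e in self.edges):
            raise GraphIntegrityError(
                f"sentence {self.sentence_id!r}: no token attached to root"
            )
        return self


# ---------------------------------------------------------------------------
# CoNLL-U I/O
# ---------------------------------------------------------------------------

_N_COLS = 10


def read_conllu(text: str) -> list[DependencyGraph]:
    """Parse a CoNLL-U document into one graph per sentence block.

    ``# sent_id`` and ``# text`` comments populate the corresponding graph
    fields.  When a token row carries enhanced dependencies in the DEPS
    column they define the token's (possibly multiple) incoming edges;
    otherwise HEAD/DEPREL define a single edge.  Multi-word-token ranges
    and empty nodes are skipped with a warning.
    """
    graphs: list[DependencyGraph] = []
    sent_id = ""
    stext = ""
    tokens: list[Token] = []
    edges: list[DependencyEdge] = []

    def flush() -> None:
        nonlocal sent_id, stext, tokens, edges
        if tokens:
            graphs.append(
                DependencyGraph(sent_id, stext, tokens, edges).validate()
            )
        sent_id, stext, tokens, edges = "", "", [], []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\r")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            key, sep, value = body.partition("=")
            if sep:
                key = key.strip()
                if key == "sent_id":
                    sent_id = value.strip()
                elif key == "text":
                    stext = value.strip()
            continue
        cols = line.split("\t")
        if len(cols) != _N_COLS:
            raise ConlluParseError(
                f"line {lineno}: expected {_N_COLS} tab-separated columns, "
                f"got {len(cols)}"
            )
        tid = cols[0]
        if "-" in tid or "." in tid:
            log.warning("line %d: skipping multi-word/empty node row %r", lineno, tid)
            continue
        try:
            idx = int(tid)
        except ValueError:
            raise ConlluParseError(
                f"line {lineno}: non-integer token id {tid!r}"
            ) from None
        tokens.append(Token(idx, cols[1], cols[2], cols[3], cols[4]))
        head, deprel, deps = cols[6], cols[7], cols[8]
        if deps != "_":
            for item in deps.split("|"):
                gov_s, sep, rel = item.partition(":")
                if not sep or not rel:
                    raise ConlluParseError(
                        f"line {lineno}: malformed DEPS item {item!r}"
                    )
                try:
                    gov = int(gov_s)
                except ValueError:
                    raise ConlluParseError(
                        f"line {lineno}: non-integer head {gov_s!r} in DEPS"
                    ) from None
                edges.append(DependencyEdge(gov, idx, rel))
        elif head != "_":
            try:
                gov = int(head)
            except ValueError:
                raise ConlluParseError(
                    f"line {lineno}: non-integer head {head!r}"
                ) from None
            edges.append(DependencyEdge(gov, idx, deprel))
    flush()
    return graphs


def write_conllu(graphs) -> str:
    """Serialize graphs to canonical 10-column CoNLL-U.

    Every incoming edge of a token is written to DEPS (sorted by governor,
    then relation); HEAD/DEPREL repeat the first of those.  Absent fields
    are underscores.  ``read_conllu(write_conllu(gs))`` reproduces ``gs``.
    """
    out: list[str] = []
    for g in graphs:
        g.validate()
        if g.sentence_id:
            out.append(f"# sent_id = {g.sentence_id}")
        if g.text:
            out.append(f"# text = {g.text}")
        for t in g.tokens:
            govs = sorted(g.governors_of(t.index), key=lambda p: (p[1], p[0]))
            if govs:
                head, deprel = str(govs[0][1]), govs[0][0]
                deps = "|".join(f"{gov}:{rel}" for rel, gov in govs)
            else:
                head = deprel = deps = "_"
            out.append(
                "\t".join(
                    [
                        str(t.index),
                        t.form,
                        t.lemma or "_",
                        t.upos or "_",
                        t.xpos or "_",
                        "_",
                        head,
                        deprel,
                        deps,
                        "_",
                    ]
                )
            )
        out.append("")
    return "\n".join(out) + "\n" if out else ""


# ---------------------------------------------------------------------------
# Subtree yield
# ---------------------------------------------------------------------------


def subtree_yield(graph: DependencyGraph, node: int, exclude=()) -> str:
    """Surface phrase dominated by ``node``.

    Walks governor->dependent edges transitively from ``node``, never
    entering token indices in ``exclude`` (so whole excluded subtrees drop
    out), skips punctuation (upos PUNCT) in the output, and joins the
    remaining forms in surface order with single spaces.  A visited set
    guards against cycles in the (possibly multi-governor) edge set.
    """
    graph.token(node)  # KeyError on unknown node
    ex = set(exclude)
    seen: set[int] = set()
    keep: list[int] = []
    stack = [node]
    while stack:
        i = stack.pop()
        if i in seen or i in ex:
            continue
        seen.add(i)
        if graph.token(i).upos != "PUNCT":
            keep.append(i)
        for _rel, dep in graph.dependents_of(i):
            if dep not in seen and dep not in ex:
                stack.append(dep)
    return " ".join(graph.token(i).form for i in sorted(keep))
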