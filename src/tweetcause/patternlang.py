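"""A Semgrex-subset pattern language over dependency graphs.

Grammar (whitespace insignificant outside regex literals)::

    Pattern   := Node
    Node      := "{" AttrList? "}" ("=" name)? RelClause*
    AttrList  := attr ":" "/" regex "/" (";" attr ":" "/" regex "/")*
    RelClause := ("<" | ">") RelName? Operand
    RelName   := bareword | "/" regex "/"
    Operand   := Node | "(" Node ")"

Attributes are ``word`` (surface form), ``lemma`` and ``tag`` (treebank
POS, e.g. VBZ).  Attribute regexes are implicitly anchored: the whole
attribute value must match.  They are case-sensitive; use an inline
``(?i)`` flag for case-insensitive matching.

Operator semantics follow Semgrex: ``X > rel Y`` means X *governs* Y via
rel, ``X < rel Y`` means X is a *dependent* of Y via rel.  A bare relation
name matches the exact label or any colon-subtyped extension of it
(``nmod`` matches ``nmod:of``); a ``/regex/`` relation must match the full
label.  Clauses on one node are conjunctive.  Negation, optionality and
uniqueness operators of full Semgrex are not implemented.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

__all__ = [
    "Direction",
    "NodePattern",
    "RelClause",
    "PatternAST",
    "MatchResult",
    "PatternSyntaxError",
    "parse_pattern",
    "pretty",
    "find_matches",
]

ATTRIBUTES = ("word", "lemma", "tag")


class PatternSyntaxError(ValueError):
    """Pattern source could not be parsed; carries a character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class Direction(Enum):
    GOVERNS = ">"
    DEPENDS = "<"


@dataclass(frozen=True)
class NodePattern:
    """Constraints on a single token; empty constraints match any token."""

    constraints: tuple[tuple[str, str], ...] = ()
    capture: str | None = None


@dataclass(frozen=True)
class RelClause:
    direction: Direction
    relation: str | None  # bare relation name, or None
    relation_regex: str | None  # slash-delimited regex source, or None
    child: "PatternAST"


@dataclass(frozen=True)
class PatternAST:
    node: NodePattern
    clauses: tuple[RelClause, ...] = ()


@dataclass(frozen=True)
class MatchResult:
    """One assignment of graph tokens to the pattern's captured nodes."""

    anchor: int
    bindings: tuple[tuple[str, int], ...]

    def binding(self, name: str) -> int:
        return dict(self.bindings)[name]


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_RELNAME = re.compile(r"[A-Za-z_][A-Za-z0-9_:]*")


class _Parser:
    def __init__(self, src: str):
        self.src = src
        self.i = 0

    def error(self, message: str):
        raise PatternSyntaxError(message, self.i)

    def ws(self) -> None:
        while self.i < len(self.src) and self.src[self.i].isspace():
            self.i += 1

    def peek(self) -> str:
        return self.src[self.i] if self.i < len(self.src) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            self.error(f"expected {ch!r}")
        self.i += 1

    def ident(self, rx=_IDENT) -> str:
        m = rx.match(self.src, self.i)
        if not m:
            self.error("expected identifier")
        self.i = m.end()
        return m.group()

    def regex_literal(self) -> str:
        self.expect("/")
        out = []
        while True:
            c = self.peek()
            if c == "":
                self.error("unterminated regex literal")
            if c == "\\" and self.i + 1 < len(self.src) and self.src[self.i + 1] == "/":
                out.append("/")
                self.i += 2
                continue
            if c == "/":
                self.i += 1
                break
            out.append(c)
            self.i += 1
        src = "".join(out)
        try:
            re.compile(src)
        except re.error as exc:
            self.error(f"invalid regex {src!r}: {exc}")
        return src

    def parse(self) -> PatternAST:
        self.ws()
        ast = self.node()
        self.ws()
        if self.i != len(self.src):
            self.error("trailing input after pattern")
        return ast

    def node(self) -> PatternAST:
        self.expect("{")
        constraints: list[tuple[str, str]] = []
        self.ws()
        if self.peek() != "}":
            while True:
                at = self.i
                attr = self.ident()
                if attr not in ATTRIBUTES:
                    self.i = at
                    self.error(f"unknown attribute {attr!r}")
                self.ws()
                self.expect(":")
                self.ws()
                constraints.append((attr, self.regex_literal()))
                self.ws()
                if self.peek() == ";":
                    self.i += 1
                    self.ws()
                    continue
                break
        self.expect("}")
        capture = None
        self.ws()
        if self.peek() == "=":
            self.i += 1
            self.ws()
            capture = self.ident()
        clauses: list[RelClause] = []
        while True:
            mark = self.i
            self.ws()
            if self.peek() in ("<", ">"):
                clauses.append(self.clause())
            else:
                self.i = mark
                break
        return PatternAST(NodePattern(tuple(constraints), capture), tuple(clauses))

    def clause(self) -> RelClause:
        direction = Direction.GOVERNS if self.peek() == ">" else Direction.DEPENDS
        self.i += 1
        self.ws()
        relation = relation_regex = None
        c = self.peek()
        if c == "/":
            relation_regex = self.regex_literal()
        elif c not in ("{", "(", ""):
            relation = self.ident(_RELNAME)
        self.ws()
        c = self.peek()
        if c == "(":
            self.i += 1
            self.ws()
            child = self.node()
            self.ws()
            self.expect(")")
        elif c == "{":
            child = self.node()
        else:
            self.error("expected operand node")
        return RelClause(direction, relation, relation_regex, child)


def parse_pattern(src: str) -> PatternAST:
    """Parse a pattern string into its AST.

    Raises :class:`PatternSyntaxError` (with character offset) on
    unbalanced braces/parens, unknown attributes or invalid regexes.
    """
    if not src or not src.strip():
        raise PatternSyntaxError("empty pattern", 0)
    return _Parser(src).parse()


def pretty(ast: PatternAST) -> str:
    """Canonical string form; ``parse_pattern(pretty(a)) == a``."""
    np = ast.node
    s = "{" + ";".join(f"{a}:/{rx.replace('/', chr(92) + '/')}/" for a, rx in np.constraints) + "}"
    if np.capture:
        s += f"={np.capture}"
    for cl in ast.clauses:
        rel = ""
        if cl.relation_regex is not None:
            rel = "/" + cl.relation_regex.replace("/", "\\/") + "/"
        elif cl.relation is not None:
            rel = cl.relation
        s += f" {cl.direction.value}{rel} ({pretty(cl.child)})"
    return s


# ---------------------------------------------------------------------------
# Matcher
# ---------------------------------------------------------------------------


@lru_cache(maxsize=512)
def _rx(src: str):
    return re.compile(src)


def _attr_value(tok, attr: str) -> str:
    if attr == "word":
        return tok.form
    if attr == "lemma":
        return tok.lemma
    return tok.xpos  # "tag"


def _node_ok(np: NodePattern, tok) -> bool:
    return all(_rx(rx).fullmatch(_attr_value(tok, attr)) for attr, rx in np.constraints)


def _rel_ok(cl: RelClause, label: str) -> bool:
    if cl.relation_regex is not None:
        return _rx(cl.relation_regex).fullmatch(label) is not None
    if cl.relation is not None:
        return label == cl.relation or label.startswith(cl.relation + ":")
    return True


def _match_node(ast: PatternAST, idx: int, graph, bindings: dict):
    tok = graph.token(idx)
    if not _node_ok(ast.node, tok):
        return
    cap = ast.node.capture
    if cap is not None:
        if cap in bindings:
            if bindings[cap] != idx:
                return  # same name must re-bind the same token
        elif idx in bindings.values():
            return  # distinct capture names bind distinct tokens
        else:
            bindings = {**bindings, cap: idx}
    yield from _match_clauses(ast.clauses, 0, idx, graph, bindings)


def _match_clauses(clauses, k: int, idx: int, graph, bindings: dict):
    if k == len(clauses):
        yield bindings
        return
    cl = clauses[k]
    if cl.direction is Direction.GOVERNS:
        cands = graph.dependents_of(idx)
    else:
        cands = [(rel, gov) for rel, gov in graph.governors_of(idx) if gov != 0]
    for rel, other in sorted(cands, key=lambda p: (p[1], p[0])):
        if not _rel_ok(cl, rel):
            continue
        for b in _match_node(cl.child, other, graph, bindings):
            yield from _match_clauses(clauses, k + 1, idx, graph, b)


def find_matches(ast: PatternAST, graph) -> list[MatchResult]:
    """All token assignments satisfying the pattern on one graph.

    Results are deduplicated on their binding maps and returned in a
    deterministic order: ascending anchor index, then ascending bound
    token indices.
    """
    seen = set()
    out: list[MatchResult] = []
    for tok in graph.tokens:
        for b in _match_node(ast, tok.index, graph, {}):
            key = (tok.index, tuple(sorted(b.items())))
            if key in seen:
                continue
            seen.add(key)
            out.append(MatchResult(anchor=tok.index, bindings=key[1]))
    out.sort(key=lambda m: (m.anchor, tuple(sorted(i for _, i in m.bindings))))
    return out
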