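"""Shared test helpers: random graphs/patterns and a brute-force matcher oracle."""

from __future__ import annotations

import itertools
import random
import re

import pytest

from tweetcause.depgraph import DependencyEdge, DependencyGraph, Token
from tweetcause.patternlang import Direction, NodePattern, PatternAST, RelClause

_VOCAB = [
    # form, lemma, upos, xpos
    ("stress", "stress", "NOUN", "NN"),
    ("causes", "cause", "VERB", "VBZ"),
    ("insomnia", "insomnia", "NOUN", "NN"),
    ("my", "my", "PRON", "PRP$"),
    ("made", "make", "VERB", "VBD"),
    ("result", "result", "NOUN", "NN"),
    ("leads", "lead", "VERB", "VBZ"),
    ("school", "school", "NOUN", "NN"),
    ("headaches", "headache", "NOUN", "NNS"),
]
_RELS = [
    "nsubj",
    "dobj",
    "nmod:of",
    "nmod:agent",
    "conj",
    "advmod",
    "amod",
    "case",
    "nsubjpass",
]


def random_graph(rng: random.Random, max_tokens: int = 8) -> DependencyGraph:
    """A random (possibly multi-governor, non-tree) dependency graph."""
    n = rng.randint(1, max_tokens)
    tokens = [Token(i, *rng.choice(_VOCAB)) for i in range(1, n + 1)]
    root = rng.randint(1, n)
    edges = [DependencyEdge(0, root, "root")]
    for i in range(1, n + 1):
        if i == root:
            continue
        gov = rng.choice([j for j in range(1, n + 1) if j != i])
        edges.append(DependencyEdge(gov, i, rng.choice(_RELS)))
    for _ in range(rng.randint(0, 2)):  # extra enhanced-style edges
        if n < 2:
            break
        dep = rng.randint(1, n)
        gov = rng.choice([j for j in range(1, n + 1) if j != dep])
        edges.append(DependencyEdge(gov, dep, rng.choice(_RELS)))
    text = " ".join(t.form for t in tokens)
    return DependencyGraph(f"rand-{rng.random():.8f}/0", text, tokens, edges)


def random_pattern(rng: random.Random, max_nodes: int = 4) -> PatternAST:
    """A random pattern with at most ``max_nodes`` pattern nodes."""
    budget = [rng.randint(1, max_nodes)]
    names = iter("abcdef")

    def node(depth: int) -> PatternAST:
        budget[0] -= 1
        constraints = []
        if rng.random() < 0.7:
            attr = rng.choice(["word", "lemma", "tag"])
            col = {"word": 0, "lemma": 1, "tag": 3}[attr]
            val = rng.choice(_VOCAB)[col]
            if rng.random() < 0.4:
                alt = rng.choice(_VOCAB)[col]
                rx = f"({re.escape(val)}|{re.escape(alt)})"
            else:
                rx = re.escape(val)
            constraints.append((attr, rx))
        capture = next(names) if rng.random() < 0.6 else None
        clauses = []
        if depth < 2:
            for _ in range(rng.randint(0, 2)):
                if budget[0] <= 0:
                    break
                direction = rng.choice([Direction.GOVERNS, Direction.DEPENDS])
                roll = rng.random()
                if roll < 0.4:
                    rel, rrx = rng.choice(_RELS), None
                elif roll < 0.7:
                    rel, rrx = None, rng.choice(
                        ["nmod:(of|agent)", "nsubj.*", "dobj", "nmod:.*"]
                    )
                else:
                    rel, rrx = None, None
                clauses.append(RelClause(direction, rel, rrx, node(depth + 1)))
        return PatternAST(NodePattern(tuple(constraints), capture), tuple(clauses))

    return node(0)


def _flatten(ast: PatternAST):
    nodes, links = [], []

    def rec(a: PatternAST) -> int:
        nid = len(nodes)
        nodes.append(a.node)
        for cl in a.clauses:
            cid = rec(cl.child)
            links.append((nid, cid, cl))
        return nid

    rec(ast)
    return nodes, links


def brute_force_matches(ast: PatternAST, graph: DependencyGraph) -> set:
    """Exhaustive enumeration over all token assignments to pattern nodes.

    Independent of the backtracking matcher; returns the set of
    (anchor, frozenset(capture bindings)) pairs.
    """
    nodes, links = _flatten(ast)
    idxs = [t.index for t in graph.tokens]
    toks = {t.index: t for t in graph.tokens}
    edge_set = [(e.governor, e.dependent, e.relation) for e in graph.edges]

    def attr(tok, a):
        return tok.form if a == "word" else tok.lemma if a == "lemma" else tok.xpos

    def node_ok(np, tok):
        return all(re.fullmatch(rx, attr(tok, a)) for a, rx in np.constraints)

    def rel_ok(cl, label):
        if cl.relation_regex is not None:
            return re.fullmatch(cl.relation_regex, label) is not None
        if cl.relation is not None:
            return label == cl.relation or label.startswith(cl.relation + ":")
        return True

    results = set()
    for assign in itertools.product(idxs, repeat=len(nodes)):
        if not all(node_ok(nodes[i], toks[assign[i]]) for i in range(len(nodes))):
            continue
        ok = True
        for pid, cid, cl in links:
            if cl.direction is Direction.GOVERNS:
                gov, dep = assign[pid], assign[cid]
            else:
                gov, dep = assign[cid], assign[pid]
            if not any(
                g == gov and d == dep and rel_ok(cl, r) for g, d, r in edge_set
            ):
                ok = False
                break
        if not ok:
            continue
        captures = {}
        consistent = True
        for i, np in enumerate(nodes):
            if np.capture is None:
                continue
            if np.capture in captures and captures[np.capture] != assign[i]:
                consistent = False
                break
            captures[np.capture] = assign[i]
        if not consistent or len(set(captures.values())) != len(captures):
            continue
        results.add((assign[0], frozenset(captures.items())))
    return results


def matcher_agrees_with_oracle(ast, graph) -> tuple[set, set]:
    from tweetcause.patternlang import find_matches

    got = {(m.anchor, frozenset(m.bindings)) for m in find_matches(ast, graph)}
    want = brute_force_matches(ast, graph)
    return got, want


@pytest.fixture(scope="session")
def fixtures_by_slug():
    from tweetcause.fixtures import fixture_map

    return fixture_map()
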