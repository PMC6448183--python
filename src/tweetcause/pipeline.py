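"""End-to-end orchestration: prefilter, parse lookup, batch extraction.

The flow mirrors a surveillance pipeline over a large message corpus:
a cheap keyword prefilter keeps only messages that can possibly mention a
target effect, each surviving message is mapped to its sentence-level
dependency parses, and the rule engine runs per sentence.  Parsing itself
is delegated: either pre-parsed CoNLL-U keyed by record id (authoritative
for tests), or any callable adapter that turns raw text into CoNLL-U.
Processing is streaming — records are consumed one at a time.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

from .depgraph import DependencyGraph, read_conllu
from .rules import CausalRule, CausalTriple, extract_triples

__all__ = [
    "CorpusRecord",
    "RunReport",
    "keyword_filter",
    "ConlluParseSource",
    "AdapterParseSource",
    "TextLookupParseSource",
    "run_extraction",
    "iter_extraction",
    "frequency_table",
    "read_records",
    "write_triples_jsonl",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorpusRecord:
    record_id: str
    text: str
    source_meta: tuple = ()


@dataclass
class RunReport:
    """Tallies for one extraction run.

    ``per_rule_counts[rule_id][effect]`` counts *sentences*: a sentence
    counts once under every (rule, effect) pair that fired in it, so the
    per-rule sums can exceed the number of deduplicated triples.
    """

    n_input: int = 0
    n_keyword_matched: int = 0
    n_missing_parse: int = 0
    per_rule_counts: dict = field(default_factory=dict)
    n_triples: dict = field(default_factory=dict)

    def per_rule_totals(self) -> dict[int, int]:
        return {r: sum(d.values()) for r, d in sorted(self.per_rule_counts.items())}

    def total_triples(self) -> int:
        return sum(self.n_triples.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_keyword_matched": self.n_keyword_matched,
            "n_missing_parse": self.n_missing_parse,
            "per_rule_counts": {
                str(r): dict(sorted(d.items()))
                for r, d in sorted(self.per_rule_counts.items())
            },
            "n_triples": dict(sorted(self.n_triples.items())),
        }


# ---------------------------------------------------------------------------
# Keyword prefilter
# ---------------------------------------------------------------------------


def _keyword_regex(keywords) -> re.Pattern:
    # No letter may precede the keyword; trailing letters are allowed so
    # that plural/derived forms ("headaches", "stressed") survive the
    # filter.  This is deliberately recall-oriented: the filter must never
    # drop a message the rule engine could extract from.
    alts = "|".join(re.escape(k) for k in sorted(keywords, key=len, reverse=True))
    return re.compile(rf"(?<![a-zA-Z])(?:{alts})", re.IGNORECASE)


def keyword_filter(
    records: Iterable[CorpusRecord], keywords
) -> Iterator[CorpusRecord]:
    """Keep records whose text contains any keyword; order preserved."""
    rx = _keyword_regex(keywords)
    for rec in records:
        if rx.search(rec.text):
            yield rec


# ---------------------------------------------------------------------------
# Parse sources
# ---------------------------------------------------------------------------


class ConlluParseSource:
    """Pre-parsed sentences keyed by ``# sent_id = <record_id>/<n>``."""

    def __init__(self, conllu_text: str):
        self._by_record: dict[str, list[DependencyGraph]] = {}
        for g in read_conllu(conllu_text):
            rid = g.sentence_id.rsplit("/", 1)[0]
            self._by_record.setdefault(rid, []).append(g)

    def graphs_for(self, record: CorpusRecord):
        return self._by_record.get(record.record_id)


class TextLookupParseSource:
    """Gold graphs looked up by exact sentence text (fixture-backed)."""

    def __init__(self, graphs: Iterable[DependencyGraph]):
        self._by_text = {g.text: [g] for g in graphs}

    def graphs_for(self, record: CorpusRecord):
        return self._by_text.get(record.text)


class AdapterParseSource:
    """Wraps an external parser adapter: raw text -> CoNLL-U string.

    The adapter owns sentence splitting, tokenization, lemmatization, POS
    tagging and dependency parsing.  Adapter failures are logged and the
    record skipped.
    """

    def __init__(self, parse_fn: Callable[[str], str]):
        self._parse_fn = parse_fn

    def graphs_for(self, record: CorpusRecord):
        try:
            return read_conllu(self._parse_fn(record.text)) or None
        except Exception:
            log.exception("parser adapter failed on record %s", record.record_id)
            return None


def _as_parse_source(parses):
    if hasattr(parses, "graphs_for"):
        return parses
    if isinstance(parses, str):
        return ConlluParseSource(parses)
    if callable(parses):
        return AdapterParseSource(parses)
    raise TypeError(f"cannot interpret parse source of type {type(parses)!r}")


# ---------------------------------------------------------------------------
# Batch extraction
# ---------------------------------------------------------------------------


def iter_extraction(
    records: Iterable[CorpusRecord],
    parses,
    effects,
    rules: list[CausalRule] | None = None,
    report: RunReport | None = None,
    keywords=None,
) -> Iterator[CausalTriple]:
    """Streaming extraction; fills ``report`` in place as it goes."""
    source = _as_parse_source(parses)
    if report is None:
        report = RunReport()
    keywords = keywords or effects
    rx = _keyword_regex(keywords)
    for rec in records:
        report.n_input += 1
        if not rx.search(rec.text):
            continue
        report.n_keyword_matched += 1
        graphs = source.graphs_for(rec)
        if not graphs:
            report.n_missing_parse += 1
            log.warning("no parse for record %s; skipped", rec.record_id)
            continue
        for graph in graphs:
            triples = extract_triples(graph, effects, rules)
            for rule_id, effect in sorted({(t.rule_id, t.effect) for t in triples}):
                by_eff = report.per_rule_counts.setdefault(rule_id, {})
                by_eff[effect] = by_eff.get(effect, 0) + 1
            for t in triples:
                report.n_triples[t.effect] = report.n_triples.get(t.effect, 0) + 1
                yield t


def run_extraction(
    records, parses, effects, rules=None, keywords=None
) -> tuple[list[CausalTriple], RunReport]:
    """Run the full pipeline and return (triples, report)."""
    report = RunReport()
    triples = list(
        iter_extraction(records, parses, effects, rules, report, keywords)
    )
    return triples, report


def frequency_table(triples) -> list[tuple[str, str, int]]:
    """Ranked (normalized cause phrase, effect, count) tuples.

    Cause phrases are lower-cased and whitespace-normalized before
    counting; ties are broken lexicographically.
    """
    counts: dict[tuple[str, str], int] = {}
    for t in triples:
        key = (" ".join(t.cause.split()).lower(), t.effect)
        counts[key] = counts.get(key, 0) + 1
    return sorted(
        ((phrase, effect, n) for (phrase, effect), n in counts.items()),
        key=lambda row: (-row[2], row[0], row[1]),
    )


# ---------------------------------------------------------------------------
# Record / triple I/O
# ---------------------------------------------------------------------------


def read_records(lines: Iterable[str]) -> Iterator[CorpusRecord]:
    """Records from UTF-8 lines: JSONL ({"id", "text"}) or plain text.

    Plain-text lines get sequential ids ``line-<n>``.
    """
    for n, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("{"):
            obj = json.loads(line)
            meta = tuple(
                sorted((k, str(v)) for k, v in obj.items() if k not in ("id", "text"))
            )
            yield CorpusRecord(str(obj["id"]), obj["text"], meta)
        else:
            yield CorpusRecord(f"line-{n:06d}", line)


def triple_to_dict(t: CausalTriple) -> dict:
    return {
        "id": t.sentence_id.rsplit("/", 1)[0],
        "sentence_id": t.sentence_id,
        "rule_id": t.rule_id,
        "cause": t.cause,
        "trigger": t.trigger,
        "effect": t.effect,
        "cause_head": t.cause_head,
        "effect_head": t.effect_head,
    }


def write_triples_jsonl(triples, fh) -> None:
    for t in triples:
        fh.write(json.dumps(triple_to_dict(t), ensure_ascii=False) + "\n")
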