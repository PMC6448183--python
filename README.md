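# tweetcause

Rule-based extraction of explicit cause–effect statements about health
complaints from short informal texts (tweets and similar messages).

People routinely attribute everyday health problems to everyday causes —
"Missing someone causes insomnia.", "School is the main cause of my
stress". Harvesting these attributions at scale gives public-health
researchers a view of perceived causes of conditions like **stress**,
**insomnia** and **headache** that clinical records do not capture. Doing
it precisely is the hard part: informal language is full of negated,
hypothetical and interrogative near-misses ("Could this be the cause of
my insomnia?"), so this package takes the high-precision route of
matching lexico-syntactic patterns against dependency parses rather than
bag-of-words heuristics or trained classifiers.

## The method

Each sentence is represented as an **enhanced Universal Dependencies
graph** (tokens plus labeled directed edges; a token may have several
governors). Against this graph the package matches six rule templates,
written in a subset of the Semgrex pattern language, anchored on a small
trigger lexicon:

* trigger **verbs** (7): *cause, stimulate, make, derive, trigger,
  result, lead*
* trigger **nouns** (3): *result, reason, cause*
* phrasal prepositions: *in, to, from*

| # | construction | example |
|---|--------------|---------|
| 1 | A *caused* B (nominal subject) | Stress causes insomnia |
| 2 | A-ing *caused* B (clausal subject) | Over thinking can … cause insomnia |
| 3 | B *was caused by* A (nominal agent) | My insomnia was caused by stress |
| 4 | A *is a reason/cause/result of* B | Stress is a reason of my insomnia |
| 5 | B *was caused by* A-ing (clausal agent) | Insomnia was caused by overthinking |
| 6 | A *results in/to/from* B | Stress results to insomnia |

A template such as rule 1,

```
{}=subj <nsubj ({lemma:/cause|…/;tag:/VB.*/}=target >dobj {}=obj)
```

reads: a token `subj` that is the nominal subject of a trigger verb
`target`, which also governs a direct object `obj`. Matching is on the
*lemma*, so "causes", "caused" and "causing" all fire. A per-rule role
map turns captures into a triple **⟨cause, trigger, effect⟩**; for the
"result of" and "results from" constructions the causal direction flips
("Insomnia is a result of stress" ⇒ cause = stress). A match is kept
only when the effect token — or a conjunct reachable from it, so that
"swollen eye & headaches" matches *headache* — is one of the configured
target effects. The cause phrase is the matched token's subtree yield.

Precision against human annotation is computed per effect category and
micro-averaged, in two modes: **strict** (only clearly asserted causal
statements count as correct) and **relaxed** (negated or hypothetical
causal statements also count). A `modality_flag` heuristic
(negation / modal auxiliary / question mark) helps triage those cases,
but annotation remains the source of truth.

Because no public corpus exists for this task, the package ships a
deterministic synthetic-corpus generator (`tweetcause.synthgen`) that
builds sentences *with* their gold graphs and gold triples from the six
constructions plus distractors (negated, hypothetical, interrogative,
non-causal), and a set of 22 hand-annotated gold fixtures
(`tweetcause.fixtures`) covering every construction.

## Worked example

```python
from tweetcause import (
    fixture_map, extract_triples, modality_flag, frequency_table,
    run_extraction, gold_fixtures,
)
from tweetcause.pipeline import TextLookupParseSource

ex = fixture_map()["missing-someone-causes-insomnia"]
(t,) = extract_triples(ex.graph, {"insomnia"})
print(f"rule {t.rule_id}: cause={t.cause!r} trigger={t.trigger!r} effect={t.effect!r}")
print("modality:", modality_flag(ex.graph).value)

reported = [e for e in gold_fixtures() if e.group == "reported"]
source = TextLookupParseSource([e.graph for e in reported])
triples, report = run_extraction(
    (e.record for e in reported), source, {"stress", "insomnia", "headache"}
)
print("per-rule sentence tally:", report.per_rule_totals())
for phrase, effect, n in frequency_table(triples)[:3]:
    print(f"{n}x  {phrase!r} -> {effect}")
```

prints

```
rule 1: cause='Missing someone' trigger='cause' effect='insomnia'
modality: NONE
per-rule sentence tally: {1: 3, 4: 2, 6: 3}
1x  'missing someone' -> insomnia
1x  'money' -> stress
1x  'my neck' -> headache
```

"Missing someone causes insomnia." fires the direct
subject–verb–object rule with *Missing someone* as the extracted cause;
across the eight bundled informal messages, three fire rule 1, two the
copular rule 4 and three the phrasal rule 6, and the frequency table
aggregates the normalized cause phrases per effect.

There is also a CLI: `tweetcause synth` writes a synthetic corpus
(text + CoNLL-U + gold triples), `tweetcause extract` runs the pipeline
over a message file with pre-parsed CoNLL-U (`--parses`) or any external
UD parser adapter (`--parser module:callable`), and
`tweetcause evaluate` renders strict/relaxed precision from an
annotation TSV.

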