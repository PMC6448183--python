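# Methods

## Problem and scope

The package extracts *explicitly stated, within-sentence* cause–effect
assertions about a fixed set of health effects (default: stress,
insomnia, headache) from short informal texts. It deliberately optimizes
precision over recall: the intended use is surveillance over very large
corpora where a human reviews the extractions, so a small set of
high-confidence syntactic templates beats broad-coverage heuristics.
Cross-sentence causality, hashtag semantics, and synonym expansion of
the effect terms ("can't sleep" for insomnia) are out of scope.

## Representation

Sentences are enhanced-style Universal Dependencies graphs: 1-based
tokens (index 0 is the artificial root) and an explicit edge list in
which a token may have several governors — enhanced UD propagates, for
example, the object relation to conjoined verbs and the `nmod:to`
relation to conjoined nominals. Serialization is 10-column CoNLL-U; on
writing, every incoming edge goes to DEPS and HEAD/DEPREL repeat the
first of them, which makes `read ∘ write` the identity. Multi-word-token
ranges and empty nodes are skipped with a warning: the short informal
register this targets essentially never needs them, and skipping keeps
the graph model simple.

Parsing itself is *not* part of the package. The pipeline accepts either
pre-parsed CoNLL-U keyed by `# sent_id = <record_id>/<n>` (authoritative
for all tests) or any callable adapter mapping raw text to CoNLL-U.
Parses are model-dependent and parser stacks age quickly; keeping the
contract thin makes the rule engine testable against hand-annotated gold
graphs and usable with whatever UD parser a deployment has.

## Pattern language

The matcher implements the Semgrex subset the rules need: node
constraints on `word`/`lemma`/`tag` as implicitly anchored regexes,
conjunctive relation clauses `>`/`<` (governs / is-dependent-of), bare
or regex relation names, named captures. A bare relation name also
matches its colon-subtyped extensions (`nmod` matches `nmod:of`), since
enhanced UD subtypes labels freely; a regex relation must match the full
label. Distinct capture names must bind distinct tokens — this is what
prevents degenerate matches where cause and effect collapse onto the
same token. Negation, optionality and uniqueness operators of full
Semgrex are intentionally absent; none of the six templates needs them.
Matching is plain backtracking over the (tiny) per-sentence graph, with
results deduplicated on their binding maps and ordered by anchor index,
then bound indices, so runs are deterministic. Its soundness and
completeness are tested against an independent brute-force enumerator
over all token assignments on random graphs of up to 8 tokens.

## Rules and roles

Six templates cover the active, clausal-subject, passive (nominal and
clausal agent), copular-noun and phrasal constructions. Two design
points deserve explanation:

* **Tag constraints on triggers.** The lemma "cause" is both a trigger
  verb and a trigger noun. Verb rules therefore require `tag:/VB.*/` and
  the copular rule `tag:/NN.*/`, so "causes/VBZ" dispatches to rule 1
  and "cause/NN" to rule 4. Without this, the noun reading could fire
  verb templates on parser quirks.
* **Direction policies.** Capture order in a pattern reflects surface
  syntax, not causal direction. "A is a reason of B" has cause = subject,
  but "A is a *result* of B" reverses it, and likewise "A results
  *from* B" reverses "A results in/to B". Rules 4 and 6 carry explicit
  flip policies (on trigger lemma *result*, and on an `nmod:from` edge,
  respectively). The "from" flip follows English semantics; it is
  exercised by the generator's templates rather than by a bundled
  reference sentence.
* **Rule 6 triggers** are the phrasal lemmas *cause, result, reason*
  plus *lead* ("leads to …"), used verbally.

Trigger matching is on lemma, so inflection is free. A match becomes a
triple only if the effect-role token, or a token reachable from it over
`conj` edges, has a target lemma (lower-cased; plural surface forms
match via the lemma). The cause phrase is the subtree yield of the
cause-role token with three exclusions: punctuation, the trigger and
effect subtrees, and `case`/`mark` function words attached directly to
the cause head — the last so that a passive agent yields "stress", not
"by stress". How to delimit multi-word cause phrases is genuinely open;
subtree yield with these exclusions reproduces phrases like "Missing
someone" and "Night before first day of school" without hand-tuning.
Per sentence, at most one triple per (rule, effect keyword) is emitted
(lowest match anchor wins), which makes per-rule tallies sentence-level
counts.

## Pipeline

The keyword prefilter keeps messages containing a target keyword with no
letter immediately to its left; trailing letters are allowed so that
"Headaches" and "STRESSED" pass. This is deliberately recall-oriented —
the filter must never drop a message the rule engine could extract from,
and that property (filter-then-extract ≡ extract-alone) is tested on the
fixtures and on synthetic corpora. Records are processed as a stream;
memory does not grow with corpus size. Reports tally inputs, filter
survivors, missing parses, per-rule per-effect sentence counts and
triple counts.

## Evaluation

Precision = annotated positives / system extractions, per effect
category, with the micro-average pooling counts across categories.
Strict mode counts only `CAUSAL` labels; relaxed mode additionally
counts `HYPOTHETICAL_OR_NEGATED`. Internally all ratios are exact
`Fraction`s; rendering rounds half-up to two decimals, so 135/181 →
74.59% and 167/181 → 92.27% exactly. Relaxed ≥ strict holds by
construction and is property-tested. The `modality_flag` heuristic
(question mark > negation lemma attached via `neg`/`advmod` > modal
auxiliary, checked sentence-wide) is advisory metadata only; it is never
folded into precision silently. Checking the whole sentence rather than
the trigger's clause alone is a deliberate simplification: for matrix
negation ("I wouldn't say it causes insomnia though") the cue lies
outside the trigger's clause, and a sentence-wide scan still flags it.

## Synthetic data

The generator emulates the *syntactic* phenomena the extractor must
handle, not real tweet orthography (no hashtags, emoji or elongations).
Defaults:

* `n_sentences=100`, `seed=0`, `distractor_rate=0.0`;
* `rule_mix = {1: .40, 2: .09, 3: .08, 4: .12, 5: .06, 6: .25}` — direct
  active constructions dominate informal messages, the phrasal
  construction is second, passives are rare;
* effect vocabulary {stress, insomnia, headache}; ten 1–3-token cause
  phrases (nouns with amod/compound/poss/advmod structure) plus four
  gerund phrases for the clausal constructions.

Distractors split evenly over four kinds: negated ("X never causes Y"),
hypothetical (modal auxiliary), interrogative, and non-causal trigger
usage ("X makes life more stress free", where the trigger verb's object
is not an effect term). The first three still fire a rule — that is
exactly the strict-mode error mode — while carrying no strict-gold
triple, so end-to-end strict precision on a mixed corpus equals the
planted fraction by exact counting. Gold graphs are template-built, so
passing tests certify the engine's behavior *given a correct parse*;
they say nothing about robustness to real parser errors, which is the
main caveat when moving to live data.

The 22 bundled gold fixtures are hand-annotated enhanced-UD graphs
covering each construction (rules 2, 3 and 5 appear only there), the
direction flips, conjoined effects, and the modality/error shapes.
Where a sentence admits several defensible annotations (e.g. the head
of "Missing someone", annotated as the nominal with the participle as
its modifier; the propagated `csubj` onto a conjoined trigger verb),
the choice is recorded inline in `fixtures.py`.

## Problem sizes and numerics

The test suite uses corpora of 10^3 generated sentences, a matcher
equivalence sweep of 10^3 random graph/pattern pairs (≤ 8 tokens,
≤ 4 pattern nodes), and a 10^5-record streaming check; the whole suite
runs in a few seconds. There are no floating-point tolerances anywhere:
rule dispatch is discrete, and evaluation arithmetic is exact rational,
rounded only at rendering. Ties in match enumeration are broken by token
index; dictionary iteration never determines output order.

## Known limitations

* Relation labels follow the enhanced-UD inventory the rule set was
  designed around (`nmod:agent`, `nmod:of`, `advcl:by`, `nsubjpass`);
  corpora parsed with newer UD revisions (`obl:agent`, `nsubj:pass`)
  need a relabeling shim or adjusted rule config.
* Six templates cannot cover the full variety of causal language; recall
  is unmeasured by design.
* Effect terms are matched literally by lemma; no synonym or spelling
  variation handling.
* `modality_flag` is a cue heuristic, not a scope-aware negation
  detector.
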